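# Methods

This note documents the models implemented in `coroperf`, the defaults and
the reasoning behind them, what the synthetic-geometry generator does and
does not emulate, and the numerical choices that matter when interpreting
results.

## 1. Hybrid vascular network

The arterial domain is a forest of two trees rooted at the coronary ostia.
Epicardial ("segmented") vessels are centerline curves with a
cross-sectional area per node at a fixed 0.01 cm arc-length spacing, the
resolution at which image-derived centerlines are conventionally resampled.
Downstream ("synthetic") vessels are straight cylinders of constant radius;
each carries an undilated reference radius `r0` and a dilation fraction, so
vasodilation is a reversible state, not a destructive edit.

Strahler orders are assigned by the classic topological rule (leaves
minimal; a parent whose maximal child order is attained twice increments
it), shifted so terminals sit at order 5, followed by one diameter-based
reassignment pass: a segment whose mean diameter falls outside the
mean ± SD band of its order moves to the adjacent order.  On the default
geometry this puts terminals mainly in orders 5–6 and the ostial vessels at
orders 10–11, the ordering ranges reported for human coronary trees.  An
iterated variant of the reassignment is available
(`max_refine_iterations`) but degrades the flow–order relationship (see
§8) and is not the default.

Elements — maximal chains of same-order segments — are the unit of
per-order flow statistics.  Trimming removes synthetic trees that achieved
less than 20% of their target flow (strict comparison: a tree at exactly
20% survives); on default geometries the removed trees carry well under 2%
of terminals.

## 2. Synthetic geometry generator

The generator stands in for patient imaging and produces three things.

**LV wall.**  A truncated half-ellipsoid shell (endocardial semi-axes
2.5/2.5/6 cm, epicardial 3.5/3.5/7 cm, basal plane at the equator; volume
≈ 101 mL, inside the normal 60–200 mL range).  The shell is meshed by a
structured transmural × meridional × azimuthal grid whose hexahedral cells
are split into 12 tetrahedra around their centroid (8 for the prisms that
close the apex).  This keeps the mesh conforming and watertight with no
external meshing dependency, pins the element count near the requested
target, and reproduces the analytic shell volume to well under 1% at
ordinary resolutions.  Requests coarse enough to violate the 2% volume
contract are rejected.

**Epicardial vessels.**  Four named vessels — left main (LM) splitting
into LAD and LCX, plus the RCA — as spline paths on a 2%-offset epicardial
surface: a wrap-around LAD to the apex and inferior wall, a long circumflex
course, an RCA with a proximal segment elevated above the base (its roots
there are flagged as not perfusing the LV).  Calibers taper geometrically
(LM 0.17→0.15, LAD 0.14→0.05, LCX/RCA 0.13→0.05 cm radius).  An optional
stenosis multiplies the local diameter by a smooth cosine bump of
prescribed reduction and length.

**Roots, stems and forest.**  Synthetic-tree roots sit at the three distal
outlets and along the vessels at 1.2 cm intervals (side-root radius 0.7×
the local trunk radius).  Each root carries a *stem*: a 7 cm chain of
constant-caliber, non-dilating segments running along the epicardial
surface, standing in for the epicardial branch (diagonal, marginal, distal
run-off) that a segmentation of only four vessels necessarily misses.  The
stem is the load-bearing design choice of the fixture: the physiological
behaviour of the coupled regimes requires substantial *non-dilating*
resistance on every outlet path (see §5), while clinically measured FFR
lives on the trunks, which must therefore stay wide.  Real patients satisfy
both because side branches carry that resistance; the stems reproduce this
with four explicit vessels.

From each stem end a tree grows by sequential competitive volume-minimising
growth: candidate perfusion sites are sampled uniformly in the wall; each
site goes to the nearby tree (within 4× the minimal distance) with the
largest flow deficit relative to its target share (targets ∝ root
diameter^2.7); the site connects to the segment of that tree minimising the
incremental vascular volume — new-branch length plus the Murray up-sizing
cost of the path back to the root, ≈ (2/3)Σ Lᵢ wᵢ^(−1/3) for one added
terminal — subject to the new branch staying inside the wall.  Each
connection bifurcates an existing segment, so the terminal count rises by
exactly one per accepted site and growth stops exactly at the requested
count (non-LV outlets included in the total).  Radii are assigned top-down:
the stub takes the root caliber and the bifurcation power law
r_parent^η = Σ r_child^η (η = 3, Murray) splits it by subtree flow weight;
leaf weights are lognormal (σ = 0.5) to emulate terminal-flow
heterogeneity.  Terminal radii shrink with forest size as n^(−1/3) and span
more than an order of magnitude across the network at n ≥ 2000.

What the generator does **not** emulate: real branching anatomy (vessel
names beyond the four trunks, septal perforators, apical collaterals),
transmural penetration ordering of arterioles, the staged macro/micro
growth of the reference generator, and inter-patient anatomical
variability beyond the seed.  Consequences of the first two are visible in
§8.

## 3. Coronary flow solver

Flows are solved by subtree summation of the imposed terminal flows (mass
balance is then exact to machine precision at every junction).  Pressures
march from the ostia (P_AO = 93 mmHg, both regimes) to the terminals with
continuity at junctions.  On segmented vessels the marching form is

    dp/dz = ρ (α Q² S′/S³ − 8πν Q/S²),

integrated by the trapezoidal rule on the 0.01 cm node grid; for constant S
this is exactly Poiseuille.  α = 4/3 (parabolic profile) except at
area-increasing nodes, where it is multiplied by a regime- and
location-dependent factor (rest: 0.29 inside / 0.34 outside bifurcating
regions; hyperemia: 0.72 / 0.36) so that expansions do not recover the full
dynamic pressure.  A bifurcating region extends one local radius of
arc-length from a junction (the extent is not physically pinned down;
it is configurable).  α is treated as a *local* coefficient — its spatial
derivative is not differentiated.  Differentiating α(z) inside the
advective term would make the model predict a pressure *rise* where α
drops at constant area, the opposite of the factor's purpose.

Synthetic segments use the Poiseuille drop at their current (dilated)
radius, so a fully dilated vessel has 1.4⁻⁴ ≈ 0.26 of its undilated
resistance.

## 4. Outflow physiology

* Total resting LV flow: Q = ζ V_LV^γ with ζ = 3.41 mL^0.25 min⁻¹ and
  γ = 0.75 — an allometric fit that centres resting perfusion at
  ≈ 1 mL min⁻¹ g⁻¹.
* Terminal split: qᵢ ∝ rᵢ^2.7, normalised exactly.
* Non-LV outlets: 20% of the LV total, same split law, quadrupled under
  hyperemia like everything else.

**Resting adaptation.**  Rest flows are held at their ideal values; the
only degree of freedom is dilation.  A tree dilates in 1% increments (cap
40%) while any of its outlets sits below a perfusion floor of 60 mmHg —
equivalently, while its implied microvascular resistance
(p_out − 15)/q is below the minimum implied by the floor.  Healthy
geometries need no resting dilation; a severe stenosis drives its tree to
the cap, and only that tree.

**Hyperemic adaptation.**  All synthetic trees to the 40% cap; ideal flows
4× rest; the per-outlet microvascular resistance floor is a quarter of its
resting value.  The fixed point q ↦ min(ideal, (p_out − 15)/R_floor) is
iterated with per-outlet Aitken (secant) relaxation.  Plain
under-relaxation is insufficient here: a focal stenosis couples hundreds of
outlets through one shared pressure drop, producing a collective gain far
above the stability limit of any fixed factor.  Outlets whose *resting*
pressure already sits below 15 mmHg (possible behind a severe stenosis,
since rest flows are imposed) have no meaningful implied resistance; they
are limited instead by a perfusion-pressure cap that scales flow towards
the value restoring p_out = 15 mmHg.  Convergence is declared when the
largest flow change, scaled by the outlet's ideal flow, falls below 10⁻⁴
(scaling by the current flow would let collapsed outlets chatter around
the numerical floor forever).

## 5. Why the regimes behave as they do

The achieved hyperemic/resting flow factor follows, per outlet, from
f = 4(p_h − 15)/(p_r − 15).  Writing the rest drop as a non-dilating part
(trunk + stem) plus a dilating part (synthetic tree), the factor lands in
the physiological 2.7–3.4 band only when the non-dilating part dominates;
if nearly all resistance dilates, f → 3.8–4.  With the default fixture the
rest drop is ≈ 10 mmHg (trunk ≈ 1–2, stems ≈ 4–6, trees ≈ 3–4), the
hyperemic drop ≈ 22 mmHg, f ≈ 3.37, and the healthy trunks keep FFR
≥ 0.83.  These values are stable across seeds.

## 6. Myocardium model

Single-compartment Darcy flow: w = −K∇p with isotropic constant
K = 2·10⁻⁵ cm² Pa⁻¹ s⁻¹ (internally converted to mmHg/min units), mass
balance ∇·w = β_src(p_src − p) − β_snk(p − p_snk), no-flux walls.
Conductances come from the total-flow balance

    β_src = Q_tot / ((p̄_src − p̄) V_LV),   β_snk = Q_tot / ((p̄ − p_snk) V_LV),

with target mean capillary pressure p̄ = 15 mmHg and venous reference
p_snk = 0.  Both scale with Q_tot, so hyperemia raises them — the porous
analogue of microvascular recruitment.  p̄_src is the unweighted arithmetic
mean of the outlet pressures (a flow-weighted option exists).  For a
spatially uniform source pressure the construction gives mean p = 15
exactly; with territory-wise variation the volume-averaged pressure stays
within a fraction of a percent, the residual reflecting correlation
between territory volume and source pressure.

Discretisation: P1 tetrahedra, consistent mass matrix, element-wise
constant source field; the SPD system is solved by Jacobi-preconditioned
conjugate gradients to a 10⁻⁸ relative residual (direct sparse solve as a
fallback).  Source support is each outlet's whole territory with a
territory-constant p_src, which keeps β_src spatially constant and makes
territory inflow Q_j = ∫ β_src(p_src,j − p) well defined.  Territory
inflows are mesh-converged to below 1% already between ~12k and ~25k
elements.

**Territories.**  Discrete Laguerre tessellation over element centroids:
argminᵢ ‖x − sᵢ‖² − (λ dᵢ)².  The weight scale is λ = 8 (configurable).
This is deliberate: with λ ≈ 1 the weights (λd)² ~ 10⁻³ cm² are negligible
against inter-outlet distances² ~ 10⁻¹ cm², the tessellation degenerates to
an unweighted Voronoi partition, outlet caliber stops influencing territory
size, and the coupled model *reduces* outlet-flow dispersion instead of
raising it.  At λ = 8 territory volume correlates with diameter (r ≈ 0.6)
and coupling raises the outlet-flow SD by ≈ 25–35% at equal mean — the
expected behaviour of a diameter-weighted partition.  Power cells of
heavily dominated outlets can be empty; such outlets receive no territory
and their coupled flow is pinned at the numerical floor.

## 7. Coupling

Gauss–Seidel exchange per iteration k: coronary solve with current outlet
flows → outlet pressures; conductances re-estimated from the (fixed) regime
total and the current mean source pressure; Darcy solve → territory
inflows; outlet flows updated towards the inflows with per-outlet Aitken
relaxation (initial factor 0.5, tolerance 10⁻³ on the relative flow change,
at most 50 iterations).  Holding Q_tot fixed inside the loop keeps the
conductance estimate well posed.  At convergence total outlet flow and
total territory inflow agree to the loop tolerance; healthy cases converge
in ≈ 6–10 iterations, severe stenosis in ≈ 20–30.

## 8. Post-processing

* **FFR** = p/P_AO; positive (hemodynamically significant) strictly below
  0.8.  Per-tree minima are reported over the *segmented* vessels by
  default: FFR is an epicardial, pressure-wire quantity; arteriolar outlet
  pressures sit far lower in any healthy network.
* **MBF** = Q_j/(ρ_tissue Ω_j), tissue density 1.05 g mL⁻¹, at four
  resolutions: whole myocardium (~100 mL), the three main-artery
  territories (~35 mL), AHA-17 segments (~6 mL), and per-element "voxels"
  (~10⁻³–10⁻⁴ mL).  Statistics are volume-weighted, which makes the mean
  exactly invariant across resolutions; SD grows monotonically with
  resolution.  The stand-alone coronary model spreads each terminal flow
  uniformly over its territory; the coupled model uses the per-element
  Darcy source inflow.
* **AHA-17**: apical cap (lowest 15% of the long axis) is segment 17;
  the remaining axis splits into thirds with 6/6/4 circumferential sectors
  (apical sectors rotated 45°), anterior at +y.
* **Perfusion maps**: polar (bull's-eye) raster, radius apex→base, cell
  volumes near the 6.4·10⁻² mL PET resolution, volume-weighted per cell;
  the map mean conserves whole-organ MBF.
* **Strahler statistics**: mean element flow per order, least-squares line
  on ln(flow) vs order (orders with fewer than two elements excluded), and
  per-order pressure summaries.
* **Fractal analysis**: octree-style cubic blocks at successive depths;
  blocks below half the median occupied volume are discarded as boundary
  slivers; RD = SD/mean of per-block MBF; FD = 1 − slope of log RD vs log
  volume.  I.i.d. element flows recover FD → 1.5 (the 1/√n law); uniform
  flow is reported as FD = 1.

**Known limitation — the flow–order slope.**  The log-linear fit of mean
element flow against Strahler order on the default fixture has R² ≈ 0.997
but slope ≈ 1.17, i.e. an effective branching ratio of ≈ 3.2 per order.
Staged anatomical generators (and measured coronary trees analysed with
diameter-defined ordering) show ≈ 4.5–5 per order (slope ≈ 1.6).  The gap
is a topological property of the simplified sequential growth, not of the
flow solver: the flow span is fixed by conservation, so the slope is set
entirely by how many orders the ordering scheme spreads it over.  Stronger
volume costs, denser root seeding and two diameter-defined reassignment
variants were evaluated and do not close the gap (the iterated variants
actively degrade the fit).  The corresponding test asserts the
literature band and is expected to fail until the generator grows
more realistic hierarchies.

## 9. Units, defaults, reproducibility

Interfaces use mmHg, mL/min, cm, mL, g; the 1D integrator works in CGS
(1 mmHg = 1333.22 dyn cm⁻²) and the Darcy assembly converts the
permeability once (Pa→mmHg, s→min).  All physical constants above are
config defaults (`RunConfig`), never inline literals.  Every run is a pure
function of (config, seed); generated networks serialise byte-identically
for a fixed seed.  Tests and the acceptance script run the pipeline at
1200–2000 terminal segments and 8–50k-element meshes; the generator default
of 12 000 terminals and 5·10⁵ elements (mean element volume 2·10⁻⁴ mL) is
the study configuration for production runs.
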