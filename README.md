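# coroperf

Coupled simulation of coronary blood flow and left-ventricle (LV)
myocardial perfusion.

Clinical models of coronary artery disease usually stop at the epicardial
vessels visible in a CT angiogram: the effect of a stenosis on vessel flow
can be computed (FFR), but its consequence for the *tissue* cannot.
`coroperf` bridges that gap for researchers in computational physiology: it
solves steady blood flow on a hybrid arterial network — centerline-resolved
epicardial vessels extended by a synthetic forest of thousands of
arteriole-scale vessels — and couples it, two ways, to a porous-medium
model of LV perfusion.  The output is myocardial blood flow (MBF) at
clinically meaningful resolutions, FFR along the vessels, bull's-eye
perfusion maps, and network statistics (Strahler flow laws, fractal flow
heterogeneity).  Patient imaging is replaced by a built-in synthetic
geometry generator, so every experiment is fully reproducible from a seed.

## The model

**Coronary side.**  Steady 1D momentum balance along each centerline
coordinate z,

    d/dz(α Q²/S) + (S/ρ) dp/dz + 8πν Q/S = 0,      dQ/dz = 0,

with blood density ρ = 1.06 g cm⁻³, viscosity μ = 0.053 g cm⁻¹ s⁻¹, and
momentum-correction coefficient α = 4/3, reduced in area-increasing regions
to limit pressure recovery.  Constant-radius synthetic vessels collapse to
Poiseuille resistors.  Aortic pressure P_AO = 93 mmHg is imposed at the two
ostia; terminal flows are imposed at the outlets.

**Outflow physiology.**  Total resting LV flow follows the allometric law
Q = ζ V_LV^γ (ζ = 3.41 mL^0.25 min⁻¹, γ = 0.75); terminal flows split as
r^2.7.  Non-LV outlets carry an extra 20%.  Hyperemia quadruples the ideal
flows, dilates all synthetic vessels by up to 40% in diameter, and limits
each outlet so its implied microvascular resistance never falls below a
quarter of its resting value — the achieved stress/rest ratio therefore
lands below 4, limited by the network.

**Myocardium side.**  Single-compartment Darcy model,
w = −K∇p, ∇·w = β_src(p_src − p) − β_snk(p − p_snk), with K = 2·10⁻⁵
cm² Pa⁻¹ s⁻¹, solved with P1 tetrahedral finite elements and no-flux walls.
Conductances are set from the total flow so the mean capillary pressure is
15 mmHg.  Tissue is apportioned to outlets by a Laguerre (power-distance)
tessellation weighted by terminal diameters.

**Coupling.**  Outlet pressures become territory source pressures; Darcy
territory inflows become new outlet flows; a relaxed fixed point iterates
until outlet flows are stationary.

## Worked example

```python
from coroperf import CoronaryPerfusionModel, RunConfig
from coroperf.io import FixtureConfig

cfg = RunConfig(fixture=FixtureConfig(n_term=2000, target_elements=20000), seed=0)
model = CoronaryPerfusionModel.from_config(cfg)   # generate geometry
results = model.fit()                             # both regimes, coupled
print(results.summary())
```

prints

```
Coronary–myocardium perfusion model
================================================
V_LV                 :     100.6 mL
terminal segments    :      1993
LV outlets (coupled) :      1992
Q_rest LV ideal      :     108.3 mL/min
Q_rest non-LV ideal  :      21.7 mL/min
------------------------------------------------
[rest] achieved total :     129.9 mL/min
[rest] mean drop      :      9.70 mmHg
[rest] max dilation   :       0.0 %
[rest] coupling       : converged in 6 it (residual 5.27e-04)
[rest] MBF_AHA        :   1.02 ±  0.01 (0.99–1.04) mL/min/g
------------------------------------------------
[hyperemia] achieved total :     438.1 mL/min
[hyperemia] mean drop      :     22.16 mmHg
[hyperemia] max dilation   :      40.0 %
[hyperemia] coupling       : converged in 9 it (residual 5.97e-04)
[hyperemia] MBF_AHA        :   3.33 ±  0.06 (3.24–3.46) mL/min/g
------------------------------------------------
achieved hyperemia/rest flow ratio: 3.37
```

Reading this: a 100.6 mL ventricle receives 108 mL/min at rest (about
1 mL min⁻¹ g⁻¹ of tissue, the textbook resting perfusion), plus 20% through
non-LV branches.  Under pharmacological stress the network delivers 3.37×
the resting flow — short of the ideal factor 4 because the tree's own
resistance is non-negligible — and the mean root-to-outlet pressure drop
roughly doubles while flow more than triples, the signature of synthetic
vasodilation.  Coupled MBF at the AHA-segment scale is tightly homogeneous
(SD 0.01–0.06 mL min⁻¹ g⁻¹), unlike the stand-alone coronary model.

Derived quantities hang off the same results object:

```python
results.ffr()                       # min FFR per epicardial tree (hyperemia)
results.mbf("hyperemia", "coupled") # multi-resolution MBF report
results.strahler("rest")            # per-order flow statistics + log-law fit
results.fractal("rest", "coupled")  # relative-dispersion fractal analysis
results.perfusion_map().to_png("map.png")
```

Adding `stenosis=StenosisConfig()` to the fixture places an 80% diameter
narrowing in the LAD: its distal FFR falls to ~0.3 (< 0.8, a positive
test), the diseased tree dilates at rest while the healthy ones do not,
and the hyperemic perfusion map shows a contiguous anterior deficit.

A command-line driver wraps the same pipeline:

```
coroperf generate   --config run.yaml --out out/   # geometry (JSON + VTU)
coroperf run-coupled --config run.yaml --out out/  # both regimes + reports
coroperf postprocess --config run.yaml --out out/  # FFR, maps, fractal
coroperf report      --config run.yaml --out out/  # model-comparison table
```

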