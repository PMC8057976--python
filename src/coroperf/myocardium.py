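"""Single-compartment Darcy perfusion model of the LV myocardium.

The myocardium is treated as a porous medium: Darcy velocity
``w = -K grad(p)`` with a mass balance carrying distributed source terms
(arterial inflow through the coronary outlets) and sink terms (venous
drainage),

    div(w) = beta_source * (p_source - p) - beta_sink * (p - p_sink).

Substituting the momentum law gives one Poisson-type equation for the
capillary pressure p, discretised here with P1 (linear) tetrahedral finite
elements and a no-flux condition on the myocardial wall.  Conductances
``beta_source``/``beta_sink`` are spatially constant and estimated from the
total flow, the mean source pressure, and the targeted mean capillary
pressure (15 mmHg); the source pressure field is piecewise constant over the
perfusion territories obtained from a discrete Laguerre (power-distance)
tessellation weighted by terminal-segment diameters.

Units: geometry in cm, volumes in mL, pressures in mmHg, flows in mL/min.
The permeability is supplied in cm^2 Pa^-1 s^-1 (literature convention) and
converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import ParameterError

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322


class SolverError(RuntimeError):
    """Raised when the sparse linear solve fails."""


@dataclass
class MyocardiumMesh:
    """Tetrahedral LV-wall mesh.

    Attributes
    ----------
    nodes : (N, 3) float array, cm
    tets : (M, 4) int array
    wall_tags : dict mapping tag name -> (F, 3) boundary face array
    long_axis : unit vector from apex towards base (for AHA decomposition)
    apex, base_center : reference points on the long axis, cm
    """

    nodes: np.ndarray
    tets: np.ndarray
    wall_tags: dict = field(default_factory=dict)
    long_axis: np.ndarray | None = None
    apex: np.ndarray | None = None
    base_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=int)
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ParameterError("mesh contains non-positive-volume elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        """Element volumes in mL (= cm^3)."""
        x = self.nodes[self.tets]
        a = x[:, 1] - x[:, 0]
        b = x[:, 2] - x[:, 0]
        c = x[:, 3] - x[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    @property
    def V_LV(self) -> float:
        return float(self.element_volumes().sum())

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tet (the wall surface)."""
        faces = np.vstack(
            [
                self.tets[:, [0, 1, 2]],
                self.tets[:, [0, 1, 3]],
                self.tets[:, [0, 2, 3]],
                self.tets[:, [1, 2, 3]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]


@dataclass
class DarcyParams:
    """Parameters of the single-compartment porous model."""

    K: float = 2e-5  # permeability, cm^2 Pa^-1 s^-1 (isotropic)
    beta_source: float | None = None  # mL min^-1 mL^-1 mmHg^-1
    beta_sink: float | None = None
    p_sink: float = 0.0  # venous reference pressure, mmHg
    p_bar: float = 15.0  # targeted mean capillary pressure, mmHg

    @property
    def K_internal(self) -> float:
        """Permeability in cm^2 mmHg^-1 min^-1."""
        return self.K * PA_PER_MMHG * 60.0


@dataclass
class PerfusionTerritory:
    """Per-element assignment of myocardial tissue to terminal outlets."""

    labels: np.ndarray  # (M,) index into the outlet list
    outlet_ids: np.ndarray  # network leaf ids, parallel to label values
    volumes: np.ndarray  # (n_outlets,) territory volumes, mL

    @property
    def n_territories(self) -> int:
        return len(self.outlet_ids)


@dataclass
class DarcyField:
    """Converged Darcy solution."""

    pressure: np.ndarray  # (N,) nodal capillary pressure, mmHg
    velocity: np.ndarray  # (M, 3) elementwise Darcy velocity, cm/min
    territory_inflow: np.ndarray  # (n_outlets,) Q_j, mL/min
    element_inflow: np.ndarray  # (M,) per-element source inflow, mL/min
    mean_pressure: float  # volume-weighted mean of p, mmHg
    sink_outflow: float  # total venous drainage, mL/min


def laguerre_territories(
    mesh: MyocardiumMesh,
    outlet_positions: np.ndarray,
    outlet_diameters: np.ndarray,
    outlet_ids: np.ndarray | None = None,
    weight_scale: float = 8.0,
    chunk: int = 4096,
) -> PerfusionTerritory:
    """Discrete Laguerre (power-distance) tessellation of the mesh.

    Each tetrahedron is assigned to the outlet minimising
    ``|x_c - s_i|^2 - (weight_scale * d_i)^2`` over its centroid ``x_c``,
    so larger-caliber outlets claim larger territories.  The default weight
    scale makes the diameter weights comparable to the inter-outlet spacing
    of a dense forest; with small weights the tessellation degenerates to an
    unweighted Voronoi partition and outlet caliber stops influencing
    territory size.  Power cells of heavily dominated outlets can be empty.
    """
    pos = np.atleast_2d(np.asarray(outlet_positions, dtype=float))
    dia = np.asarray(outlet_diameters, dtype=float)
    if len(pos) == 0:
        raise ParameterError("territory assignment requires >= 1 outlet")
    if len(dia) != len(pos):
        raise ParameterError("outlet diameters/positions length mismatch")
    cent = mesh.centroids()
    w2 = (weight_scale * dia) ** 2
    labels = np.empty(len(cent), dtype=int)
    for lo in range(0, len(cent), chunk):
        hi = min(lo + chunk, len(cent))
        d2 = ((cent[lo:hi, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        labels[lo:hi] = np.argmin(d2 - w2[None, :], axis=1)
    vols = np.bincount(labels, weights=mesh.element_volumes(), minlength=len(pos))
    if outlet_ids is None:
        outlet_ids = np.arange(len(pos))
    return PerfusionTerritory(labels, np.asarray(outlet_ids), vols)


def compute_betas(
    Q_tot: float,
    p_source_mean: float,
    p_bar: float = 15.0,
    p_sink: float = 0.0,
    V_LV: float = 1.0,
) -> tuple[float, float]:
    """Source and sink conductances from the total-flow balance.

    ``beta_source = Q_tot / ((p_source_mean - p_bar) V_LV)`` and
    ``beta_sink = Q_tot / ((p_bar - p_sink) V_LV)``; both scale linearly with
    the total flow, so hyperemia (larger ``Q_tot``) raises the conductances,
    mimicking microvascular recruitment.
    """
    if Q_tot <= 0 or V_LV <= 0:
        raise ParameterError("Q_tot and V_LV must be positive")
    if p_source_mean <= p_bar or p_bar <= p_sink:
        raise ParameterError("requires p_source_mean > p_bar > p_sink")
    beta_source = Q_tot / ((p_source_mean - p_bar) * V_LV)
    beta_sink = Q_tot / ((p_bar - p_sink) * V_LV)
    return beta_source, beta_sink


class _P1Assembly:
    """Cached P1 stiffness/mass assembly for repeated solves on one mesh."""

    def __init__(self, mesh: MyocardiumMesh) -> None:
        self.mesh = mesh
        nodes, tets = mesh.nodes, mesh.tets
        x = nodes[tets]
        vol = mesh.element_volumes()
        # shape-function gradients: rows of the inverse Jacobian construction
        m = np.empty((len(tets), 3, 3))
        m[:, 0] = x[:, 1] - x[:, 0]
        m[:, 1] = x[:, 2] - x[:, 0]
        m[:, 2] = x[:, 3] - x[:, 0]
        minv = np.linalg.inv(m)
        g = np.empty((len(tets), 4, 3))
        g[:, 1:] = minv.transpose(0, 2, 1)
        g[:, 0] = -g[:, 1:].sum(axis=1)
        self.grads = g
        self.vol = vol
        rows = np.repeat(tets, 4, axis=1).reshape(len(tets), 4, 4)
        cols = rows.transpose(0, 2, 1)
        self._rows = rows.ravel()
        self._cols = cols.ravel()
        ke = np.einsum("eid,ejd->eij", g, g) * vol[:, None, None]
        n = mesh.n_nodes
        self.stiffness = sp.csr_matrix(
            (ke.ravel(), (self._rows, self._cols)), shape=(n, n)
        )
        me = (np.ones((4, 4)) + np.eye(4) * 1.0)[None, :, :] * (vol / 20.0)[
            :, None, None
        ]
        self.mass = sp.csr_matrix(
            (me.ravel(), (self._rows, self._cols)), shape=(n, n)
        )
        # lumped load vector weights: V/4 to each node of the element
        self.node_load = sp.csr_matrix(
            (
                np.repeat(vol / 4.0, 4),
                (tets.ravel(), np.repeat(np.arange(len(tets)), 4)),
            ),
            shape=(n, len(tets)),
        )


def solve_darcy(
    mesh: MyocardiumMesh,
    territories: PerfusionTerritory,
    params: DarcyParams,
    p_source: np.ndarray,
    rtol: float = 1e-8,
    assembly: _P1Assembly | None = None,
) -> DarcyField:
    """Solve the Darcy pressure Poisson problem with no-flux walls.

    ``p_source`` gives the source pressure per territory (mmHg).  The weak
    form of  −div(K grad p) + (βs+βk) p = βs p_source(x) + βk p_sink  with
    natural boundary conditions yields a symmetric positive definite sparse
    system, solved by diagonally preconditioned conjugate gradients.
    """
    if params.beta_source is None or params.beta_sink is None:
        raise ParameterError("beta_source/beta_sink must be set (compute_betas)")
    bs, bk = params.beta_source, params.beta_sink
    if bs <= 0 or bk <= 0:
        raise ParameterError("conductances must be positive")
    p_source = np.asarray(p_source, dtype=float)
    if len(p_source) != territories.n_territories:
        raise ParameterError("p_source length must match number of territories")
    asm = assembly if assembly is not None else _P1Assembly(mesh)
    A = params.K_internal * asm.stiffness + (bs + bk) * asm.mass
    ps_elem = p_source[territories.labels]
    rhs = asm.node_load @ (bs * ps_elem + bk * params.p_sink * np.ones(mesh.n_elements))
    d = A.diagonal()
    M = sp.diags(1.0 / d)
    p, info = spla.cg(A, rhs, rtol=rtol, atol=0.0, M=M, maxiter=20000)
    if info != 0:
        p = spla.spsolve(A.tocsc(), rhs)
        if not np.all(np.isfinite(p)):
            raise SolverError(f"Darcy solve failed (cg info={info})")
    vol = asm.vol
    p_elem = p[mesh.tets].mean(axis=1)
    elem_inflow = bs * (ps_elem - p_elem) * vol
    territory_inflow = np.bincount(
        territories.labels, weights=elem_inflow, minlength=territories.n_territories
    )
    sink_outflow = float(np.sum(bk * (p_elem - params.p_sink) * vol))
    grad_p = np.einsum("eid,ei->ed", asm.grads, p[mesh.tets])
    velocity = -params.K_internal * grad_p
    mean_p = float(np.sum(p_elem * vol) / vol.sum())
    return DarcyField(
        pressure=p,
        velocity=velocity,
        territory_inflow=territory_inflow,
        element_inflow=elem_inflow,
        mean_pressure=mean_p,
        sink_outflow=sink_outflow,
    )
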