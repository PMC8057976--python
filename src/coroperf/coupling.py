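"""Two-way fixed-point coupling of the coronary and myocardium models.

The two models exchange quantities at the terminal-segment outlets: the
coronary model hands each outlet pressure to its perfusion territory as the
Darcy source pressure; the Darcy model hands back the territory inflow as
the new outlet-flow boundary condition.  A Gauss–Seidel loop with
under-relaxation iterates this exchange until the outlet flows stop
changing; the source/sink conductances are re-estimated each iteration from
the (fixed) regime total flow and the current mean source pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coronary
from .myocardium import (
    DarcyField,
    DarcyParams,
    MyocardiumMesh,
    PerfusionTerritory,
    _P1Assembly,
    compute_betas,
    solve_darcy,
)
from .network import ParameterError, VascularNetwork
from .regimes import RegimeState


class CouplingError(RuntimeError):
    """Raised when the coupling loop exceeds its iteration budget."""


@dataclass
class CouplingConfig:
    relaxation: float = 0.5
    tol: float = 1e-3  # max relative outlet-flow change
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxation <= 1.0:
            raise ParameterError("relaxation factor must lie in (0, 1]")
        if self.tol <= 0:
            raise ParameterError("tolerance must be positive")


@dataclass
class CoupledSolution:
    """Converged coupled state for one regime."""

    state: coronary.HemodynamicState
    darcy: DarcyField
    territories: PerfusionTerritory
    outlet_flows: dict  # leaf id -> converged flow, mL/min
    residuals: list = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.residuals)


def couple(
    network: VascularNetwork,
    mesh: MyocardiumMesh,
    territories: PerfusionTerritory,
    regime_state: RegimeState,
    config: CouplingConfig | None = None,
    darcy_params: DarcyParams | None = None,
    P_AO: float = 93.0,
    fluid: coronary.FluidProperties | None = None,
) -> CoupledSolution:
    """Run the coronary <-> Darcy fixed-point loop for one regime.

    ``territories.outlet_ids`` selects the coupled (LV) outlets; flows of
    all other outlets stay at their regime values.  The regime's achieved
    total flow is held fixed for conductance estimation throughout.
    """
    config = config or CouplingConfig()
    base = darcy_params or DarcyParams()
    outlets = [int(i) for i in territories.outlet_ids]
    q = np.array([regime_state.achieved[i] for i in outlets], dtype=float)
    Q_tot = float(q.sum())
    if Q_tot <= 0:
        raise ParameterError("regime total flow must be positive")
    V_LV = mesh.V_LV
    fixed = {
        i: qv for i, qv in regime_state.achieved.items() if i not in set(outlets)
    }
    assembly = _P1Assembly(mesh)
    residuals: list[float] = []
    converged = False
    state = None
    darcy = None
    # outlets whose power cell is empty receive no myocardial territory and
    # therefore no flow from the Darcy model: their fixed point is the flow
    # floor, set directly instead of being approached geometrically
    floor = 1e-12 * Q_tot
    empty = territories.volumes <= 0
    q = np.maximum(q, floor)
    q[empty] = floor
    q_bar = Q_tot / max(len(q), 1)
    # per-outlet Aitken relaxation, initialised at the configured factor:
    # outlets downstream of a severe stenosis flip between positive inflow
    # and the floor under fixed relaxation, which a secant update damps out
    omega = np.full(len(q), config.relaxation)
    r_prev = None
    for _ in range(config.max_iterations):
        flows = dict(zip(outlets, q)) | fixed
        state = coronary.solve(network, flows, P_AO, regime_state.regime, fluid)
        p_src = state.outlet_pressure(outlets)
        bs, bk = compute_betas(Q_tot, float(np.mean(p_src)), base.p_bar, base.p_sink, V_LV)
        params = DarcyParams(
            K=base.K, beta_source=bs, beta_sink=bk, p_sink=base.p_sink, p_bar=base.p_bar
        )
        darcy = solve_darcy(mesh, territories, params, p_src, assembly=assembly)
        target = np.maximum(darcy.territory_inflow, floor)
        target[empty] = floor
        r = target - q
        if r_prev is not None:
            dr = r - r_prev
            upd = np.abs(dr) > 1e-14
            omega[upd] = np.clip(-omega[upd] * r_prev[upd] / dr[upd], 0.02, 1.0)
        q_new = q + omega * r
        # relative change; degenerate near-zero flows are measured against a
        # small fraction of the mean outlet flow
        resid = float(np.max(np.abs(q_new - q) / np.maximum(q, 1e-3 * q_bar)))
        residuals.append(resid)
        q, r_prev = q_new, r
        if resid < config.tol:
            converged = True
            break
    if not converged:
        raise CouplingError(
            f"coupling did not converge in {config.max_iterations} iterations "
            f"(last residual {residuals[-1]:.3e})"
        )
    flows = dict(zip(outlets, q)) | fixed
    state = coronary.solve(network, flows, P_AO, regime_state.regime, fluid)
    return CoupledSolution(
        state=state,
        darcy=darcy,
        territories=territories,
        outlet_flows={i: float(v) for i, v in zip(outlets, q)},
        residuals=residuals,
        converged=converged,
    )
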