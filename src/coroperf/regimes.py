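"""Rest and hyperemia parameterization of the coronary outflow.

Total resting LV flow follows the allometric law Q = zeta * V_LV^gamma
(zeta = 3.41 mL^0.25 min^-1, gamma = 0.75); terminal flows split in
proportion to terminal radius^2.7.  Outlets not perfusing the LV receive an
extra 20% of the LV total, split by the same law.  Ideal hyperemic flows
are four times resting flows (total coronary resistance falls to a quarter
under maximal vasodilation), with achieved flows limited by the network:

* resting adaptation: baseline flows are held at their ideal values; if a
  tree produces excessive pressure loss (outlet pressure below a perfusion
  floor, i.e. implied microvascular resistance below its ideal minimum),
  its synthetic segments are dilated in 1% increments up to the 40% cap;
* hyperemic adaptation: all synthetic trees are dilated to the 40% cap, the
  per-outlet microvascular resistance floor is a quarter of its resting
  value, and a relaxed fixed-point iteration limits each outlet flow so the
  implied microvascular resistance never falls below that floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coronary
from .network import ParameterError, VascularNetwork


class AdaptationError(RuntimeError):
    """Raised when an adaptation loop fails to converge."""


@dataclass
class PerfusionParams:
    """Flow-allocation constants (defaults are the model's standard values)."""

    zeta: float = 3.41  # mL^0.25 min^-1
    gamma: float = 0.75
    split_exponent: float = 2.7
    non_lv_fraction: float = 0.2
    hyperemia_factor: float = 4.0
    dilation_cap: float = 0.40
    dilation_increment: float = 0.01
    p_ref: float = 15.0  # target capillary pressure, mmHg
    p_floor: float = 60.0  # minimal resting outlet pressure, mmHg


@dataclass
class RegimeState:
    """Converged boundary-condition state for one physiological regime."""

    regime: str
    ideal: dict  # leaf id -> ideal terminal flow, mL/min
    achieved: dict  # leaf id -> achieved terminal flow, mL/min
    outlet_pressure: dict  # leaf id -> p^{T,i}, mmHg
    dilation: dict  # synthetic-tree stub id -> fraction
    state: coronary.HemodynamicState
    iterations: int = 0

    @property
    def total_achieved(self) -> float:
        return float(sum(self.achieved.values()))

    @property
    def total_ideal(self) -> float:
        return float(sum(self.ideal.values()))

    def microvascular_resistance(self, p_ref: float = 15.0) -> dict:
        """Implied downstream resistance (p^T - p_ref)/q per outlet."""
        out = {}
        for i, q in self.achieved.items():
            if q > 0:
                out[i] = (self.outlet_pressure[i] - p_ref) / q
        return out


def total_resting_flow(V_LV: float, params: PerfusionParams | None = None) -> float:
    """Total resting LV flow, mL/min, from the myocardial volume in mL."""
    params = params or PerfusionParams()
    if V_LV <= 0:
        raise ParameterError("V_LV must be positive")
    return params.zeta * V_LV**params.gamma


def split_terminal_flows(
    radii: np.ndarray, Q_tot: float, exponent: float = 2.7
) -> np.ndarray:
    """Split a total flow over outlets in proportion to radius^exponent."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ParameterError("empty outlet set")
    if np.any(radii <= 0) or Q_tot <= 0:
        raise ParameterError("radii and Q_tot must be positive")
    w = radii**exponent
    return Q_tot * w / w.sum()


def ideal_rest_flows(
    network: VascularNetwork,
    V_LV: float,
    params: PerfusionParams | None = None,
) -> tuple[dict, float, float]:
    """Ideal resting terminal flows for every outlet of the network.

    Returns (flows, Q_rest_LV_tot, Q_rest_nonLV_tot).  LV outlets share the
    allometric total; non-LV outlets share the extra 20%.  Outlets that lost
    their synthetic tree to trimming keep a zero flow.
    """
    params = params or PerfusionParams()
    Q_lv = total_resting_flow(V_LV, params)
    flows: dict[int, float] = {}
    lv = network.lv_leaves()
    non_lv = network.non_lv_leaves()
    dead_lv = [i for i in lv if network.segments[i].kind == "segmented"]
    live_lv = [i for i in lv if network.segments[i].kind == "synthetic"]
    if not live_lv:
        raise ParameterError("no LV-perfusing outlets in network")
    q_lv = split_terminal_flows(
        network.outlet_radii(live_lv), Q_lv, params.split_exponent
    )
    flows.update(dict(zip(live_lv, q_lv)))
    flows.update({i: 0.0 for i in dead_lv})
    Q_non = params.non_lv_fraction * Q_lv
    if non_lv:
        q_non = split_terminal_flows(
            network.outlet_radii(non_lv), Q_non, params.split_exponent
        )
        flows.update(dict(zip(non_lv, q_non)))
    else:
        Q_non = 0.0
    return flows, Q_lv, Q_non


def non_lv_flows(
    network: VascularNetwork,
    Q_rest_LV_tot: float,
    params: PerfusionParams | None = None,
) -> dict:
    """Resting flows of outlets not perfusing the LV (20% of the LV total)."""
    params = params or PerfusionParams()
    non_lv = network.non_lv_leaves()
    if not non_lv:
        return {}
    q = split_terminal_flows(
        network.outlet_radii(non_lv),
        params.non_lv_fraction * Q_rest_LV_tot,
        params.split_exponent,
    )
    return dict(zip(non_lv, q))


def resting_adaptation(
    network: VascularNetwork,
    ideal_q: dict,
    P_AO: float = 93.0,
    params: PerfusionParams | None = None,
    fluid: coronary.FluidProperties | None = None,
) -> tuple[VascularNetwork, RegimeState]:
    """Dilate synthetic trees until resting outlet pressures are adequate.

    Resting flows are always held at their ideal values; dilation is the
    only degree of freedom.  A tree is dilated (in ``dilation_increment``
    steps, up to the cap) while any of its outlets sits below ``p_floor``,
    which is equivalent to its implied microvascular resistance falling
    below the minimum (p_floor - p_ref)/q.
    """
    params = params or PerfusionParams()
    net = network.copy()
    tree_of = net.synthetic_tree_of()
    max_iter = int(np.ceil(params.dilation_cap / params.dilation_increment)) + 2
    state = None
    for it in range(max_iter):
        state = coronary.solve(net, ideal_q, P_AO, "rest", fluid)
        frac = net.dilation_fractions()
        to_dilate: dict[int, float] = {}
        for i in net.leaves():
            q = ideal_q.get(i, 0.0)
            if q <= 0:
                continue
            if state.p_out[i] < params.p_floor:
                stub = int(tree_of[i]) if tree_of[i] >= 0 else -1
                if stub < 0:
                    continue
                f = frac[stub]
                if f < params.dilation_cap - 1e-12:
                    to_dilate[stub] = min(
                        params.dilation_cap, f + params.dilation_increment
                    )
        if not to_dilate:
            break
        net.dilate({**frac, **to_dilate}, cap=params.dilation_cap)
    else:
        state = coronary.solve(net, ideal_q, P_AO, "rest", fluid)
    leaves = net.leaves()
    return net, RegimeState(
        regime="rest",
        ideal=dict(ideal_q),
        achieved=dict(ideal_q),
        outlet_pressure={i: float(state.p_out[i]) for i in leaves},
        dilation=net.dilation_fractions(),
        state=state,
        iterations=it + 1,
    )


def hyperemic_adaptation(
    network_rest: VascularNetwork,
    rest: RegimeState,
    P_AO: float = 93.0,
    params: PerfusionParams | None = None,
    fluid: coronary.FluidProperties | None = None,
    relax: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 800,
) -> tuple[VascularNetwork, RegimeState]:
    """Hyperemic regime: full dilation, then flow limitation.

    All synthetic trees are set to the 40% dilation cap.  Ideal flows are
    four times resting; each outlet's flow is limited so that its implied
    microvascular resistance stays above a quarter of the resting value,
    via an under-relaxed fixed point on the outlet flows.
    """
    params = params or PerfusionParams()
    net = network_rest.copy()
    net.dilate(params.dilation_cap, cap=params.dilation_cap)
    ideal = {i: params.hyperemia_factor * q for i, q in rest.achieved.items()}
    R_rest = rest.microvascular_resistance(params.p_ref)
    # outlets whose rest pressure already sits below p_ref (possible behind a
    # severe stenosis, where ideal rest flows are imposed regardless) have no
    # meaningful implied resistance; they are limited by the perfusion-
    # pressure cap below instead of a resistance floor
    R_floor = {
        i: R / params.hyperemia_factor for i, R in R_rest.items() if R > 0
    }
    ids = [i for i, v in ideal.items() if v > 0]
    idl = np.array([ideal[i] for i in ids])
    q_arr = idl.copy()
    rf = np.array([R_floor.get(i, np.inf) for i in ids])
    fixed = {i: v for i, v in ideal.items() if v <= 0}
    state = None
    # per-outlet Aitken relaxation: a focal stenosis couples many downstream
    # outlets into one stiff collective constraint, for which a fixed global
    # under-relaxation factor either diverges or crawls
    omega = np.full(len(ids), relax)
    r_prev = None
    resid = np.inf
    for it in range(max_iter):
        state = coronary.solve(net, dict(zip(ids, q_arr)) | fixed, P_AO, "hyperemia", fluid)
        p = np.array([state.p_out[i] for i in ids])
        target = np.minimum(idl, (p - params.p_ref) / rf)
        # perfusion-pressure cap: flow into the microvasculature needs
        # p_out >= p_ref; scale towards the flow that (for a drop linear
        # in q) would bring the outlet back to p_ref
        low = p < params.p_ref
        cap = q_arr * np.maximum(
            0.05, (P_AO - params.p_ref) / np.maximum(P_AO - p, 1e-9)
        )
        target = np.where(low, np.minimum(target, cap), target)
        target = np.maximum(target, 1e-9 * idl)
        r = target - q_arr
        if r_prev is not None:
            dr = r - r_prev
            upd = np.abs(dr) > 1e-14
            omega[upd] = np.clip(-omega[upd] * r_prev[upd] / dr[upd], 0.02, 1.0)
        q_next = q_arr + omega * r
        # changes scaled by the ideal flow: collapsed outlets chattering
        # around the tiny-flow floor must not dominate the residual
        resid = float(np.max(np.abs(q_next - q_arr) / idl))
        q_arr, r_prev = q_next, r
        if resid < tol:
            break
    else:
        raise AdaptationError(
            f"hyperemic flow limitation did not converge (residual {resid:.2e})"
        )
    q = dict(zip(ids, (float(v) for v in q_arr))) | fixed
    state = coronary.solve(net, q, P_AO, "hyperemia", fluid)
    leaves = net.leaves()
    return net, RegimeState(
        regime="hyperemia",
        ideal=ideal,
        achieved=q,
        outlet_pressure={i: float(state.p_out[i]) for i in leaves},
        dilation=net.dilation_fractions(),
        state=state,
        iterations=it + 1,
    )


def coronary_resistance_share(regime_state: RegimeState, P_AO: float = 93.0) -> float:
    """Coronary-tree share of total (tree + microvascular) resistance.

    The tree resistance is [P_AO - mean(p^T)] / sum(q); the system total is
    referenced to the venous pressure (0 mmHg), so the share reduces to the
    mean fractional pressure drop across the tree.
    """
    leaves = [i for i, qv in regime_state.achieved.items() if qv > 0]
    p_mean = float(np.mean([regime_state.outlet_pressure[i] for i in leaves]))
    return (P_AO - p_mean) / P_AO
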