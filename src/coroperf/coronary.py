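"""Steady 1D / 0D hemodynamics on the hybrid coronary network.

Segmented (centerline-resolved) vessels use the steady one-dimensional
momentum balance along the centerline coordinate z,

    d/dz(alpha Q^2 / S) + (S/rho) dp/dz + 8 pi nu Q / S = 0,

with Q constant per segment (steady mass balance).  The momentum-flux
correction alpha is 4/3 for a parabolic profile; in area-increasing regions
it is scaled down (regime-dependent factors, different inside and outside
bifurcating regions) so that the model does not predict full pressure
recovery downstream of expansions.  alpha is treated as a local
coefficient: the marching form integrated on the 0.01 cm node grid is

    dp/dz = rho * (alpha Q^2 S' / S^3  -  8 pi nu Q / S^2),

which reduces exactly to Poiseuille for constant S.  Synthetic vessels have
constant S and collapse to 0D Poiseuille resistors.

Flows are solved leaf-to-root by subtree summation of the imposed terminal
flows; pressures root-to-leaf with pressure continuity at junctions.

External units: mL/min, mmHg, cm.  Internal integration is CGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    CenterlineSegment,
    ParameterError,
    VascularNetwork,
)

MMHG_TO_DYN = 1333.22  # dyn cm^-2 per mmHg
MLMIN_TO_CGS = 1.0 / 60.0  # cm^3 s^-1 per mL min^-1


@dataclass
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    rho: float = 1.06  # g cm^-3
    mu: float = 0.053  # g cm^-1 s^-1

    @property
    def nu(self) -> float:
        """Kinematic viscosity, cm^2 s^-1."""
        return self.mu / self.rho


#: regime-dependent scale factors applied to alpha = 4/3 at area-increasing
#: nodes, keyed by (regime, inside_bifurcating_region)
ALPHA_MULTIPLIERS = {
    ("rest", True): 0.29,
    ("rest", False): 0.34,
    ("hyperemia", True): 0.72,
    ("hyperemia", False): 0.36,
}


@dataclass
class AlphaRule:
    """Momentum-correction coefficient rule."""

    base: float = 4.0 / 3.0
    regime: str = "rest"
    multipliers: dict = field(default_factory=lambda: dict(ALPHA_MULTIPLIERS))
    bifurcation_extent_radii: float = 1.0  # extent of the junction region

    def factor(self, in_bifurcation: bool) -> float:
        return self.multipliers[(self.regime, bool(in_bifurcation))]


def alpha_profile(
    segment: CenterlineSegment,
    rule: AlphaRule,
    junction_at_start: bool = True,
    junction_at_end: bool = True,
) -> np.ndarray:
    """Per-node alpha values for a segmented vessel.

    Nodes where the area increases downstream get the regime- and
    location-dependent reduced alpha; all other nodes keep the base value.
    A node is "in a bifurcating region" when its arc-length distance to an
    adjacent junction is below ``bifurcation_extent_radii`` local radii.
    """
    S = segment.areas
    n = len(S)
    increasing = np.zeros(n, dtype=bool)
    increasing[:-1] = np.diff(S) > 0
    increasing[-1] = increasing[-2] if n > 1 else False

    z = segment.spacing * np.arange(n)
    in_bif = np.zeros(n, dtype=bool)
    if junction_at_start:
        r0 = np.sqrt(S[0] / np.pi)
        in_bif |= z <= rule.bifurcation_extent_radii * r0
    if junction_at_end:
        r1 = np.sqrt(S[-1] / np.pi)
        in_bif |= (z[-1] - z) <= rule.bifurcation_extent_radii * r1

    alpha = np.full(n, rule.base)
    inc_in = increasing & in_bif
    inc_out = increasing & ~in_bif
    alpha[inc_in] = rule.base * rule.factor(True)
    alpha[inc_out] = rule.base * rule.factor(False)
    return alpha


def segment_pressure_profile(
    segment: CenterlineSegment,
    Q: float,
    alpha: np.ndarray,
    fluid: FluidProperties,
    p_in: float,
) -> np.ndarray:
    """Pressure along a segmented vessel by trapezoidal marching.

    ``Q`` in mL/min, ``p_in`` (inlet pressure) in mmHg; returns nodal
    pressures in mmHg.  For constant S and alpha the integral reduces to the
    Poiseuille drop 8 mu L Q / (pi r^4).
    """
    S = segment.areas
    if not np.all(np.isfinite(S)):
        raise ParameterError("non-finite areas in segment")
    q = Q * MLMIN_TO_CGS
    h = segment.spacing
    Sp = np.gradient(S, h)
    f = fluid.rho * (alpha * q**2 * Sp / S**3 - 8.0 * np.pi * fluid.nu * q / S**2)
    dp = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * h)])
    return p_in + dp / MMHG_TO_DYN


def poiseuille_drop(radius: float, length: float, Q: float, fluid: FluidProperties) -> float:
    """Poiseuille pressure drop in mmHg for Q in mL/min."""
    q = Q * MLMIN_TO_CGS
    return 8.0 * fluid.mu * length * q / (np.pi * radius**4) / MMHG_TO_DYN


@dataclass
class HemodynamicState:
    """Solved steady flow/pressure state on a network."""

    Q: np.ndarray  # per-segment flow, mL/min
    p_in: np.ndarray  # per-segment inlet pressure, mmHg
    p_out: np.ndarray  # per-segment outlet pressure, mmHg
    node_pressures: dict  # segment id -> nodal pressures (segmented only)
    P_AO: float
    regime: str
    terminal_flows: dict  # leaf id -> imposed flow, mL/min

    def outlet_pressure(self, leaf_ids) -> np.ndarray:
        return np.array([self.p_out[i] for i in leaf_ids])

    def mean_outlet_drop(self, leaf_ids=None, weights: np.ndarray | None = None) -> float:
        """Mean aortic-root-to-outlet pressure drop, mmHg."""
        if leaf_ids is None:
            raise ParameterError("leaf ids required")
        drops = self.P_AO - self.outlet_pressure(leaf_ids)
        if weights is None:
            return float(np.mean(drops))
        return float(np.average(drops, weights=weights))


def solve_flows(network: VascularNetwork, terminal_flows: dict[int, float]) -> np.ndarray:
    """Per-segment flow from imposed terminal flows (subtree summation)."""
    leaves = network.leaves()
    missing = [i for i in leaves if i not in terminal_flows]
    if missing:
        raise ParameterError(f"missing terminal flows for leaves {missing[:5]}...")
    Q = np.zeros(len(network.segments))
    for i in leaves:
        Q[i] = terminal_flows[i]
    for i in reversed(network.topological_order()):
        p = network.parent[i]
        if p >= 0:
            Q[p] += Q[i]
    return Q


def solve_pressures(
    network: VascularNetwork,
    Q: np.ndarray,
    P_AO: float = 93.0,
    regime: str = "rest",
    fluid: FluidProperties | None = None,
    alpha_rule: AlphaRule | None = None,
) -> HemodynamicState:
    """March pressures from the ostia to the terminals.

    Root inlet pressure is the mean aortic pressure ``P_AO``; pressure is
    continuous across junctions.  Segmented vessels use the 1D profile,
    synthetic vessels the Poiseuille drop at their current (dilated) radius.
    """
    fluid = fluid or FluidProperties()
    rule = alpha_rule or AlphaRule(regime=regime)
    if rule.regime != regime:
        rule = AlphaRule(
            base=rule.base,
            regime=regime,
            multipliers=rule.multipliers,
            bifurcation_extent_radii=rule.bifurcation_extent_radii,
        )
    n = len(network.segments)
    p_in = np.zeros(n)
    p_out = np.zeros(n)
    node_pressures: dict[int, np.ndarray] = {}
    for i in network.topological_order():
        p = network.parent[i]
        p_in[i] = P_AO if p < 0 else p_out[p]
        seg = network.segments[i]
        if seg.kind == "segmented":
            alpha = alpha_profile(
                seg,
                rule,
                junction_at_start=p >= 0,
                junction_at_end=bool(network.children[i]),
            )
            prof = segment_pressure_profile(seg, float(Q[i]), alpha, fluid, p_in[i])
            node_pressures[i] = prof
            p_out[i] = prof[-1]
        else:
            p_out[i] = p_in[i] - poiseuille_drop(seg.radius, seg.length, float(Q[i]), fluid)
    leaves = network.leaves()
    return HemodynamicState(
        Q=Q,
        p_in=p_in,
        p_out=p_out,
        node_pressures=node_pressures,
        P_AO=P_AO,
        regime=regime,
        terminal_flows={i: float(Q[i]) for i in leaves},
    )


def solve(
    network: VascularNetwork,
    terminal_flows: dict[int, float],
    P_AO: float = 93.0,
    regime: str = "rest",
    fluid: FluidProperties | None = None,
    alpha_rule: AlphaRule | None = None,
) -> HemodynamicState:
    """Convenience: flows then pressures."""
    Q = solve_flows(network, terminal_flows)
    return solve_pressures(network, Q, P_AO, regime, fluid, alpha_rule)
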