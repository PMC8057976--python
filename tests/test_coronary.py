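"""1D/0D hemodynamic solver: flows, alpha rules, pressure profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_binary_tree, make_chain, make_random_tree, make_segmented
from coroperf import coronary
from coroperf.coronary import (
    MMHG_TO_DYN,
    AlphaRule,
    FluidProperties,
    alpha_profile,
    poiseuille_drop,
    segment_pressure_profile,
    solve_flows,
    solve_pressures,
)
from coroperf.network import (
    CenterlineSegment,
    ParameterError,
    SyntheticSegment,
    VascularNetwork,
)


class TestSolveFlows:
    def test_single_segment(self):
        net = make_chain([1.0])
        Q = solve_flows(net, {0: 1.0})
        assert Q[0] == 1.0

    def test_binary_tree_conservation(self):
        net = make_binary_tree(depth=1)
        leaves = net.leaves()
        Q = solve_flows(net, {leaves[0]: 1.0, leaves[1]: 2.0})
        assert Q[0] == pytest.approx(3.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_subtree_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_tree(rng, int(rng.integers(2, 60)))
        flows = {i: float(rng.uniform(0.1, 2.0)) for i in net.leaves()}
        Q = solve_flows(net, flows)

        def subtree_sum(i):
            if not net.children[i]:
                return flows[i]
            return sum(subtree_sum(c) for c in net.children[i])

        for i in range(len(net.segments)):
            assert Q[i] == pytest.approx(subtree_sum(i), rel=1e-12)

    def test_missing_terminal_flow_rejected(self):
        net = make_binary_tree(depth=1)
        with pytest.raises(ParameterError):
            solve_flows(net, {net.leaves()[0]: 1.0})


class TestAlphaProfile:
    def test_constant_area_is_base_everywhere(self):
        seg = make_segmented(r0=0.1, r1=0.1)
        alpha = alpha_profile(seg, AlphaRule(regime="rest"))
        assert np.allclose(alpha, 4.0 / 3.0)

    def test_expansion_outside_bifurcation_rest(self):
        seg = make_segmented(n_nodes=401, r0=0.05, r1=0.1)  # expanding
        alpha = alpha_profile(
            seg, AlphaRule(regime="rest"), junction_at_start=False, junction_at_end=False
        )
        assert alpha[200] == pytest.approx(4.0 / 3.0 * 0.34)

    def test_expansion_inside_bifurcation_hyperemia(self):
        seg = make_segmented(n_nodes=401, r0=0.05, r1=0.1)
        alpha = alpha_profile(
            seg, AlphaRule(regime="hyperemia"), junction_at_start=True
        )
        assert alpha[0] == pytest.approx(4.0 / 3.0 * 0.72)

    def test_table_multipliers(self):
        rule_r = AlphaRule(regime="rest")
        rule_h = AlphaRule(regime="hyperemia")
        assert rule_r.factor(True) == 0.29
        assert rule_r.factor(False) == 0.34
        assert rule_h.factor(True) == 0.72
        assert rule_h.factor(False) == 0.36


class TestPressureProfile:
    def test_constant_area_reduces_to_poiseuille(self):
        # r = 0.05 cm, L = 1 cm, Q = 1 mL/min, mu = 0.053:
        # dp = 8 mu L Q / (pi r^4) ~ 360 dyn/cm^2 ~ 0.27 mmHg
        seg = make_segmented(n_nodes=101, r0=0.05, r1=0.05)
        fluid = FluidProperties()
        alpha = np.full(101, 4.0 / 3.0)
        prof = segment_pressure_profile(seg, 1.0, alpha, fluid, 93.0)
        drop = 93.0 - prof[-1]
        expect = 8 * 0.053 * 1.0 * (1.0 / 60.0) / (np.pi * 0.05**4) / MMHG_TO_DYN
        assert expect == pytest.approx(0.27, abs=0.005)
        assert drop == pytest.approx(expect, rel=1e-9)
        assert drop == pytest.approx(poiseuille_drop(0.05, 1.0, 1.0, fluid), rel=1e-9)

    def test_zero_flow_gives_flat_profile(self):
        seg = make_segmented()
        prof = segment_pressure_profile(
            seg, 0.0, np.full(seg.n_nodes, 4 / 3), FluidProperties(), 93.0
        )
        assert np.allclose(prof, 93.0)

    def test_expanding_cone_matches_fine_grid_quadrature(self):
        # gently expanding cone, fixed alpha: independent quadrature of
        # dp/dz = rho (alpha Q^2 S'/S^3 - 8 pi nu Q/S^2) on a 10x finer grid
        n = 201
        z = np.arange(n) * 0.01
        r = 0.05 + 0.01 * z / z[-1]
        seg = CenterlineSegment(
            np.column_stack([z, np.zeros(n), np.zeros(n)]), np.pi * r**2
        )
        fluid = FluidProperties()
        Q = 2.0
        prof = segment_pressure_profile(seg, Q, np.full(n, 4 / 3), fluid, 93.0)
        # oracle: dense quadrature with the analytic cone area
        zf = np.linspace(0, z[-1], 20 * n)
        rf = 0.05 + 0.01 * zf / z[-1]
        Sf = np.pi * rf**2
        Spf = np.gradient(Sf, zf)
        q = Q / 60.0
        f = fluid.rho * (
            (4 / 3) * q**2 * Spf / Sf**3 - 8 * np.pi * fluid.nu * q / Sf**2
        )
        drop_oracle = -np.trapezoid(f, zf) / MMHG_TO_DYN
        drop = 93.0 - prof[-1]
        assert drop == pytest.approx(drop_oracle, rel=1e-3)

    def test_nonfinite_area_rejected(self):
        seg = make_segmented(n_nodes=11)
        seg.areas[4] = np.nan
        with pytest.raises(ParameterError):
            segment_pressure_profile(
                seg, 1.0, np.full(11, 4 / 3), FluidProperties(), 93.0
            )


class TestSolvePressures:
    def test_zero_flows_keep_aortic_pressure(self):
        net = make_binary_tree(depth=2)
        Q = np.zeros(len(net.segments))
        state = solve_pressures(net, Q, P_AO=93.0)
        assert np.allclose(state.p_out, 93.0)

    def test_symmetric_branches_have_equal_outlet_pressures(self):
        segs = [
            SyntheticSegment([0, 0, 0], [1, 0, 0], 0.08),
            SyntheticSegment([1, 0, 0], [2, 1, 0], 0.05),
            SyntheticSegment([1, 0, 0], [2, -1, 0], 0.05),
        ]
        net = VascularNetwork(segs, [-1, 0, 0])
        state = coronary.solve(net, {1: 1.5, 2: 1.5})
        assert state.p_out[1] == pytest.approx(state.p_out[2], rel=1e-14)

    def test_total_inflow_equals_terminal_sum(self, fitted):
        state = fitted.regimes["rest"].state
        net = fitted.networks["rest"]
        inflow = sum(state.Q[i] for i in net.roots)
        outflow = sum(state.Q[i] for i in net.leaves())
        assert inflow == pytest.approx(outflow, rel=1e-12)

    def test_doubling_flows_doubles_drops_on_synthetic_network(self):
        net = make_binary_tree(depth=3)
        leaves = net.leaves()
        q1 = {i: 0.5 for i in leaves}
        q2 = {i: 1.0 for i in leaves}
        s1 = coronary.solve(net, q1)
        s2 = coronary.solve(net, q2)
        d1 = 93.0 - s1.p_out
        d2 = 93.0 - s2.p_out
        assert np.allclose(d2, 2 * d1, rtol=1e-12)

    def test_pressure_nonincreasing_along_paths(self, fitted):
        # down every root-to-terminal path the pressure never rises across
        # a segment (healthy fixture: no expansions, positive flows)
        net = fitted.networks["hyperemia"]
        state = fitted.regimes["hyperemia"].state
        for i in range(len(net.segments)):
            assert state.p_out[i] <= state.p_in[i] + 1e-9

    def test_pressure_decreasing_across_strahler_orders(self, fitted):
        # element-level check echoing the per-order pressure ordering
        net = fitted.networks["rest"]
        state = fitted.regimes["rest"].state
        orders = net.strahler_order()
        for leaf in net.leaves()[::25]:
            path = list(reversed(net.path_to_root(leaf)))
            last_p = np.inf
            last_o = None
            for i in path:
                if last_o is not None and orders[i] < last_o:
                    assert state.p_out[i] <= last_p + 1e-9
                last_o = orders[i]
                last_p = state.p_out[i]
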