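"""Network structure: Strahler ordering, elements, trimming, dilation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_binary_tree, make_chain, make_random_tree
from coroperf.network import (
    ParameterError,
    SyntheticSegment,
    TopologyError,
    VascularNetwork,
)


def brute_strahler(net):
    """Independent recursive Strahler oracle (order 1 at the leaves)."""

    def order(i):
        ch = net.children[i]
        if not ch:
            return 1
        sub = sorted((order(c) for c in ch), reverse=True)
        if len(sub) >= 2 and sub[0] == sub[1]:
            return sub[0] + 1
        return sub[0]

    return np.array([order(i) for i in range(len(net.segments))])


class TestStrahler:
    def test_single_segment_gets_base_offset(self):
        net = make_chain([1.0])
        assert net.strahler_order(base_offset=5)[0] == 5

    def test_perfect_binary_tree_root_order(self):
        net = make_binary_tree(depth=3)
        orders = net.strahler_order(base_offset=5, diameter_refine=False)
        assert orders[0] == 5 + 3
        leaves = net.leaves()
        assert all(orders[i] == 5 for i in leaves)

    def test_caterpillar_root_order(self):
        # each junction: one leaf + one continuing branch -> root = base + 1
        segs = [SyntheticSegment([0, 0, 0], [1, 0, 0], 0.05)]
        parent = [-1]
        for k in range(5):
            x = k + 1.0
            segs.append(SyntheticSegment([x, 0, 0], [x + 1, 0, 0], 0.05))
            parent.append(len(segs) - 2 if k == 0 else len(segs) - 3)
            segs.append(SyntheticSegment([x, 0, 0], [x, 1, 0], 0.05))
            parent.append(parent[-1])
        net = VascularNetwork(segs, parent)
        orders = net.strahler_order(base_offset=5, diameter_refine=False)
        assert orders[0] == 6

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 50))
    def test_matches_brute_force_oracle(self, seed, n):
        net = make_random_tree(np.random.default_rng(seed), n)
        got = net.strahler_order(base_offset=1, diameter_refine=False)
        assert np.array_equal(got, brute_strahler(net))

    def test_order_never_decreases_towards_root(self):
        net = make_random_tree(np.random.default_rng(7), 40)
        orders = net.strahler_order()
        for i in range(len(net.segments)):
            p = net.parent[i]
            if p >= 0:
                assert orders[p] >= orders[i]

    def test_cycle_raises_topology_error(self):
        segs = [
            SyntheticSegment([0, 0, 0], [1, 0, 0], 0.05),
            SyntheticSegment([1, 0, 0], [2, 0, 0], 0.05),
        ]
        with pytest.raises(TopologyError):
            VascularNetwork(segs, [1, 0])


class TestElements:
    def test_single_segment_is_one_element(self):
        net = make_chain([1.0])
        els = net.decompose_elements(net.strahler_order())
        assert len(els) == 1

    def test_binary_tree_has_no_chains(self):
        net = make_binary_tree(depth=2)
        orders = net.strahler_order(diameter_refine=False)
        els = net.decompose_elements(orders)
        assert len(net.segments) == 7
        assert len(els) == 7

    def test_same_order_chain_merges(self):
        net = make_chain([1.0, 1.0, 1.0])
        els = net.decompose_elements(net.strahler_order())
        assert len(els) == 1
        assert sorted(els[0].segment_ids) == [0, 1, 2]

    def test_every_segment_in_exactly_one_element(self):
        net = make_random_tree(np.random.default_rng(3), 45)
        els = net.decompose_elements(net.strahler_order())
        seen = sorted(i for e in els for i in e.segment_ids)
        assert seen == list(range(len(net.segments)))


class TestTrimming:
    def _forest(self, fractions):
        """One synthetic tree per fraction hanging off separate roots."""
        segs, parent = [], []
        for k, _ in enumerate(fractions):
            segs.append(SyntheticSegment([k, 0, 0], [k, 1, 0], 0.05))
            parent.append(-1)
            segs.append(SyntheticSegment([k, 1, 0], [k, 2, 0], 0.03))
            parent.append(2 * k)
        net = VascularNetwork(segs, parent)
        ach = {2 * k: f for k, f in enumerate(fractions)}
        tgt = {2 * k: 1.0 for k in range(len(fractions))}
        return net, ach, tgt

    def test_under_threshold_trees_removed(self):
        net, ach, tgt = self._forest([0.05, 0.10, 0.15])
        assert len(net.trim_undergrown(ach, tgt).segments) == 0

    def test_exact_threshold_retained(self):
        net, ach, tgt = self._forest([0.20, 0.05])
        out = net.trim_undergrown(ach, tgt)
        assert len(out.segments) == 2

    def test_empty_forest(self):
        net = VascularNetwork([], [])
        assert len(net.trim_undergrown({}, {}).segments) == 0

    def test_idempotent(self):
        net, ach, tgt = self._forest([0.5, 0.1, 0.3])
        once = net.trim_undergrown(ach, tgt)
        # surviving trees keep their flows; re-trimming changes nothing
        ach2 = {0: 0.5, 2: 0.3}
        tgt2 = {0: 1.0, 2: 1.0}
        twice = once.trim_undergrown(ach2, tgt2)
        assert len(once.segments) == len(twice.segments)

    def test_nonpositive_target_rejected(self):
        net, ach, tgt = self._forest([0.5])
        tgt[0] = 0.0
        with pytest.raises(ParameterError):
            net.trim_undergrown(ach, tgt)


class TestDilation:
    def test_zero_fraction_is_identity(self):
        net = make_binary_tree(depth=2)
        before = [s.radius for s in net.segments]
        net.dilate(0.0)
        assert [s.radius for s in net.segments] == before

    def test_full_dilation_diameter_ratio(self):
        net = make_binary_tree(depth=2)
        r0 = [s.r0 for s in net.segments]
        net.dilate(0.40)
        ratios = [s.radius / r for s, r in zip(net.segments, r0)]
        assert np.allclose(ratios, 1.40)

    def test_poiseuille_resistance_ratio(self):
        # resistance ~ r^-4, so full dilation scales it by 1.4^-4
        net = make_chain([1.0])
        r_before = net.segments[0].radius
        net.dilate(0.40)
        ratio = (r_before / net.segments[0].radius) ** 4
        assert ratio == pytest.approx(1.4**-4, rel=1e-12)

    def test_over_cap_clipped_with_warning(self):
        net = make_chain([1.0])
        with pytest.warns(UserWarning):
            net.dilate(0.55)
        assert net.segments[0].dilation == pytest.approx(0.40)

    def test_geometry_topology_and_lengths_preserved(self):
        net = make_binary_tree(depth=3)
        lengths = [s.length for s in net.segments]
        parent = net.parent.copy()
        net.dilate(0.3)
        assert np.array_equal(net.parent, parent)
        assert np.allclose([s.length for s in net.segments], lengths)

    def test_non_dilatable_segments_untouched(self):
        segs = [
            SyntheticSegment([0, 0, 0], [1, 0, 0], 0.05, dilatable=False),
            SyntheticSegment([1, 0, 0], [2, 0, 0], 0.03),
        ]
        net = VascularNetwork(segs, [-1, 0])
        net.dilate(0.40)
        assert segs[0].dilation == 0.0
        assert segs[1].dilation == pytest.approx(0.40)
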