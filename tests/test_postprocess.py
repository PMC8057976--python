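"""Derived quantities: FFR, MBF levels, AHA-17, maps, Strahler, fractal."""

import numpy as np
import pytest

from conftest import make_chain
from coroperf.fixtures import LVShellSpec, make_lv_mesh
from coroperf.network import ParameterError
from coroperf.postprocess import (
    FFR_THRESHOLD,
    aha17,
    ffr,
    ffr_positive,
    fractal_analysis,
    mbf_report,
    perfusion_map,
    strahler_stats,
)


@pytest.fixture(scope="module")
def mesh():
    return make_lv_mesh(LVShellSpec(target_elements=10_000))


class TestFFR:
    def test_root_node_is_unity(self):
        assert ffr(np.array([93.0]), 93.0)[0] == 1.0

    def test_boundary_value_is_negative(self):
        # 74.4 / 93 = 0.8 exactly: not *below* the threshold -> negative
        v = ffr(np.array([74.4]), 93.0)[0]
        assert v == pytest.approx(FFR_THRESHOLD)
        assert not ffr_positive(v + 1e-12)

    def test_strictly_below_is_positive(self):
        assert ffr_positive(0.79)

    def test_nonpositive_aortic_pressure_rejected(self):
        with pytest.raises(ParameterError):
            ffr(np.array([80.0]), 0.0)

    def test_in_unit_interval_with_unity_at_ostia(self, fitted):
        for reg in ("rest", "hyperemia"):
            st = fitted.regimes[reg].state
            net = fitted.networks[reg]
            vals = st.p_out / st.P_AO
            assert np.all(vals > 0)
            assert np.all(vals <= 1.0 + 1e-12)
            for r in net.roots:
                assert st.p_in[r] / st.P_AO == pytest.approx(1.0)

    def test_stenosed_lad_positive_others_negative(self, fitted_stenosis):
        by_tree = fitted_stenosis.ffr("hyperemia", "coupled")
        assert by_tree["LAD"] < 0.8
        assert by_tree["LCX"] > 0.8
        assert by_tree["RCA"] > 0.8


class TestMBF:
    def test_whole_myocardium_definition(self, mesh):
        vols = mesh.element_volumes()
        flows = vols / vols.sum() * 100.0  # 100 mL/min total
        rep = mbf_report(mesh, flows, density=1.0)
        # 100 mL/min over ~100 g -> ~1 mL/min/g
        assert rep["myo"].mean == pytest.approx(100.0 / mesh.V_LV, rel=1e-12)

    def test_uniform_field_has_zero_sd_at_all_levels(self, mesh):
        vols = mesh.element_volumes()
        flows = 2.0 * vols
        rep = mbf_report(mesh, flows, aha_labels=aha17(mesh))
        for lev in rep.levels.values():
            assert lev.sd == pytest.approx(0.0, abs=1e-10)
            assert lev.mean == pytest.approx(2.0 / rep.density, rel=1e-9)

    def test_mean_invariant_and_sd_grows_with_resolution(self, fitted):
        for which in ("coronary", "coupled"):
            rep = fitted.mbf("rest", which)
            means = [rep[k].mean for k in ("myo", "trees", "AHA", "voxels")]
            assert max(means) - min(means) < 0.01 * means[0]
            sds = [rep[k].sd for k in ("myo", "trees", "AHA", "voxels")]
            assert sds == sorted(sds)

    def test_hyperemia_rest_ratio_equal_across_levels(self, fitted):
        rep_r = fitted.mbf("rest", "coupled")
        rep_h = fitted.mbf("hyperemia", "coupled")
        ratios = [
            rep_h[k].mean / rep_r[k].mean for k in ("myo", "trees", "AHA", "voxels")
        ]
        assert max(ratios) / min(ratios) < 1.02
        assert 2.5 < ratios[0] < 3.5


class TestAHA17:
    def test_labels_partition_into_seventeen(self, mesh):
        labels = aha17(mesh)
        assert set(np.unique(labels)) == set(range(1, 18))

    def test_basal_segments_equal_volumes(self, mesh):
        labels = aha17(mesh)
        vols = mesh.element_volumes()
        basal = [vols[labels == k].sum() for k in range(1, 7)]
        assert max(basal) / min(basal) < 1.1  # rotational symmetry

    def test_segment_volume_scale(self, mesh):
        # AHA segments are ~6 mL order of magnitude on a ~100 mL ventricle
        labels = aha17(mesh)
        vols = mesh.element_volumes()
        seg_vols = [vols[labels == k].sum() for k in range(1, 17)]
        assert 2.0 < np.mean(seg_vols) < 12.0


class TestPerfusionMap:
    def test_uniform_field_gives_uniform_map(self, mesh):
        m = perfusion_map(mesh, np.full(mesh.n_elements, 1.5))
        vals = m.values[np.isfinite(m.values)]
        assert np.allclose(vals, 1.5)

    def test_cell_volume_near_pet_resolution(self, mesh):
        m = perfusion_map(mesh, np.ones(mesh.n_elements))
        occupied = m.cell_volumes[m.cell_volumes > 0]
        assert np.median(occupied) == pytest.approx(6.4e-2, rel=1.0)

    def test_map_mean_conserves_global_mbf(self, fitted):
        rep = fitted.mbf("hyperemia", "coupled")
        m = fitted.perfusion_map("hyperemia", "coupled")
        assert m.mean() == pytest.approx(rep["myo"].mean, rel=0.02)

    def test_stenosis_map_shows_contiguous_deficit(self, fitted_stenosis):
        vols = fitted_stenosis.mesh.element_volumes()
        flows = fitted_stenosis.element_flows("hyperemia", "coupled")
        mbf = flows / (1.05 * vols)
        labels = fitted_stenosis.tree_element_labels()
        lad = labels == "LAD"
        mean_lad = np.average(mbf[lad], weights=vols[lad])
        mean_rest = np.average(mbf[~lad], weights=vols[~lad])
        assert mean_lad < 0.75 * mean_rest


class TestStrahlerStats:
    def test_self_similar_tree_slope_is_closed_form(self):
        # perfect binary tree with equal terminal flows: every element of
        # order k carries exactly 2^(k-1) q, so the fitted slope is ln 2
        from conftest import make_binary_tree
        from coroperf import coronary

        net = make_binary_tree(depth=4)
        q = {i: 1.0 for i in net.leaves()}
        state = coronary.solve(net, q)
        orders = net.strahler_order(base_offset=1, diameter_refine=False)
        stats = strahler_stats(net, state.Q, state, orders)
        assert stats.slope == pytest.approx(np.log(2.0), rel=1e-9)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_order_network_has_no_fit(self):
        net = make_chain([1.0, 1.0])
        from coroperf import coronary

        state = coronary.solve(net, {1: 1.0})
        orders = np.full(2, 5)
        with pytest.raises(ParameterError):
            strahler_stats(net, state.Q, state, orders)

    def test_fixture_log_linearity(self, fitted):
        stats = fitted.strahler("rest")
        assert stats.r2 > 0.95
        assert stats.slope > 0


class TestFractal:
    def test_iid_flows_follow_inverse_sqrt_law(self, mesh):
        rng = np.random.default_rng(0)
        vols = mesh.element_volumes()
        flows = rng.gamma(2.0, 1.0, size=len(vols)) * vols
        res = fractal_analysis(mesh, flows)
        assert res.slope == pytest.approx(-0.5, abs=0.1)
        assert res.fd == pytest.approx(1.5, abs=0.1)

    def test_uniform_flow_is_scale_free(self, mesh):
        flows = 1.7 * mesh.element_volumes()
        res = fractal_analysis(mesh, flows)
        assert res.fd == pytest.approx(1.0)

    def test_zero_flow_rejected(self, mesh):
        with pytest.raises(ParameterError):
            fractal_analysis(mesh, np.zeros(mesh.n_elements))

    def test_coupled_model_closer_to_uniform_than_standalone(self, fitted):
        fd_c = fitted.fractal("rest", "coupled").fd
        fd_s = fitted.fractal("rest", "coronary").fd
        assert fd_c < fd_s
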