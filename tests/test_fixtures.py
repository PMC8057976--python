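"""Synthetic geometry generator: shell mesh, epicardial trees, growth."""

import json

import numpy as np
import pytest

from conftest import TEST_N_TERM
from coroperf.fixtures import (
    EpicardialTreeSpec,
    GeometryError,
    GrowthConfig,
    LVShell,
    LVShellSpec,
    Root,
    RootSeedConfig,
    StenosisSpec,
    default_fixture,
    grow_forest,
    make_epicardial_trees,
    make_lv_mesh,
    seed_roots,
)
from coroperf.network import ParameterError


class TestLVMesh:
    def test_volume_matches_analytic_shell(self, shell, small_mesh):
        # (3.5,3.5,7)/(2.5,2.5,6) half-ellipsoid shell truncated at equator
        assert shell.analytic_volume == pytest.approx(
            2 * np.pi / 3 * (3.5 * 3.5 * 7 - 2.5 * 2.5 * 6)
        )
        err = abs(small_mesh.V_LV - shell.analytic_volume) / shell.analytic_volume
        assert err < 0.02

    def test_degenerate_axes_rejected(self):
        with pytest.raises(GeometryError):
            LVShellSpec(endo_axes=(3.5, 3.5, 7.0), epi_axes=(3.5, 3.5, 7.0))

    def test_element_count_and_mean_volume(self):
        # the organ-scale mesh: element count ~ target, so mean element
        # volume ~ V/target (2e-4 mL at the full 5e5-element resolution)
        spec = LVShellSpec(target_elements=30_000)
        mesh = make_lv_mesh(spec)
        assert abs(mesh.n_elements - 30_000) / 30_000 < 0.15
        mean_vol = mesh.V_LV / mesh.n_elements
        expect = LVShell(spec).analytic_volume / 30_000
        assert mean_vol == pytest.approx(expect, rel=0.2)

    def test_watertight_boundary(self, small_mesh):
        faces = small_mesh.boundary_faces()
        assert len(faces) > 0
        # every boundary edge is shared by exactly two boundary faces
        edges = np.vstack(
            [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)


class TestEpicardialTrees:
    def test_node_spacing_and_taper(self, shell):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        for seg in net.segments:
            assert seg.spacing == pytest.approx(0.01)
            assert np.all(np.diff(seg.areas) <= 1e-12)  # monotone taper

    def test_stenosis_minimum_area(self, shell):
        st = StenosisSpec(vessel="LAD", reduction=0.8)
        spec = EpicardialTreeSpec(stenosis=st)
        net = make_epicardial_trees(spec, shell)
        healthy = make_epicardial_trees(EpicardialTreeSpec(), shell)
        lad = next(s for s in net.segments if s.name == "LAD")
        lad_h = next(s for s in healthy.segments if s.name == "LAD")
        k = int(np.argmin(lad.areas))
        # area = pi (d/2)^2 -> 80% diameter reduction leaves 4% of the area
        assert lad.areas[k] == pytest.approx(0.2**2 * lad_h.areas[k], rel=1e-6)

    def test_zero_length_path_rejected(self, shell):
        spec = EpicardialTreeSpec(
            paths={"LM": [np.zeros(3), np.zeros(3)]},
            radii={"LM": (0.2, 0.18)},
        )
        with pytest.raises(GeometryError):
            make_epicardial_trees(spec, shell)

    def test_invalid_stenosis_reduction(self):
        with pytest.raises(GeometryError):
            StenosisSpec(reduction=0.99)


class TestSeedRoots:
    def test_interval_larger_than_tree_gives_outlets_only(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        _, roots = seed_roots(net, small_mesh, RootSeedConfig(side_interval=100.0))
        assert all(r.kind == "outlet" for r in roots)
        assert len(roots) == 3  # LAD, LCX, RCA distal tips

    def test_root_count_is_outlets_plus_side_roots(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        _, roots = seed_roots(net, small_mesh)
        n_out = sum(1 for r in roots if r.kind == "outlet")
        n_side = sum(1 for r in roots if r.kind == "side")
        assert n_out == 3
        assert len(roots) == n_out + n_side

    def test_proximal_rca_roots_flagged_non_lv(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        _, roots = seed_roots(net, small_mesh)
        non_lv = [r for r in roots if not r.lv]
        assert len(non_lv) >= 1
        # the far-from-wall roots sit on the elevated proximal RCA course
        assert all(r.position[2] > 0 for r in non_lv)

    def test_flow_stays_piecewise_constant_after_splitting(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        seeded, roots = seed_roots(net, small_mesh)
        # each split piece is a valid centerline vessel with >= 2 nodes
        assert all(s.n_nodes >= 2 for s in seeded.segments)
        assert len(seeded.segments) > len(net.segments)


class TestGrowForest:
    def test_terminal_count_exact(self, fitted):
        assert fitted.model.fixture is not None
        # before trimming the forest has exactly the requested terminals
        net, ach, tgt = (
            fitted.model.fixture.network,
            fitted.model.fixture.achieved,
            fitted.model.fixture.target,
        )
        trimmed_terms = TEST_N_TERM - net.n_term
        assert 0 <= trimmed_terms < 0.02 * TEST_N_TERM

    def test_stub_only_forest_when_target_equals_roots(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        seeded, roots = seed_roots(net, small_mesh)
        n_roots = len(roots)
        cfg = GrowthConfig(n_term=n_roots, seed=0)
        grown, _, _ = grow_forest(seeded, roots, shell, cfg)
        assert grown.n_term == n_roots

    def test_target_below_root_count_rejected(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        seeded, roots = seed_roots(net, small_mesh)
        with pytest.raises(ParameterError):
            grow_forest(seeded, roots, shell, GrowthConfig(n_term=2, seed=0))

    def test_identical_competing_roots_split_evenly(self, shell, small_mesh):
        net = make_epicardial_trees(EpicardialTreeSpec(), shell)
        seeded, _ = seed_roots(net, small_mesh, RootSeedConfig(side_interval=100.0))
        pos1 = shell.surface_point(np.radians(60), 0.3)
        pos2 = shell.surface_point(np.radians(240), 0.3)
        counts = np.zeros((10, 2))
        for s in range(10):
            roots = [
                Root(pos1, 0.05, 0, kind="outlet", tangent=np.array([0.0, 0, -1])),
                Root(pos2, 0.05, 0, kind="outlet", tangent=np.array([0.0, 0, -1])),
            ]
            cfg = GrowthConfig(n_term=200, seed=s, stem_length=0.0)
            grown, ach, tgt = grow_forest(seeded, roots, shell, cfg)
            counts[s] = [round(v * 200) for v in ach.values()]
        means = counts.mean(axis=0)
        assert abs(means[0] - means[1]) / means.mean() < 0.2

    def test_reproducible_from_seed(self, shell, small_mesh):
        nets = []
        for _ in range(2):
            fx = default_fixture(n_term=300, target_elements=8000, seed=11)
            nets.append(json.dumps(fx.network.to_dict(), sort_keys=True))
        assert nets[0] == nets[1]

    def test_generated_vessels_stay_in_wall_region(self, fitted):
        shell = fitted.model.fixture.shell
        net = fitted.networks["rest"]
        pts = []
        for s in net.segments:
            if s.kind == "synthetic" and s.dilatable:
                pts.append(0.5 * (s.start + s.end))
        inside = shell.inside(np.array(pts), margin=0.15)
        assert inside.mean() > 0.999

    def test_terminal_radii_span_an_order_of_magnitude(self, fitted):
        net = fitted.networks["rest"]
        rr = net.outlet_radii()
        assert rr.max() / rr.min() >= 10.0
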