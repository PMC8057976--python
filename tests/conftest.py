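"""Shared fixtures: geometry, networks, and fitted models.

Session-scoped fitted models are reused across test modules; the study
conditions (terminal counts, mesh sizes) are scaled-down versions of the
generator defaults so the whole suite stays fast while exercising the full
pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from coroperf.fixtures import LVShell, LVShellSpec, make_lv_mesh
from coroperf.io import FixtureConfig, RunConfig, StenosisConfig
from coroperf.model import CoronaryPerfusionModel
from coroperf.network import (
    CenterlineSegment,
    SyntheticSegment,
    VascularNetwork,
)

TEST_N_TERM = 2000
TEST_MESH = 15000


@pytest.fixture(scope="session")
def shell_spec():
    return LVShellSpec(target_elements=8000)


@pytest.fixture(scope="session")
def shell(shell_spec):
    return LVShell(shell_spec)


@pytest.fixture(scope="session")
def small_mesh(shell_spec):
    return make_lv_mesh(shell_spec)


@pytest.fixture(scope="session")
def fitted():
    """Fully fitted healthy model (rest + hyperemia, coupled)."""
    cfg = RunConfig(
        fixture=FixtureConfig(n_term=TEST_N_TERM, target_elements=TEST_MESH),
        seed=0,
    )
    model = CoronaryPerfusionModel.from_config(cfg)
    return model.fit()


@pytest.fixture(scope="session")
def fitted_stenosis():
    """Fitted model with an 80% diameter LAD stenosis."""
    cfg = RunConfig(
        fixture=FixtureConfig(
            n_term=1000, target_elements=TEST_MESH, stenosis=StenosisConfig()
        ),
        seed=0,
    )
    model = CoronaryPerfusionModel.from_config(cfg)
    return model.fit()


def make_chain(lengths, radius=0.05, lv=True):
    """Linear chain of synthetic segments along +x."""
    segs, parent = [], []
    x = 0.0
    for k, L in enumerate(lengths):
        segs.append(
            SyntheticSegment(np.array([x, 0, 0]), np.array([x + L, 0, 0]), radius)
        )
        parent.append(k - 1)
        x += L
    return VascularNetwork(segs, parent, [lv] * len(segs))


def make_binary_tree(depth, radius=0.05, length=1.0):
    """Perfect binary tree of synthetic segments (2^(depth+1) - 1 segments)."""
    segs = [
        SyntheticSegment(np.array([0.0, 0, 0]), np.array([length, 0, 0]), radius)
    ]
    parent = [-1]
    frontier = [(0, np.array([length, 0.0, 0.0]), 0)]
    for d in range(depth):
        new_frontier = []
        for pid, tip, lane in frontier:
            for s, dy in ((0, 0.5), (1, -0.5)):
                end = tip + np.array([length, dy / (d + 1), 0.0])
                segs.append(SyntheticSegment(tip, end, radius * 0.7 ** (d + 1)))
                parent.append(pid)
                new_frontier.append((len(segs) - 1, end, 2 * lane + s))
        frontier = new_frontier
    return VascularNetwork(segs, parent)


def make_random_tree(rng, n_segments, radius=0.05):
    """Random forest-free tree: each new segment attaches to a random one."""
    segs = [
        SyntheticSegment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), radius)
    ]
    parent = [-1]
    tips = [np.array([1.0, 0.0, 0.0])]
    for k in range(1, n_segments):
        p = int(rng.integers(0, k))
        tip = tips[p]
        end = tip + rng.normal(0, 0.5, 3) + np.array([0.5, 0, 0])
        if np.linalg.norm(end - tip) < 1e-3:
            end = tip + np.array([0.5, 0, 0])
        segs.append(SyntheticSegment(tip, end, radius * rng.uniform(0.3, 1.0)))
        parent.append(p)
        tips.append(end)
    return VascularNetwork(segs, parent)


def make_segmented(n_nodes=101, r0=0.1, r1=0.05, spacing=0.01, name=""):
    """Straight tapering centerline vessel along +x."""
    z = np.arange(n_nodes) * spacing
    pts = np.column_stack([z, np.zeros(n_nodes), np.zeros(n_nodes)])
    r = np.linspace(r0, r1, n_nodes)
    return CenterlineSegment(pts, np.pi * r**2, spacing, name)
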