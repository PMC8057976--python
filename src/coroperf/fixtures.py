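"""Synthetic geometry standing in for patient image data.

Real studies of this kind segment the epicardial coronary arteries and the
left-ventricle (LV) myocardium from cCTA.  Here both are generated:

* an idealized LV wall as a truncated ellipsoid shell, tetrahedralised by a
  structured grid (hex/prism cells split around cell centroids);
* parametric epicardial coronary trees (left main -> LAD/LCX, and RCA)
  as centerline vessels with tapering cross-section and an optional
  stenosis of prescribed diameter reduction;
* synthetic-tree roots at segmented outlets and along vessel sides, with
  roots far from the LV wall flagged as not perfusing the LV;
* a space-filling forest of synthetic vessels grown by sequential
  volume-minimising competitive growth (a simplified constrained
  constructive optimisation), terminating at a prescribed number of
  terminal segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .myocardium import MyocardiumMesh
from .network import (
    CenterlineSegment,
    ParameterError,
    SyntheticSegment,
    VascularNetwork,
)


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate geometric specifications."""


class GrowthError(RuntimeError):
    """Raised when forest growth cannot reach its terminal-count target."""


# ---------------------------------------------------------------------------
# LV shell geometry
# ---------------------------------------------------------------------------


@dataclass
class LVShellSpec:
    """Idealized LV wall: region between two co-centred half ellipsoids.

    Axes in cm; the shell is truncated by the basal plane z = truncation
    height (0 = equatorial plane), apex pointing towards negative z.
    """

    endo_axes: tuple[float, float, float] = (2.5, 2.5, 6.0)
    epi_axes: tuple[float, float, float] = (3.5, 3.5, 7.0)
    truncation_height: float = 0.0
    target_elements: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(e > i for e, i in zip(self.epi_axes, self.endo_axes)):
            raise GeometryError("epicardial axes must exceed endocardial axes")
        if self.truncation_height >= 0.9 * self.endo_axes[2]:
            raise GeometryError("truncation plane too close to the far pole")


class LVShell:
    """Analytic helpers for the truncated ellipsoid shell."""

    def __init__(self, spec: LVShellSpec) -> None:
        self.spec = spec
        self.endo = np.asarray(spec.endo_axes, dtype=float)
        self.epi = np.asarray(spec.epi_axes, dtype=float)
        self.z_top = float(spec.truncation_height)

    @staticmethod
    def _half_volume(axes: np.ndarray, z_top: float) -> float:
        a, b, c = axes
        zt = min(z_top, c)
        return math.pi * a * b * (zt - zt**3 / (3 * c**2) + 2 * c / 3.0)

    @property
    def analytic_volume(self) -> float:
        """Shell volume below the truncation plane, mL."""
        return self._half_volume(self.epi, self.z_top) - self._half_volume(
            self.endo, self.z_top
        )

    def _implicit(self, pts: np.ndarray, axes: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(pts) / axes
        return (q**2).sum(axis=1)

    def inside(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points lie in the wall (relative implicit margin)."""
        pts = np.atleast_2d(pts)
        v_en = self._implicit(pts, self.endo)
        v_ep = self._implicit(pts, self.epi)
        return (
            (v_en >= 1.0 - margin)
            & (v_ep <= 1.0 + margin)
            & (pts[:, 2] <= self.z_top + margin * self.epi[2])
        )

    def sample_inside(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform rejection sampling of n points inside the wall."""
        out = np.empty((0, 3))
        lo = np.array([-self.epi[0], -self.epi[1], -self.epi[2]])
        hi = np.array([self.epi[0], self.epi[1], self.z_top])
        while len(out) < n:
            cand = rng.uniform(lo, hi, size=(4 * n, 3))
            out = np.vstack([out, cand[self.inside(cand)]])
        return out[:n]

    def pull_into_wall(self, p: np.ndarray) -> np.ndarray:
        """Project a point near the shell onto the mid-wall along its ray."""
        mid = 0.5 * (self.endo + self.epi)
        q = np.array(p, dtype=float)
        q[2] = min(q[2], self.z_top - 0.05 * mid[2])
        s = 1.0 / math.sqrt(float(self._implicit(q, mid)[0]))
        return q * s

    def surface_point(self, phi: float, t: float, offset: float = 1.02) -> np.ndarray:
        """Point on the (offset) epicardial surface.

        ``phi`` is the azimuth (radians); ``t`` in [0, 1] runs from the basal
        ring (truncation plane) towards the apex.
        """
        c = self.epi[2]
        th0 = math.acos(min(self.z_top / c, 1.0))
        th = th0 + t * (math.pi - th0 - 0.03)
        a, b = self.epi[0], self.epi[1]
        return offset * np.array(
            [a * math.sin(th) * math.cos(phi), b * math.sin(th) * math.sin(phi), c * math.cos(th)]
        )

    def basal_point(self, phi: float, height: float, offset: float = 1.02) -> np.ndarray:
        """Point above the basal ring (used for ostia / proximal courses)."""
        a, b = self.epi[0], self.epi[1]
        return np.array(
            [offset * a * math.cos(phi), offset * b * math.sin(phi), self.z_top + height]
        )


def make_lv_mesh(spec: LVShellSpec) -> MyocardiumMesh:
    """Structured tetrahedral mesh of the truncated ellipsoid shell.

    The shell is gridded in transmural / meridional / azimuthal directions;
    each hexahedral cell is split into 12 tets around its centroid (8 around
    the prism cells closing the apex), which keeps the mesh conforming and
    watertight without external meshing tools.
    """
    shell = LVShell(spec)
    V = shell.analytic_volume
    M = max(int(spec.target_elements), 200)
    h = (12.0 * V / M) ** (1.0 / 3.0)
    thick = float(np.mean(shell.epi - shell.endo))
    mid = 0.5 * (shell.endo + shell.epi)
    circ = 2 * math.pi * 0.5 * (mid[0] + mid[1])
    merid = 0.5 * math.pi * math.sqrt(0.5 * (mid[0] ** 2 + mid[2] ** 2))
    for _ in range(4):
        n_t = max(2, round(thick / h))
        n_phi = max(8, round(circ / h))
        n_th = max(4, round(merid / h))
        m_actual = n_t * n_phi * (12 * (n_th - 1) + 8)
        h *= (m_actual / M) ** (1.0 / 3.0)
    # fine-tune the azimuthal count to pin the element total near the target
    n_phi = max(8, round(M / (n_t * (12 * (n_th - 1) + 8))))

    # vertices: rings (layer k, ring j, azimuth i) + apex points per layer
    xi = np.linspace(0.0, 1.0, n_t + 1)
    phis = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)
    nodes = []
    ring_id = np.empty((n_t + 1, n_th, n_phi), dtype=int)
    apex_id = np.empty(n_t + 1, dtype=int)
    for k, x in enumerate(xi):
        axes = shell.endo + x * (shell.epi - shell.endo)
        a, b, c = axes
        th0 = math.acos(min(shell.z_top / c, 1.0))
        thetas = th0 + (math.pi - th0) * np.arange(n_th) / n_th
        for j, th in enumerate(thetas):
            st, ct = math.sin(th), math.cos(th)
            for i, ph in enumerate(phis):
                ring_id[k, j, i] = len(nodes)
                nodes.append((a * st * math.cos(ph), b * st * math.sin(ph), c * ct))
        apex_id[k] = len(nodes)
        nodes.append((0.0, 0.0, -c))

    tets: list[tuple[int, int, int, int]] = []

    def _quad_tris(q: tuple[int, int, int, int]):
        # split along the diagonal through the lowest-numbered vertex so the
        # triangulation of shared faces is identical for both cells
        k0 = q.index(min(q))
        a, b, c, d = q[k0], q[(k0 + 1) % 4], q[(k0 + 2) % 4], q[(k0 + 3) % 4]
        return [(a, b, c), (a, c, d)]

    def _add_cell(faces):
        cid = len(nodes)
        pts = np.array([nodes[v] for f in faces for v in f])
        nodes.append(tuple(pts.mean(axis=0)))
        for f in faces:
            if len(f) == 4:
                for t in _quad_tris(f):
                    tets.append((*t, cid))
            else:
                tets.append((*f, cid))

    for k in range(n_t):
        for i in range(n_phi):
            i2 = (i + 1) % n_phi
            for j in range(n_th - 1):
                v000 = ring_id[k, j, i]
                v010 = ring_id[k, j, i2]
                v011 = ring_id[k, j + 1, i2]
                v001 = ring_id[k, j + 1, i]
                v100 = ring_id[k + 1, j, i]
                v110 = ring_id[k + 1, j, i2]
                v111 = ring_id[k + 1, j + 1, i2]
                v101 = ring_id[k + 1, j + 1, i]
                _add_cell(
                    [
                        (v000, v010, v011, v001),
                        (v100, v110, v111, v101),
                        (v000, v010, v110, v100),
                        (v001, v011, v111, v101),
                        (v000, v001, v101, v100),
                        (v010, v011, v111, v110),
                    ]
                )
            # prism closing the apex
            j = n_th - 1
            w00 = ring_id[k, j, i]
            w01 = ring_id[k, j, i2]
            w10 = ring_id[k + 1, j, i]
            w11 = ring_id[k + 1, j, i2]
            a0, a1 = apex_id[k], apex_id[k + 1]
            _add_cell(
                [
                    (w00, w01, a0),
                    (w10, w11, a1),
                    (w00, w01, w11, w10),
                    (w00, a0, a1, w10),
                    (w01, a0, a1, w11),
                ]
            )

    nodes_arr = np.asarray(nodes, dtype=float)
    tets_arr = np.asarray(tets, dtype=int)
    mesh = MyocardiumMesh(
        nodes=nodes_arr,
        tets=tets_arr,
        long_axis=np.array([0.0, 0.0, 1.0]),
        apex=np.array([0.0, 0.0, -shell.epi[2]]),
        base_center=np.array([0.0, 0.0, shell.z_top]),
    )
    mesh.wall_tags["wall"] = mesh.boundary_faces()
    if abs(mesh.V_LV - V) / V > 0.02:
        raise GeometryError(
            f"discretised volume {mesh.V_LV:.1f} mL deviates >2% from analytic {V:.1f} mL"
        )
    return mesh


# ---------------------------------------------------------------------------
# Epicardial (segmented-like) trees
# ---------------------------------------------------------------------------


@dataclass
class StenosisSpec:
    """Focal narrowing: smooth cosine-shaped diameter reduction."""

    vessel: str = "LAD"
    location: float = 0.25  # fraction of vessel arc length
    reduction: float = 0.8  # diameter reduction fraction in (0, 0.95)
    length: float = 0.8  # cm

    def __post_init__(self) -> None:
        if not 0.0 < self.reduction < 0.95:
            raise GeometryError("stenosis reduction must lie in (0, 0.95)")


@dataclass
class EpicardialTreeSpec:
    """Control points and calibers of the three main epicardial vessels.

    ``paths`` maps vessel name to a list of 3D control points; radii taper
    linearly from proximal to distal values along each vessel.
    """

    paths: dict = field(default_factory=dict)
    radii: dict = field(
        default_factory=lambda: {
            "LM": (0.17, 0.15),
            "LAD": (0.14, 0.05),
            "LCX": (0.13, 0.05),
            "RCA": (0.13, 0.05),
        }
    )
    stenosis: StenosisSpec | None = None
    spacing: float = 0.01  # cm, centerline node step
    taper: str = "geometric"  # or "linear"


def default_tree_paths(shell: LVShell) -> dict:
    """Default control points: LM splitting into LAD/LCX, plus the RCA."""
    d = math.radians
    sp, bp = shell.surface_point, shell.basal_point
    return {
        "LM": [bp(d(70), 0.7), bp(d(70), 0.3), sp(d(70), 0.06)],
        # anterior descending course to the apex, wrapping onto the
        # inferior wall (wrap-around LAD)
        "LAD": [
            sp(d(70), 0.06),
            sp(d(62), 0.28),
            sp(d(55), 0.52),
            sp(d(49), 0.75),
            sp(d(45), 0.93),
            sp(d(-95), 0.97),
            sp(d(-115), 0.86),
        ],
        # full lateral course to the inferolateral wall
        "LCX": [
            sp(d(70), 0.06),
            sp(d(104), 0.14),
            sp(d(140), 0.22),
            sp(d(178), 0.30),
            sp(d(214), 0.38),
            sp(d(248), 0.44),
        ],
        # proximal course above the base, then descending to the crux and
        # posterolateral branches
        "RCA": [
            bp(d(-60), 1.2),
            bp(d(-74), 0.9),
            bp(d(-88), 0.6),
            sp(d(-100), 0.12),
            sp(d(-122), 0.28),
            sp(d(-146), 0.42),
            sp(d(-170), 0.52),
            sp(d(-195), 0.58),
        ],
    }


def _resample_path(points: np.ndarray, spacing: float) -> np.ndarray:
    """Arc-length resampling of a control polygon via a cubic spline."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise GeometryError("path needs >= 2 control points")
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seglen <= 1e-12):
        raise GeometryError("zero-length or duplicated control points")
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    spline = CubicSpline(t, points, axis=0)
    dense_t = np.linspace(0, t[-1], max(4 * len(points), int(20 * t[-1])))
    dense = spline(dense_t)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    L = arc[-1]
    n = max(int(round(L / spacing)), 2)
    s_new = np.linspace(0, L, n + 1)
    return np.column_stack(
        [np.interp(s_new, arc, dense[:, k]) for k in range(3)]
    )


def make_epicardial_trees(
    spec: EpicardialTreeSpec, shell: LVShell
) -> VascularNetwork:
    """Build the segmented part of the vasculature from path specs.

    Returns a network of centerline vessels at the configured node spacing:
    two roots (left main and RCA), the left main bifurcating into LAD and
    LCX.  Cross-sectional areas follow the linear diameter taper, modulated
    by the stenosis profile if one is specified.
    """
    paths = spec.paths if spec.paths else default_tree_paths(shell)
    segs = []
    parent = []
    names = []

    def _areas(name: str, pts: np.ndarray) -> np.ndarray:
        n = len(pts)
        r0, r1 = spec.radii[name]
        s = np.linspace(0.0, 1.0, n)
        if spec.taper == "geometric":
            r = r0 * (r1 / r0) ** s
        else:
            r = r0 + (r1 - r0) * s
        if spec.stenosis is not None and spec.stenosis.vessel == name:
            st = spec.stenosis
            L_tot = spec.spacing * (n - 1)
            z = s * L_tot
            z0 = st.location * L_tot
            mask = np.abs(z - z0) < st.length / 2
            f = np.ones(n)
            f[mask] = 1.0 - st.reduction * 0.5 * (
                1 + np.cos(2 * np.pi * (z[mask] - z0) / st.length)
            )
            r = r * f
        return np.pi * r**2

    order = ["LM", "LAD", "LCX", "RCA"]
    idx = {}
    for name in order:
        if name not in paths:
            continue
        pts = _resample_path(np.asarray(paths[name]), spec.spacing)
        seg = CenterlineSegment(pts, _areas(name, pts), spec.spacing, name)
        idx[name] = len(segs)
        segs.append(seg)
        names.append(name)
        if name in ("LAD", "LCX") and "LM" in idx:
            parent.append(idx["LM"])
        else:
            parent.append(-1)
    return VascularNetwork(segs, parent)


# ---------------------------------------------------------------------------
# Root seeding
# ---------------------------------------------------------------------------


@dataclass
class Root:
    """Synthetic-tree root: an attachment site on the segmented network."""

    position: np.ndarray
    radius: float
    parent_segment: int  # id of the segmented segment it branches from
    lv: bool = True
    kind: str = "side"  # "outlet" or "side"
    tangent: np.ndarray | None = None  # local trunk direction at the site


@dataclass
class RootSeedConfig:
    side_interval: float = 1.2  # cm between side roots along a vessel
    side_radius_ratio: float = 0.7  # side-root radius / local vessel radius
    end_margin: float = 0.25  # cm kept free of side roots near segment ends
    lv_distance: float = 0.5  # cm; roots farther from the wall are non-LV


def seed_roots(
    network: VascularNetwork,
    mesh: MyocardiumMesh,
    cfg: RootSeedConfig | None = None,
) -> tuple[VascularNetwork, list[Root]]:
    """Define synthetic-tree roots on the segmented network.

    A root is placed at every segmented outlet, plus side roots at regular
    arc-length intervals along each vessel.  Segmented vessels are split at
    side-root sites so that flow stays piecewise constant between junctions.
    Roots farther than ``lv_distance`` from the LV wall are flagged non-LV.
    """
    cfg = cfg or RootSeedConfig()
    tree = cKDTree(mesh.nodes)

    segs: list[CenterlineSegment] = []
    parent: list[int] = []
    roots: list[Root] = []

    def _local_radius(seg: CenterlineSegment, i: int) -> float:
        return float(np.sqrt(seg.areas[i] / np.pi))

    # split each segmented vessel at the side-root nodes
    old_to_new_tail: dict[int, int] = {}
    for old_id in network.topological_order():
        seg = network.segments[old_id]
        n = seg.n_nodes
        L = seg.length
        cut_idx: list[int] = []
        k = 1
        while k * cfg.side_interval < L - cfg.end_margin:
            i = int(round(k * cfg.side_interval / seg.spacing))
            if cfg.end_margin / seg.spacing < i < n - 1 - cfg.end_margin / seg.spacing:
                cut_idx.append(i)
            k += 1
        bounds = [0] + cut_idx + [n - 1]
        prev = (
            old_to_new_tail[int(network.parent[old_id])]
            if network.parent[old_id] >= 0
            else -1
        )
        for a, b in zip(bounds[:-1], bounds[1:]):
            piece = CenterlineSegment(
                seg.points[a : b + 1], seg.areas[a : b + 1], seg.spacing, seg.name
            )
            new_id = len(segs)
            segs.append(piece)
            parent.append(prev)
            prev = new_id
            if b < n - 1:  # interior cut -> side root at the piece's end
                tang = seg.points[min(b + 1, n - 1)] - seg.points[max(b - 1, 0)]
                roots.append(
                    Root(
                        position=seg.points[b].copy(),
                        radius=cfg.side_radius_ratio * _local_radius(seg, b),
                        parent_segment=new_id,
                        kind="side",
                        tangent=tang / max(np.linalg.norm(tang), 1e-12),
                    )
                )
        old_to_new_tail[old_id] = prev
        if not any(network.children[old_id]):  # outlet root at the distal end
            tang = seg.points[-1] - seg.points[-2]
            roots.append(
                Root(
                    position=seg.points[-1].copy(),
                    radius=_local_radius(seg, n - 1),
                    parent_segment=prev,
                    kind="outlet",
                    tangent=tang / max(np.linalg.norm(tang), 1e-12),
                )
            )

    for r in roots:
        d, _ = tree.query(r.position)
        r.lv = bool(d <= cfg.lv_distance)

    return VascularNetwork(segs, parent), roots


# ---------------------------------------------------------------------------
# Synthetic forest growth
# ---------------------------------------------------------------------------


@dataclass
class GrowthConfig:
    """Parameters of the simplified competitive volume-minimising growth."""

    n_term: int = 12_000
    radius_exponent: float = 3.0  # bifurcation power law (Murray)
    leaf_weight_sigma: float = 0.5  # lognormal spread of per-leaf flow weight
    root_flow_exponent: float = 2.7  # root target flows ~ diameter^2.7
    upsize_cost_weight: float = 1.0  # weight of the path-upsizing volume cost
    stem_length: float = 7.0  # cm, proxy branch between a root and its tree
    stem_pieces: int = 5
    neighbourhood_factor: float = 4.0  # trees within f*dmin compete
    stub_length: float = 0.35  # cm, initial root stub length
    wall_margin: float = 0.08  # relative implicit-margin for crossing tests
    max_attempts_factor: int = 60
    seed: int = 0


class _GrowthState:
    """Growing forest stored as flat arrays for vectorised distance queries."""

    def __init__(self, cap: int) -> None:
        self.start = np.zeros((cap, 3))
        self.end = np.zeros((cap, 3))
        self.tree = np.zeros(cap, dtype=int)
        self.parent = np.full(cap, -1, dtype=int)
        self.children: list[list[int]] = []
        self.n = 0

    def add(self, start, end, tree, parent) -> int:
        i = self.n
        if i >= len(self.tree):
            grow = len(self.tree)
            self.start = np.vstack([self.start, np.zeros((grow, 3))])
            self.end = np.vstack([self.end, np.zeros((grow, 3))])
            self.tree = np.concatenate([self.tree, np.zeros(grow, dtype=int)])
            self.parent = np.concatenate([self.parent, np.full(grow, -1, dtype=int)])
        self.start[i], self.end[i] = start, end
        self.tree[i], self.parent[i] = tree, parent
        self.children.append([])
        self.n += 1
        return i

    def point_segment_dist(
        self, x: np.ndarray, idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Distance from x to the segments ``idx`` and projection parameters."""
        a = self.start[idx]
        b = self.end[idx]
        ab = b - a
        denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12)
        t = np.clip(np.einsum("ij,ij->i", x[None, :] - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(x[None, :] - proj, axis=1)
        return d, t

    def topological_order(self) -> list[int]:
        order: list[int] = []
        stack = [i for i in range(self.n) if self.parent[i] < 0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        return order


def grow_forest(
    network: VascularNetwork,
    roots: list[Root],
    mesh_or_shell,
    cfg: GrowthConfig,
) -> tuple[VascularNetwork, dict[int, float], dict[int, float]]:
    """Grow the synthetic forest from the LV roots.

    Candidate perfusion sites are sampled uniformly inside the LV wall and
    handed to the nearby tree with the largest flow deficit (target minus
    achieved share); each site is connected to the closest existing segment
    of that tree (minimal added vascular volume for a fixed new-branch
    caliber) subject to the branch not leaving the wall region, creating a
    bifurcation.  Growth stops at ``cfg.n_term`` LV terminal segments.

    Returns the hybrid network plus per-synthetic-tree achieved and target
    flow fractions (keyed by root-stub segment id) for trimming.
    """
    shell = mesh_or_shell if isinstance(mesh_or_shell, LVShell) else None
    if shell is None:
        raise ParameterError("grow_forest requires the LVShell geometry")
    rng = np.random.default_rng(cfg.seed)
    lv_roots = [r for r in roots if r.lv]
    non_lv_roots = [r for r in roots if not r.lv]
    # non-LV outlets count towards the terminal total of the final network
    n_term_lv = cfg.n_term - len(non_lv_roots)
    if n_term_lv < len(lv_roots):
        raise ParameterError("n_term must be >= number of roots")

    # root target flow fractions ~ diameter^2.7 (relative; absolute flows are
    # set later by the boundary-condition module)
    w = np.array([r.radius for r in lv_roots]) ** cfg.root_flow_exponent
    target_frac = w / w.sum()

    # proxy-branch stems: each side root carries a short constant-caliber
    # epicardial branch (standing for the vessel missed by segmentation)
    # running along the heart surface before its synthetic tree starts
    def _stem_points(r: Root) -> list[np.ndarray]:
        if cfg.stem_length <= 0 or r.tangent is None:
            return [np.asarray(r.position, dtype=float)]
        if r.kind == "outlet":
            # distal run-off: continue along the trunk direction
            lateral = np.asarray(r.tangent, dtype=float)
        else:
            n_out = r.position / shell.epi**2
            n_out = n_out / max(np.linalg.norm(n_out), 1e-12)
            lateral = np.cross(r.tangent, n_out)
        nrm = np.linalg.norm(lateral)
        if nrm < 1e-9:
            return [np.asarray(r.position, dtype=float)]
        lateral = lateral / nrm
        if lateral[2] > 0 and r.kind == "side":  # run towards the apex
            lateral = -lateral
        # walk the offset epicardial surface step by step, re-projecting the
        # heading onto the local tangent plane so arc length is preserved
        pts = [np.asarray(r.position, dtype=float)]
        step = cfg.stem_length / cfg.stem_pieces
        heading = lateral
        p = pts[0]
        for _ in range(cfg.stem_pieces):
            n_loc = p / shell.epi**2
            n_loc = n_loc / max(np.linalg.norm(n_loc), 1e-12)
            h = heading - np.dot(heading, n_loc) * n_loc
            hn = np.linalg.norm(h)
            if hn > 1e-9:
                heading = h / hn
            raw = p + heading * step
            scale = 1.0 / math.sqrt(float(shell._implicit(raw, 1.02 * shell.epi)[0]))
            proj = raw * scale
            proj[2] = min(proj[2], shell.z_top)
            pts.append(proj)
            p = proj
        return pts

    stem_points = [_stem_points(r) for r in lv_roots]

    state = _GrowthState(cap=4 * cfg.n_term + 16)
    for ti, r in enumerate(lv_roots):
        origin = stem_points[ti][-1]
        inner = shell.pull_into_wall(origin)
        direction = inner - origin
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 0.0, -1.0])
        length = min(cfg.stub_length, 0.9 * nrm) if nrm > 0.1 else cfg.stub_length
        state.add(origin, origin + direction * length, ti, -1)

    n_trees = len(lv_roots)
    term_per_tree = np.ones(n_trees, dtype=int)
    n_term_now = n_trees
    # subtree terminal counts and segment lengths, maintained incrementally
    # for the incremental-volume attachment cost
    wt = np.ones(state.start.shape[0] + 16, dtype=float)
    seg_len = np.zeros_like(wt)
    for i in range(state.n):
        seg_len[i] = np.linalg.norm(state.end[i] - state.start[i])
    attempts = 0
    max_attempts = cfg.max_attempts_factor * n_term_lv
    margin = cfg.wall_margin

    def _branch_ok(p: np.ndarray, q: np.ndarray) -> bool:
        ts = np.linspace(0.12, 0.95, 6)
        pts = p[None, :] + ts[:, None] * (q - p)[None, :]
        return bool(shell.inside(pts, margin=margin).all())

    # spatial index over segment midpoints, rebuilt periodically; segments
    # added since the last rebuild are scanned exactly
    kdt: cKDTree | None = None
    kdt_size = 0
    rebuild_every = 512
    k_query = 48

    while n_term_now < n_term_lv:
        attempts += 1
        if attempts > max_attempts:
            raise GrowthError(
                f"growth stalled at {n_term_now}/{n_term_lv} terminals "
                f"after {attempts} attempts"
            )
        if kdt is None or state.n - kdt_size >= rebuild_every:
            mids = 0.5 * (state.start[: state.n] + state.end[: state.n])
            kdt = cKDTree(mids)
            kdt_size = state.n
        x = shell.sample_inside(rng, 1)[0]
        k = min(k_query, kdt_size)
        _, near = kdt.query(x, k=k)
        near = np.atleast_1d(near)
        if state.n > kdt_size:
            near = np.concatenate([near, np.arange(kdt_size, state.n)])
        d, t = state.point_segment_dist(x, near)
        tree_near = state.tree[near]
        dmin_per_tree = np.full(n_trees, np.inf)
        np.minimum.at(dmin_per_tree, tree_near, d)
        dmin = dmin_per_tree.min()
        nearby = np.nonzero(dmin_per_tree <= cfg.neighbourhood_factor * dmin)[0]
        deficit = target_frac - term_per_tree / n_term_lv
        ti = int(nearby[np.argmax(deficit[nearby])])
        if deficit[ti] <= -1.0 / n_term_lv and len(nearby) > 1:
            ti = int(nearby[np.argmin(dmin_per_tree[nearby])])
        sel = np.nonzero(tree_near == ti)[0]
        order_c = sel[np.argsort(d[sel])[:6]]
        # incremental vascular volume of each attachment option: the new
        # branch itself plus the Murray up-sizing of the path back to the
        # root (~ (2/3) sum L_i / w_i^(1/3) for one added terminal), which
        # favours connections to already-large vessels
        costs = []
        for ci in order_c:
            si = int(near[ci])
            up = float(np.clip(t[ci], 0.1, 0.9)) * seg_len[si] * wt[si] ** (-1.0 / 3.0)
            p = int(state.parent[si])
            while p >= 0:
                up += seg_len[p] * wt[p] ** (-1.0 / 3.0)
                p = int(state.parent[p])
            costs.append(d[ci] + cfg.upsize_cost_weight * (2.0 / 3.0) * up)
        for ci in order_c[np.argsort(costs)]:
            si = int(near[ci])
            tt = float(np.clip(t[ci], 0.1, 0.9))
            att = state.start[si] + tt * (state.end[si] - state.start[si])
            if not _branch_ok(att, x):
                continue
            # bifurcate: shorten si to [start, att]; continuation inherits the
            # former children of si, the new branch runs att -> x
            old_end = state.end[si].copy()
            state.end[si] = att
            cont = state.add(att, old_end, ti, si)
            newb = state.add(att, x, ti, si)
            for c in state.children[si]:
                state.parent[c] = cont
            state.children[cont] = state.children[si]
            state.children[si] = [cont, newb]
            if len(wt) < state.n:
                wt = np.concatenate([wt, np.ones(len(wt))])
                seg_len = np.concatenate([seg_len, np.zeros(len(seg_len))])
            wt[cont] = wt[si]
            wt[newb] = 1.0
            seg_len[cont] = np.linalg.norm(old_end - att)
            seg_len[newb] = np.linalg.norm(x - att)
            seg_len[si] = tt * seg_len[si]
            a = si
            while a >= 0:
                wt[a] += 1.0
                a = int(state.parent[a])
            term_per_tree[ti] += 1
            n_term_now += 1
            break

    # assemble the hybrid network --------------------------------------------
    segs = [s for s in network.segments]
    parent = list(network.parent)
    lv_flags = [True] * len(segs)
    n_syn = state.n
    topo = state.topological_order()
    leaf = np.array([len(state.children[i]) == 0 for i in range(n_syn)])

    # radii top-down from the root-stub caliber (the patient-specific prior):
    # each segment carries a flow weight (sum of lognormal leaf weights in its
    # subtree) and the bifurcation power law r ~ weight^(1/eta) splits the
    # caliber down the tree, so terminal radii shrink with tree size
    eta = cfg.radius_exponent
    w = np.zeros(n_syn)
    leaf_w = np.exp(rng.normal(0.0, cfg.leaf_weight_sigma, size=n_syn))
    for i in reversed(topo):
        if leaf[i]:
            w[i] = leaf_w[i]
        if state.parent[i] >= 0:
            w[state.parent[i]] += w[i]
    radii = np.empty(n_syn)
    for i in topo:
        p = state.parent[i]
        if p < 0:
            radii[i] = lv_roots[state.tree[i]].radius
        else:
            radii[i] = radii[p] * (w[i] / w[p]) ** (1.0 / eta)

    # stems first: chains of non-dilating proxy-branch segments
    stem_first = [-1] * n_trees
    stem_last = [-1] * n_trees
    for ti, r in enumerate(lv_roots):
        pts = stem_points[ti]
        prev = r.parent_segment
        for a, b in zip(pts[:-1], pts[1:]):
            sid = len(segs)
            segs.append(SyntheticSegment(a, b, r.radius, dilatable=False))
            parent.append(prev)
            lv_flags.append(True)
            if stem_first[ti] < 0:
                stem_first[ti] = sid
            prev = sid
        stem_last[ti] = prev

    syn_id_map = np.full(n_syn, -1, dtype=int)
    for i in topo:
        if state.parent[i] >= 0:
            pid = syn_id_map[state.parent[i]]
        else:
            ti = int(state.tree[i])
            pid = stem_last[ti] if stem_last[ti] >= 0 else lv_roots[ti].parent_segment
        sid = len(segs)
        syn_id_map[i] = sid
        segs.append(
            SyntheticSegment(state.start[i].copy(), state.end[i].copy(), float(radii[i]))
        )
        parent.append(pid)
        lv_flags.append(True)

    # non-LV roots become plain synthetic outlet stubs (not grown)
    for r in non_lv_roots:
        away = r.position - shell.pull_into_wall(r.position)
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        segs.append(
            SyntheticSegment(r.position, r.position + 0.3 * away, r.radius)
        )
        parent.append(r.parent_segment)
        lv_flags.append(False)

    net = VascularNetwork(segs, parent, lv_flags)

    # achieved/target flow fractions per synthetic tree (root-stub ids)
    achieved: dict[int, float] = {}
    target: dict[int, float] = {}
    for ti in range(n_trees):
        if stem_first[ti] >= 0:
            stub = int(stem_first[ti])
        else:
            stub_local = int(np.nonzero(state.tree[:n_syn] == ti)[0][0])
            stub = int(syn_id_map[stub_local])
        achieved[stub] = term_per_tree[ti] / n_term_lv
        target[stub] = float(target_frac[ti])
    return net, achieved, target


# ---------------------------------------------------------------------------
# One-call fixture
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """Bundle of generated study inputs (stands in for one patient)."""

    network: VascularNetwork
    mesh: MyocardiumMesh
    shell: LVShell
    roots: list[Root]
    achieved: dict[int, float]
    target: dict[int, float]


def default_fixture(
    n_term: int = 2000,
    target_elements: int = 30_000,
    seed: int = 0,
    stenosis: StenosisSpec | None = None,
    trim: bool = True,
    shell_spec: LVShellSpec | None = None,
    growth: GrowthConfig | None = None,
    roots_cfg: RootSeedConfig | None = None,
) -> Fixture:
    """Generate the full synthetic study geometry in one call."""
    spec = shell_spec or LVShellSpec(target_elements=target_elements, seed=seed)
    shell = LVShell(spec)
    mesh = make_lv_mesh(spec)
    trees = make_epicardial_trees(EpicardialTreeSpec(stenosis=stenosis), shell)
    seeded, roots = seed_roots(trees, mesh, roots_cfg)
    gcfg = growth or GrowthConfig(n_term=n_term, seed=seed)
    if growth is None:
        gcfg.n_term = n_term
        gcfg.seed = seed
    net, achieved, target = grow_forest(seeded, roots, shell, gcfg)
    if trim:
        net = net.trim_undergrown(achieved, target)
    return Fixture(net, mesh, shell, roots, achieved, target)
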