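"""Derived clinical and physiological quantities.

* FFR: local pressure over aortic pressure under hyperemia (< 0.8 flags a
  hemodynamically significant lesion);
* MBF: flow per tissue mass at four nested spatial resolutions (whole
  myocardium, main-artery territories, AHA-17 segments, voxel/element
  scale), with volume-weighted statistics per level;
* bull's-eye perfusion maps at PET-like cell volume;
* Strahler-order statistics of element flows and pressures, with the
  log-linear flow law fit;
* fractal heterogeneity analysis: relative dispersion RD = SD/mean of
  regional flows versus aggregate volume; the log-log slope gives the
  fractal dimension FD = 1 - slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .myocardium import MyocardiumMesh, PerfusionTerritory
from .network import ParameterError, VascularNetwork

FFR_THRESHOLD = 0.8
TISSUE_DENSITY = 1.05  # g mL^-1


# ---------------------------------------------------------------------------
# FFR
# ---------------------------------------------------------------------------


def ffr(pressures: np.ndarray, P_AO: float) -> np.ndarray:
    """Fractional flow reserve: p / P_AO (dimensionless)."""
    if P_AO <= 0:
        raise ParameterError("P_AO must be positive")
    return np.asarray(pressures, dtype=float) / P_AO


def ffr_positive(value: np.ndarray | float) -> np.ndarray | bool:
    """Clinical classification: positive (diseased) iff FFR < 0.8 strictly."""
    return np.asarray(value) < FFR_THRESHOLD


def main_tree_labels(network: VascularNetwork) -> list[str]:
    """Per-segment main-coronary-tree label (RCA / LAD / LCX / LM).

    Each segment inherits the name of its nearest named ancestor; left-main
    side branches (rare) keep the LM label.
    """
    labels = [""] * len(network.segments)
    for i in network.topological_order():
        name = getattr(network.segments[i], "name", "")
        if name in ("RCA", "LAD", "LCX", "LM"):
            labels[i] = name
        elif network.parent[i] >= 0:
            labels[i] = labels[network.parent[i]]
    return labels


def min_ffr_by_tree(
    network: VascularNetwork,
    state,
    P_AO: float | None = None,
    segmented_only: bool = True,
) -> dict:
    """Minimum FFR over each main tree (nodal values where available).

    FFR is a clinical index of the epicardial vessels, so by default only
    the segmented (centerline-resolved) vasculature is scanned; arteriolar
    outlet pressures of the synthetic forest always sit much lower and are
    not what an invasive pressure wire would measure.
    """
    P = P_AO if P_AO is not None else state.P_AO
    labels = main_tree_labels(network)
    out: dict[str, float] = {}
    for i in range(len(network.segments)):
        if segmented_only and network.segments[i].kind != "segmented":
            continue
        lo = float(state.p_out[i])
        if i in state.node_pressures:
            lo = min(lo, float(np.min(state.node_pressures[i])))
        lab = labels[i] or "?"
        out[lab] = min(out.get(lab, np.inf), lo / P)
    return out


# ---------------------------------------------------------------------------
# MBF
# ---------------------------------------------------------------------------


@dataclass
class MBFLevel:
    name: str
    values: np.ndarray  # MBF per sub-volume, mL min^-1 g^-1
    volumes: np.ndarray  # sub-volume sizes, mL

    @property
    def mean(self) -> float:
        """Volume-weighted mean MBF."""
        return float(np.average(self.values, weights=self.volumes))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(
            np.sqrt(np.average((self.values - m) ** 2, weights=self.volumes))
        )

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())


@dataclass
class MBFReport:
    levels: dict  # name -> MBFLevel
    density: float = TISSUE_DENSITY

    def __getitem__(self, name: str) -> MBFLevel:
        return self.levels[name]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, lev in self.levels.items():
            lo, hi = lev.range
            rows.append(
                {
                    "level": name,
                    "n": len(lev.values),
                    "mean": lev.mean,
                    "sd": lev.sd,
                    "min": lo,
                    "max": hi,
                }
            )
        return pd.DataFrame(rows)


def territory_element_flows(
    mesh: MyocardiumMesh,
    territories: PerfusionTerritory,
    outlet_flows: np.ndarray,
) -> np.ndarray:
    """Spread territory flows uniformly over their elements (mL/min each).

    Used for the stand-alone coronary model, where the flow of territory j
    is the terminal-segment flow q^{T,j}.
    """
    vols = mesh.element_volumes()
    outlet_flows = np.asarray(outlet_flows, dtype=float)
    tvol = np.maximum(territories.volumes, 1e-30)
    per_vol = outlet_flows / tvol
    return per_vol[territories.labels] * vols


def _group_mbf(flows, vols, labels, density) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(labels)
    f = np.array([flows[labels == u].sum() for u in uniq])
    v = np.array([vols[labels == u].sum() for u in uniq])
    keep = v > 0
    if not keep.all():
        warnings.warn("zero-volume regions excluded from MBF level", stacklevel=2)
    return f[keep] / (density * v[keep]), v[keep]


def mbf_report(
    mesh: MyocardiumMesh,
    element_flows: np.ndarray,
    aha_labels: np.ndarray | None = None,
    tree_labels: np.ndarray | None = None,
    density: float = TISSUE_DENSITY,
) -> MBFReport:
    """Multi-resolution MBF from per-element flows (mL/min per element).

    Levels: ``myo`` (organ), ``trees`` (main-artery territories, if labels
    given), ``AHA`` (17 segments, if labels given) and ``voxels``
    (per element).  MBF_j = Q_j / (density * Omega_j).
    """
    vols = mesh.element_volumes()
    flows = np.asarray(element_flows, dtype=float)
    levels: dict[str, MBFLevel] = {}
    levels["myo"] = MBFLevel(
        "myo",
        np.array([flows.sum() / (density * vols.sum())]),
        np.array([vols.sum()]),
    )
    if tree_labels is not None:
        vals, v = _group_mbf(flows, vols, np.asarray(tree_labels), density)
        levels["trees"] = MBFLevel("trees", vals, v)
    if aha_labels is not None:
        vals, v = _group_mbf(flows, vols, np.asarray(aha_labels), density)
        levels["AHA"] = MBFLevel("AHA", vals, v)
    levels["voxels"] = MBFLevel("voxels", flows / (density * vols), vols)
    return MBFReport(levels, density)


# ---------------------------------------------------------------------------
# AHA 17-segment decomposition
# ---------------------------------------------------------------------------


def _axial_fraction(mesh: MyocardiumMesh, pts: np.ndarray) -> np.ndarray:
    if mesh.long_axis is None or mesh.apex is None or mesh.base_center is None:
        raise ParameterError("mesh lacks long-axis metadata for AHA labelling")
    axis = np.asarray(mesh.long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    span = float(np.dot(mesh.base_center - mesh.apex, axis))
    if abs(span) < 1e-9:
        raise ParameterError("degenerate long axis")
    return np.dot(pts - mesh.apex, axis) / span


def aha17(
    mesh: MyocardiumMesh,
    apex_fraction: float = 0.15,
    anterior_angle_deg: float = 90.0,
) -> np.ndarray:
    """Per-element AHA segment labels (1–17).

    The long axis is split into an apical cap (segment 17) and three equal
    thirds; basal and mid thirds carry 6 circumferential sectors of 60°,
    the apical third 4 sectors of 90° (rotated 45°), measured from the
    anterior direction.
    """
    cent = mesh.centroids()
    t = _axial_fraction(mesh, cent)
    ang = (
        np.degrees(np.arctan2(cent[:, 1], cent[:, 0])) - anterior_angle_deg
    ) % 360.0
    labels = np.zeros(len(cent), dtype=int)
    cap = t < apex_fraction
    labels[cap] = 17
    rest = ~cap
    third = (t - apex_fraction) / max(1.0 - apex_fraction, 1e-12) * 3.0
    sec6 = (ang // 60.0).astype(int)  # 0..5
    sec4 = (((ang + 45.0) % 360.0) // 90.0).astype(int)  # 0..3
    apical = rest & (third < 1.0)
    mid = rest & (third >= 1.0) & (third < 2.0)
    basal = rest & (third >= 2.0)
    labels[basal] = 1 + sec6[basal]
    labels[mid] = 7 + sec6[mid]
    labels[apical] = 13 + sec4[apical]
    return labels


# ---------------------------------------------------------------------------
# Perfusion (bull's-eye) maps
# ---------------------------------------------------------------------------


@dataclass
class PerfusionMap:
    """Polar raster of MBF: radius runs apex (centre) to base (rim)."""

    values: np.ndarray  # (n_r, n_phi), NaN where empty
    cell_volumes: np.ndarray
    t_edges: np.ndarray
    phi_edges: np.ndarray

    def mean(self) -> float:
        ok = np.isfinite(self.values)
        return float(
            np.average(self.values[ok], weights=self.cell_volumes[ok])
        )

    def to_png(self, path, clip: float | None = None, title: str = "") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        r = self.t_edges
        th = self.phi_edges
        vals = self.values.copy()
        if clip is not None:
            vals = np.clip(vals, None, clip)
        ax.pcolormesh(th, r, vals, shading="auto")
        for rr in (1.0 / 3, 2.0 / 3, 1.0):  # AHA third boundaries
            ax.plot(np.linspace(0, 2 * np.pi, 100), [rr] * 100, "k-", lw=0.5)
        ax.set_yticks([])
        ax.set_title(title)
        fig.savefig(path, dpi=120)
        plt.close(fig)


def perfusion_map(
    mesh: MyocardiumMesh,
    element_mbf: np.ndarray,
    target_cell_volume: float = 6.4e-2,
) -> PerfusionMap:
    """Aggregate element MBF into a PET-resolution polar raster."""
    vols = mesh.element_volumes()
    cent = mesh.centroids()
    t = np.clip(_axial_fraction(mesh, cent), 0.0, 1.0)
    phi = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * np.pi)
    n_cells = max(int(mesh.V_LV / target_cell_volume), 16)
    n_r = max(4, int(round(np.sqrt(n_cells / 6.0))))
    n_phi = max(8, int(round(n_cells / n_r)))
    t_edges = np.linspace(0.0, 1.0, n_r + 1)
    phi_edges = np.linspace(0.0, 2 * np.pi, n_phi + 1)
    ir = np.clip(np.searchsorted(t_edges, t, side="right") - 1, 0, n_r - 1)
    ip = np.clip(np.searchsorted(phi_edges, phi, side="right") - 1, 0, n_phi - 1)
    flat = ir * n_phi + ip
    wsum = np.bincount(flat, weights=vols * element_mbf, minlength=n_r * n_phi)
    vsum = np.bincount(flat, weights=vols, minlength=n_r * n_phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(vsum > 0, wsum / np.maximum(vsum, 1e-300), np.nan)
    return PerfusionMap(
        vals.reshape(n_r, n_phi), vsum.reshape(n_r, n_phi), t_edges, phi_edges
    )


# ---------------------------------------------------------------------------
# Strahler statistics
# ---------------------------------------------------------------------------


@dataclass
class StrahlerStats:
    orders: np.ndarray  # orders included in the fit
    mean_flows: np.ndarray  # mean element flow per order, mL/min
    slope: float  # d ln(mean flow) / d order
    intercept: float
    r2: float
    pressure_stats: dict  # order -> dict(mean/median/min/max), mmHg
    excluded_orders: list


def strahler_stats(
    network: VascularNetwork,
    Q: np.ndarray,
    state,
    orders: np.ndarray,
) -> StrahlerStats:
    """Per-Strahler-order element flow/pressure statistics and log-law fit.

    Elements (same-order chains) are grouped by order; a least-squares line
    is fitted to ln(mean element flow) versus order.  Orders with fewer
    than two elements are excluded from the fit (too few for statistics).
    """
    elements = network.decompose_elements(orders)
    eorder = np.array([e.order for e in elements])
    eflow = np.array(
        [float(np.mean([Q[i] for i in e.segment_ids])) for e in elements]
    )
    uniq = np.unique(eorder)
    mean_flows, kept, excluded = [], [], []
    for o in uniq:
        sel = eorder == o
        if sel.sum() < 2:
            excluded.append(int(o))
            warnings.warn(
                f"Strahler order {o} has <2 elements; excluded from fit",
                stacklevel=2,
            )
            continue
        kept.append(int(o))
        mean_flows.append(float(eflow[sel].mean()))
    if len(kept) < 2:
        raise ParameterError("log-linear fit needs >= 2 Strahler orders")
    kept_a = np.array(kept, dtype=float)
    logf = np.log(np.array(mean_flows))
    slope, intercept = np.polyfit(kept_a, logf, 1)
    pred = slope * kept_a + intercept
    ss_res = float(np.sum((logf - pred) ** 2))
    ss_tot = float(np.sum((logf - logf.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pstats = {}
    p_out = state.p_out
    for o in uniq:
        p = np.array([p_out[i] for i in np.nonzero(orders == o)[0]])
        pstats[int(o)] = {
            "mean": float(p.mean()),
            "median": float(np.median(p)),
            "min": float(p.min()),
            "max": float(p.max()),
        }
    return StrahlerStats(
        orders=np.array(kept),
        mean_flows=np.array(mean_flows),
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        pressure_stats=pstats,
        excluded_orders=excluded,
    )


def path_pressure_trace(network: VascularNetwork, state, leaf: int, orders) -> dict:
    """Root-to-terminal pressure/order trace for one path (plot support)."""
    path = list(reversed(network.path_to_root(leaf)))
    return {
        "segments": path,
        "order": [int(orders[i]) for i in path],
        "p_in": [float(state.p_in[i]) for i in path],
        "p_out": [float(state.p_out[i]) for i in path],
    }


# ---------------------------------------------------------------------------
# Fractal analysis
# ---------------------------------------------------------------------------


@dataclass
class FractalResult:
    volumes: np.ndarray  # mean aggregate volume per scale, mL
    rd: np.ndarray  # relative dispersion per scale
    slope: float  # d log10(RD) / d log10(v)
    fd: float  # fractal dimension = 1 - slope

    @property
    def n_scales(self) -> int:
        return len(self.volumes)


def fractal_analysis(
    mesh: MyocardiumMesh,
    element_flows: np.ndarray,
    density: float = TISSUE_DENSITY,
    depths: range | list | None = None,
    min_blocks: int = 8,
) -> FractalResult:
    """Relative dispersion of regional flow versus aggregate volume.

    The myocardium is partitioned into cubic spatial blocks at successive
    octree depths; at each scale RD = SD/mean of the per-block MBF values
    (blocks with less than half the median occupied volume are discarded as
    boundary slivers).  A line fitted to log RD versus log volume gives the
    fractal dimension FD = 1 - slope.
    """
    flows = np.asarray(element_flows, dtype=float)
    vols = mesh.element_volumes()
    if flows.sum() <= 0:
        raise ParameterError("mean flow must be positive for RD analysis")
    cent = mesh.centroids()
    lo = cent.min(axis=0) - 1e-9
    hi = cent.max(axis=0) + 1e-9
    span = hi - lo
    depths = depths if depths is not None else range(1, 7)
    scales, rds = [], []
    for d in depths:
        nx = 2**d
        idx = np.minimum((np.floor((cent - lo) / span * nx)).astype(int), nx - 1)
        flat = (idx[:, 0] * nx + idx[:, 1]) * nx + idx[:, 2]
        uniq, inv = np.unique(flat, return_inverse=True)
        bf = np.bincount(inv, weights=flows)
        bv = np.bincount(inv, weights=vols)
        med = np.median(bv)
        keep = bv >= 0.5 * med
        if keep.sum() < min_blocks:
            continue
        mbf = bf[keep] / (density * bv[keep])
        m = mbf.mean()
        if m <= 0:
            continue
        rds.append(mbf.std() / m)
        scales.append(float(bv[keep].mean()))
    if len(scales) < 3:
        raise ParameterError("fractal analysis needs >= 3 usable scales")
    v = np.array(scales)
    rd = np.array(rds)
    if np.all(rd < 1e-13):
        # spatially uniform flow: heterogeneity identical at all scales
        return FractalResult(v, rd, 0.0, 1.0)
    ok = rd > 0
    slope = float(np.polyfit(np.log10(v[ok]), np.log10(rd[ok]), 1)[0])
    return FractalResult(v, rd, slope, 1.0 - slope)
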