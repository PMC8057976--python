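"""Hybrid vascular network data model.

A :class:`VascularNetwork` is a forest of directed trees rooted at the
coronary ostia.  Two segment kinds coexist:

* :class:`CenterlineSegment` — image-like ("segmented") vessels resolved by a
  centerline with per-node cross-sectional area, discretised at a fixed
  0.01 cm arc-length step;
* :class:`SyntheticSegment` — generated downstream vessels, straight
  cylinders of constant radius, carrying an undilated reference radius and a
  dilation fraction (vasodilation state).

The module also implements the network-level structural operations:
Strahler ordering (classic topological scheme with an optional
diameter-based reassignment pass and a configurable base offset), element
decomposition (maximal same-order chains), trimming of under-grown synthetic
trees, and uniform per-tree dilation.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DEFAULT_NODE_SPACING = 0.01  # cm, centerline discretisation step
DILATION_CAP = 0.40  # maximal diameter increase fraction at full hyperemia


class TopologyError(ValueError):
    """Raised when the segment graph is not a valid forest."""


class ParameterError(ValueError):
    """Raised for invalid physical/configuration parameters."""


@dataclass
class CenterlineSegment:
    """Centerline-resolved vessel with variable cross-sectional area.

    Parameters
    ----------
    points : (n, 3) array
        Node positions along the centerline axis, in cm.
    areas : (n,) array
        Cross-sectional area S at each node, in cm^2.
    spacing : float
        Arc-length step between consecutive nodes, in cm.
    """

    points: np.ndarray
    areas: np.ndarray
    spacing: float = DEFAULT_NODE_SPACING
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("centerline points must be (n, 3)")
        if len(self.areas) != len(self.points):
            raise ParameterError("areas and points length mismatch")
        if len(self.points) < 2:
            raise ParameterError("centerline needs >= 2 nodes")
        if np.any(self.areas <= 0):
            raise ParameterError("cross-sectional areas must be positive")

    @property
    def kind(self) -> str:
        return "segmented"

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return self.spacing * (self.n_nodes - 1)

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]

    @property
    def outlet_radius(self) -> float:
        return float(np.sqrt(self.areas[-1] / np.pi))

    @property
    def mean_diameter(self) -> float:
        return float(2.0 * np.sqrt(np.mean(self.areas) / np.pi))


@dataclass
class SyntheticSegment:
    """Constant-radius cylindrical vessel (0D Poiseuille element).

    ``dilatable`` distinguishes generated (arteriolar) vessels, which take
    part in vasodilation, from proxy branches standing in for pre-existing
    epicardial vessels missed by segmentation, which keep their caliber.
    """

    start: np.ndarray
    end: np.ndarray
    r0: float  # undilated radius, cm
    dilation: float = 0.0  # diameter increase fraction in [0, DILATION_CAP]
    name: str = ""
    dilatable: bool = True

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.r0 <= 0:
            raise ParameterError("radius must be positive")
        if self.length <= 0:
            raise ParameterError("segment length must be positive")

    @property
    def kind(self) -> str:
        return "synthetic"

    @property
    def radius(self) -> float:
        return self.r0 * (1.0 + self.dilation)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def outlet_radius(self) -> float:
        return self.radius

    @property
    def mean_diameter(self) -> float:
        return 2.0 * self.radius


Segment = CenterlineSegment | SyntheticSegment


@dataclass
class StrahlerElement:
    """Maximal chain of consecutive segments sharing one Strahler order."""

    segment_ids: list[int]
    order: int


class VascularNetwork:
    """Directed forest of vascular segments rooted at the coronary ostia.

    Topology is stored as a parent pointer per segment (−1 for roots).
    Terminal outlets are the leaf segments; each carries an LV /non-LV flag
    used when terminal flow boundary conditions are assigned.
    """

    def __init__(
        self,
        segments: Sequence[Segment],
        parent: Sequence[int],
        lv_outlet: Sequence[bool] | None = None,
    ) -> None:
        self.segments: list[Segment] = list(segments)
        self.parent = np.asarray(parent, dtype=int)
        if len(self.parent) != len(self.segments):
            raise TopologyError("parent array length mismatch")
        n = len(self.segments)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.roots = [i for i in range(n) if self.parent[i] < 0]
        if lv_outlet is None:
            lv_outlet = [True] * n
        self.lv_outlet = np.asarray(lv_outlet, dtype=bool)
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.segments)
        seen = np.zeros(n, dtype=bool)
        stack = list(self.roots)
        while stack:
            i = stack.pop()
            if seen[i]:
                raise TopologyError("cycle or multiple parents detected")
            seen[i] = True
            stack.extend(self.children[i])
        if n and not seen.all():
            raise TopologyError("segments unreachable from any root (cycle?)")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def leaves(self) -> list[int]:
        return [i for i in range(len(self.segments)) if not self.children[i]]

    @property
    def n_term(self) -> int:
        return len(self.leaves())

    def outlet_radii(self, ids: Iterable[int] | None = None) -> np.ndarray:
        ids = self.leaves() if ids is None else list(ids)
        return np.array([self.segments[i].outlet_radius for i in ids])

    def lv_leaves(self) -> list[int]:
        return [i for i in self.leaves() if self.lv_outlet[i]]

    def non_lv_leaves(self) -> list[int]:
        return [i for i in self.leaves() if not self.lv_outlet[i]]

    def topological_order(self) -> list[int]:
        """Segment ids sorted root-first (parents before children)."""
        order: list[int] = []
        stack = list(self.roots)
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        return order

    def root_of(self, i: int) -> int:
        while self.parent[i] >= 0:
            i = int(self.parent[i])
        return i

    def path_to_root(self, i: int) -> list[int]:
        path = [i]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def synthetic_tree_roots(self) -> list[int]:
        """Ids of topmost synthetic segments (synthetic-tree root stubs)."""
        out = []
        for i, seg in enumerate(self.segments):
            if seg.kind != "synthetic":
                continue
            p = self.parent[i]
            if p < 0 or self.segments[p].kind == "segmented":
                out.append(i)
        return out

    def synthetic_tree_of(self) -> np.ndarray:
        """Per-segment id of the synthetic-tree root stub (−1 for segmented)."""
        lab = np.full(len(self.segments), -1, dtype=int)
        for i in self.topological_order():
            seg = self.segments[i]
            if seg.kind != "synthetic":
                continue
            p = self.parent[i]
            if p < 0 or self.segments[p].kind == "segmented":
                lab[i] = i
            else:
                lab[i] = lab[p]
        return lab

    def subtree_ids(self, root: int) -> list[int]:
        out = []
        stack = [root]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def copy(self) -> "VascularNetwork":
        return _copy.deepcopy(self)

    # -- Strahler ordering -------------------------------------------------

    def strahler_order(
        self,
        base_offset: int = 5,
        diameter_refine: bool = True,
        max_refine_iterations: int = 1,
    ) -> np.ndarray:
        """Assign a Strahler order to every segment.

        Classic topological Strahler (leaves get the minimal order; a parent
        whose highest child order k is attained by >= 2 children gets k+1,
        else k), shifted so leaves start at ``base_offset``.  When
        ``diameter_refine`` is set, a diameter-based reassignment pass is
        iterated to convergence: a segment moves to the adjacent order when
        its mean diameter lies outside the mean ± SD diameter band of its
        current order.  This diameter-defined variant keeps same-caliber
        trunk runs in one order instead of letting tributary ties inflate
        the order of large conduit vessels.
        """
        n = len(self.segments)
        order = np.zeros(n, dtype=int)
        for i in reversed(self.topological_order()):
            ch = self.children[i]
            if not ch:
                order[i] = 1
            else:
                omax = max(order[c] for c in ch)
                ties = sum(1 for c in ch if order[c] == omax)
                order[i] = omax + 1 if ties >= 2 else omax
        order += base_offset - 1
        if diameter_refine and n > 1:
            for _ in range(max_refine_iterations):
                new = self._diameter_reassign(order)
                if np.array_equal(new, order):
                    break
                order = new
        return order

    def _diameter_reassign(self, order: np.ndarray) -> np.ndarray:
        diam = np.array([s.mean_diameter for s in self.segments])
        new = order.copy()
        uniq = np.unique(order)
        stats = {}
        for o in uniq:
            d = diam[order == o]
            stats[o] = (d.mean(), d.std())
        for i in range(len(order)):
            o = order[i]
            m, s = stats[o]
            if s == 0:
                continue
            if diam[i] > m + s and (o + 1) in stats:
                new[i] = o + 1
            elif diam[i] < m - s and (o - 1) in stats:
                new[i] = o - 1
        # keep ordering consistent along paths: parent never below child
        for i in self.topological_order():
            p = self.parent[i]
            if p >= 0 and new[i] > new[p]:
                new[i] = new[p]
        return new

    def decompose_elements(self, order: np.ndarray) -> list[StrahlerElement]:
        """Group consecutive same-order segments into Strahler elements.

        An element is a maximal chain of segments connected in series that
        share one order; chains break at junctions where the order changes
        or where a segment has several same-order children.
        """
        n = len(self.segments)
        element_of = np.full(n, -1, dtype=int)
        elements: list[StrahlerElement] = []
        for i in self.topological_order():
            p = self.parent[i]
            joined = False
            if p >= 0 and order[p] == order[i]:
                same = [c for c in self.children[p] if order[c] == order[p]]
                if len(same) == 1:
                    eid = element_of[p]
                    elements[eid].segment_ids.append(i)
                    element_of[i] = eid
                    joined = True
            if not joined:
                element_of[i] = len(elements)
                elements.append(StrahlerElement([i], int(order[i])))
        return elements

    # -- trimming ----------------------------------------------------------

    def trim_undergrown(
        self,
        achieved_flow: dict[int, float],
        target_flow: dict[int, float],
        threshold: float = 0.20,
    ) -> "VascularNetwork":
        """Remove synthetic trees reaching < ``threshold`` of target flow.

        ``achieved_flow`` / ``target_flow`` map synthetic-tree root-stub ids
        to flows.  The comparator is strict: a tree at exactly the threshold
        is retained.  Returns a new network; removal candidates are whole
        synthetic trees (their root stub and everything below).
        """
        for k, t in target_flow.items():
            if t <= 0:
                raise ParameterError(f"target flow for tree {k} must be > 0")
        drop: set[int] = set()
        for stub, t in target_flow.items():
            a = achieved_flow.get(stub, 0.0)
            if a / t < threshold:
                drop.update(self.subtree_ids(stub))
        if not drop:
            return self.copy()
        keep = [i for i in range(len(self.segments)) if i not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        segs = [_copy.deepcopy(self.segments[i]) for i in keep]
        parent = [
            remap[self.parent[i]] if self.parent[i] >= 0 and self.parent[i] in remap else -1
            for i in keep
        ]
        lv = [bool(self.lv_outlet[i]) for i in keep]
        return VascularNetwork(segs, parent, lv)

    # -- dilation ----------------------------------------------------------

    def dilate(
        self,
        per_tree_fraction: dict[int, float] | float,
        cap: float = DILATION_CAP,
    ) -> "VascularNetwork":
        """Set the dilation fraction of synthetic trees (in place).

        ``per_tree_fraction`` maps synthetic-tree root-stub ids to diameter
        increase fractions, or is a single fraction applied to every tree.
        Fractions above ``cap`` are clipped (with a warning); segmented
        vessels are never modified.  Returns ``self``.
        """
        import warnings

        tree_of = self.synthetic_tree_of()
        if isinstance(per_tree_fraction, dict):
            frac_map = dict(per_tree_fraction)
        else:
            frac_map = {s: float(per_tree_fraction) for s in self.synthetic_tree_roots()}
        for stub, f in frac_map.items():
            if f > cap:
                warnings.warn(
                    f"dilation {f:.3f} exceeds cap {cap:.2f}; clipped", stacklevel=2
                )
                f = cap
            if f < 0:
                raise ParameterError("dilation fraction must be >= 0")
            for i in np.nonzero(tree_of == stub)[0]:
                if self.segments[i].dilatable:
                    self.segments[i].dilation = f
        return self

    def dilation_fractions(self) -> dict[int, float]:
        """Current dilation fraction per synthetic tree (by root-stub id).

        Reported from the first dilatable segment of the tree (a tree may be
        headed by non-dilating proxy-branch segments).
        """
        out = {}
        for stub in self.synthetic_tree_roots():
            frac = 0.0
            stack = [stub]
            while stack:
                i = stack.pop()
                if self.segments[i].kind == "synthetic" and self.segments[i].dilatable:
                    frac = float(self.segments[i].dilation)
                    break
                stack.extend(self.children[i])
            out[stub] = frac
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            if s.kind == "segmented":
                segs.append(
                    {
                        "kind": "segmented",
                        "points": s.points.tolist(),
                        "areas": s.areas.tolist(),
                        "spacing": s.spacing,
                        "name": s.name,
                    }
                )
            else:
                segs.append(
                    {
                        "kind": "synthetic",
                        "start": s.start.tolist(),
                        "end": s.end.tolist(),
                        "r0": s.r0,
                        "dilation": s.dilation,
                        "name": s.name,
                        "dilatable": bool(s.dilatable),
                    }
                )
        return {
            "segments": segs,
            "parent": self.parent.tolist(),
            "lv_outlet": self.lv_outlet.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularNetwork":
        segs: list[Segment] = []
        for s in d["segments"]:
            if s["kind"] == "segmented":
                segs.append(
                    CenterlineSegment(
                        np.asarray(s["points"]),
                        np.asarray(s["areas"]),
                        s.get("spacing", DEFAULT_NODE_SPACING),
                        s.get("name", ""),
                    )
                )
            else:
                segs.append(
                    SyntheticSegment(
                        np.asarray(s["start"]),
                        np.asarray(s["end"]),
                        s["r0"],
                        s.get("dilation", 0.0),
                        s.get("name", ""),
                        bool(s.get("dilatable", True)),
                    )
                )
        return cls(segs, d["parent"], [bool(x) for x in d["lv_outlet"]])
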