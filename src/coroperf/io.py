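"""Configuration schema and file formats.

Run configurations are plain YAML/JSON mappings validated against nested
dataclasses (unknown or ill-typed fields raise :class:`SchemaError` with
the offending field path).  Meshes are written as ASCII XML VTU, networks
as polyline VTP (with enough cell data to reconstruct the network) and as
JSON; both round-trip losslessly through this module's readers.
"""

from __future__ import annotations

import dataclasses
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .myocardium import MyocardiumMesh
from .network import (
    CenterlineSegment,
    SyntheticSegment,
    VascularNetwork,
)


class SchemaError(ValueError):
    """Configuration does not match the expected schema."""


class ParseError(ValueError):
    """A file could not be parsed."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class FluidConfig:
    rho: float = 1.06  # g cm^-3
    mu: float = 0.053  # g cm^-1 s^-1


@dataclass
class PerfusionConfig:
    zeta: float = 3.41
    gamma: float = 0.75
    split_exponent: float = 2.7
    non_lv_fraction: float = 0.2
    hyperemia_factor: float = 4.0
    dilation_cap: float = 0.40
    dilation_increment: float = 0.01
    p_ref: float = 15.0
    p_floor: float = 60.0


@dataclass
class DarcyConfig:
    K: float = 2e-5  # cm^2 Pa^-1 s^-1
    p_bar: float = 15.0
    p_sink: float = 0.0
    laguerre_scale: float = 8.0  # territory weight scale (cm per cm diameter)


@dataclass
class CouplingSettings:
    relaxation: float = 0.5
    tol: float = 1e-3
    max_iterations: int = 50


@dataclass
class StenosisConfig:
    vessel: str = "LAD"
    location: float = 0.25
    reduction: float = 0.8
    length: float = 0.8


@dataclass
class FixtureConfig:
    n_term: int = 12_000
    target_elements: int = 500_000
    endo_axes: tuple = (2.5, 2.5, 6.0)
    epi_axes: tuple = (3.5, 3.5, 7.0)
    truncation_height: float = 0.0
    trim_threshold: float = 0.20
    stenosis: StenosisConfig | None = None


@dataclass
class RunConfig:
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    perfusion: PerfusionConfig = field(default_factory=PerfusionConfig)
    darcy: DarcyConfig = field(default_factory=DarcyConfig)
    coupling: CouplingSettings = field(default_factory=CouplingSettings)
    P_AO: float = 93.0
    seed: int = 0
    regime: str = "both"  # rest | hyperemia | both
    output_dir: str = "out"


def _from_mapping(cls, data: dict, path: str = ""):
    if data is None:
        return None
    if not isinstance(data, dict):
        raise SchemaError(f"{path or cls.__name__}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        here = f"{path}.{key}" if path else key
        if key not in fields:
            raise SchemaError(f"{here}: unknown field")
        ftype = fields[key].type
        nested = {
            "FixtureConfig": FixtureConfig,
            "FluidConfig": FluidConfig,
            "PerfusionConfig": PerfusionConfig,
            "DarcyConfig": DarcyConfig,
            "CouplingSettings": CouplingSettings,
            "StenosisConfig | None": StenosisConfig,
        }
        if isinstance(ftype, str) and ftype in nested:
            kwargs[key] = _from_mapping(nested[ftype], value, here)
        elif isinstance(value, dict):
            raise SchemaError(f"{here}: unexpected mapping")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise SchemaError(f"{path or cls.__name__}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    return _from_mapping(RunConfig, data)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


# ---------------------------------------------------------------------------
# Network JSON
# ---------------------------------------------------------------------------


def write_network_json(network: VascularNetwork, path) -> None:
    Path(path).write_text(
        json.dumps(network.to_dict(), sort_keys=True, separators=(",", ":"))
    )


def read_network_json(path) -> VascularNetwork:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno} col {exc.colno}: {exc.msg}") from exc
    return VascularNetwork.from_dict(data)


# ---------------------------------------------------------------------------
# VTU (mesh) writer/reader — ASCII XML unstructured grid
# ---------------------------------------------------------------------------


def _data_array(name: str, arr: np.ndarray, indent: str) -> str:
    arr = np.asarray(arr)
    comps = 1 if arr.ndim == 1 else arr.shape[1]
    dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
    body = " ".join(
        repr(float(v)) if dtype == "Float64" else str(int(v)) for v in arr.ravel()
    )
    return (
        f'{indent}<DataArray type="{dtype}" Name="{name}" '
        f'NumberOfComponents="{comps}" format="ascii">\n'
        f"{indent}  {body}\n{indent}</DataArray>\n"
    )


def write_vtu(
    mesh: MyocardiumMesh,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the tet mesh (plus optional fields) as ASCII XML VTU."""
    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "  <UnstructuredGrid>\n"
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
    ]
    parts.append("      <Points>\n")
    parts.append(_data_array("Points", mesh.nodes, "        "))
    parts.append("      </Points>\n      <Cells>\n")
    parts.append(_data_array("connectivity", mesh.tets.ravel(), "        "))
    parts.append(_data_array("offsets", 4 * np.arange(1, m + 1), "        "))
    parts.append(_data_array("types", np.full(m, 10, dtype=int), "        "))
    parts.append("      </Cells>\n")
    if point_data:
        parts.append("      <PointData>\n")
        for k, v in point_data.items():
            parts.append(_data_array(k, v, "        "))
        parts.append("      </PointData>\n")
    if cell_data:
        parts.append("      <CellData>\n")
        for k, v in cell_data.items():
            parts.append(_data_array(k, v, "        "))
        parts.append("      </CellData>\n")
    parts.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text("".join(parts))


def _parse_arrays(parent) -> dict:
    out = {}
    if parent is None:
        return out
    for da in parent.findall("DataArray"):
        name = da.get("Name")
        comps = int(da.get("NumberOfComponents", "1"))
        dtype = float if da.get("type") == "Float64" else int
        vals = np.array(da.text.split(), dtype=dtype)
        out[name] = vals.reshape(-1, comps) if comps > 1 else vals
    return out


def read_vtu(path) -> tuple[MyocardiumMesh, dict, dict]:
    """Read a VTU written by :func:`write_vtu`."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise ParseError(f"{path}: no <Piece> element")
    pts = _parse_arrays(piece.find("Points"))["Points"]
    cells = _parse_arrays(piece.find("Cells"))
    conn = cells["connectivity"].astype(int)
    tets = conn.reshape(-1, 4)
    mesh = MyocardiumMesh(nodes=pts, tets=tets)
    return mesh, _parse_arrays(piece.find("PointData")), _parse_arrays(
        piece.find("CellData")
    )


def write_stl(mesh: MyocardiumMesh, path, name: str = "wall") -> None:
    """Write the boundary surface as ASCII STL."""
    faces = mesh.boundary_faces()
    pts = mesh.nodes
    lines = [f"solid {name}"]
    for f in faces:
        a, b, c = pts[f[0]], pts[f[1]], pts[f[2]]
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n)
        n = n / nn if nn > 0 else n
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in (a, b, c):
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}\n")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# VTP (network polylines) writer/reader
# ---------------------------------------------------------------------------


def write_vtp(
    network: VascularNetwork,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the network as polylines with reconstruction cell data.

    ``point_data`` maps names to per-segment lists of per-node arrays;
    ``cell_data`` maps names to per-segment scalars.
    """
    points, conn, offsets = [], [], []
    area, pd_extra = [], {k: [] for k in (point_data or {})}
    kind, r0, dil, parent, lv, spacing, dilatable = [], [], [], [], [], [], []
    off = 0
    for i, seg in enumerate(network.segments):
        if seg.kind == "segmented":
            pts = seg.points
            a = seg.areas
            sp = seg.spacing
        else:
            pts = np.vstack([seg.start, seg.end])
            a = np.full(2, np.pi * seg.radius**2)
            sp = 0.0
        n = len(pts)
        points.append(pts)
        area.append(a)
        conn.extend(range(off, off + n))
        off += n
        offsets.append(off)
        kind.append(0 if seg.kind == "segmented" else 1)
        r0.append(getattr(seg, "r0", 0.0))
        dil.append(getattr(seg, "dilation", 0.0))
        parent.append(int(network.parent[i]))
        lv.append(int(network.lv_outlet[i]))
        spacing.append(sp)
        dilatable.append(int(getattr(seg, "dilatable", True)))
        for k, v in (point_data or {}).items():
            pd_extra[k].append(np.asarray(v[i], dtype=float))
    pts_all = np.vstack(points)
    n_pts, n_cells = len(pts_all), len(offsets)
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
        "  <PolyData>\n"
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfLines="{n_cells}">\n'
    ]
    parts.append("      <Points>\n")
    parts.append(_data_array("Points", pts_all, "        "))
    parts.append("      </Points>\n      <Lines>\n")
    parts.append(_data_array("connectivity", np.array(conn), "        "))
    parts.append(_data_array("offsets", np.array(offsets), "        "))
    parts.append("      </Lines>\n      <PointData>\n")
    parts.append(_data_array("area", np.concatenate(area), "        "))
    for k, v in pd_extra.items():
        parts.append(_data_array(k, np.concatenate(v), "        "))
    parts.append("      </PointData>\n      <CellData>\n")
    parts.append(_data_array("kind", np.array(kind), "        "))
    parts.append(_data_array("r0", np.array(r0), "        "))
    parts.append(_data_array("dilation", np.array(dil), "        "))
    parts.append(_data_array("parent", np.array(parent), "        "))
    parts.append(_data_array("lv_outlet", np.array(lv), "        "))
    parts.append(_data_array("spacing", np.array(spacing), "        "))
    parts.append(_data_array("dilatable", np.array(dilatable), "        "))
    for k, v in (cell_data or {}).items():
        parts.append(_data_array(k, np.asarray(v), "        "))
    parts.append("      </CellData>\n    </Piece>\n  </PolyData>\n</VTKFile>\n")
    Path(path).write_text("".join(parts))


def read_vtp(path) -> VascularNetwork:
    """Reconstruct a network from a VTP written by :func:`write_vtp`."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise ParseError(f"{path}: no <Piece> element")
    pts = _parse_arrays(piece.find("Points"))["Points"]
    lines = _parse_arrays(piece.find("Lines"))
    pdata = _parse_arrays(piece.find("PointData"))
    cdata = _parse_arrays(piece.find("CellData"))
    offsets = lines["offsets"].astype(int)
    conn = lines["connectivity"].astype(int)
    segs = []
    start = 0
    for ci, stop in enumerate(offsets):
        ids = conn[start:stop]
        start = stop
        if int(cdata["kind"][ci]) == 0:
            segs.append(
                CenterlineSegment(
                    pts[ids], pdata["area"][ids], float(cdata["spacing"][ci])
                )
            )
        else:
            segs.append(
                SyntheticSegment(
                    pts[ids[0]],
                    pts[ids[-1]],
                    float(cdata["r0"][ci]),
                    float(cdata["dilation"][ci]),
                    dilatable=bool(cdata["dilatable"][ci]),
                )
            )
    return VascularNetwork(
        segs, cdata["parent"].astype(int), cdata["lv_outlet"].astype(bool)
    )
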