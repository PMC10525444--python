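"""Plain-text readers and writers for surfaces, curvature maps and meshes.

Formats are deliberately simple and lossless:

* surface: CSV with header ``x_mm,y_mm,z_mm`` (15 significant digits) plus a
  ``.meta`` sidecar of ``key: value`` lines (zone_diameter, surface_side,
  label);
* curvature map: CSV matrix (meridians x radii) plus a sidecar carrying the
  polar axes, origin, zone and diopter convention;
* membrane mesh: OFF-like text (counts, coordinates, triangles) plus a
  per-element attribute CSV and a sidecar for material/boundary data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .curvature import CurvatureMap
from .mechanics import MembraneMesh, YeohMaterial
from .surfaces import SurfaceSampling

__all__ = [
    "ParseError",
    "read_surface",
    "write_surface",
    "read_map",
    "write_map",
    "read_mesh",
    "write_mesh",
]

_FMT = "{:.17g}"


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


def _write_sidecar(path: Path, meta: dict) -> None:
    lines = [f"{k}: {v}" for k, v in meta.items()]
    path.write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    if not path.exists():
        raise ParseError(f"missing metadata sidecar {path}")
    meta = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{i}: expected 'key: value', got {line!r}")
        k, v = line.split(":", 1)
        meta[k.strip()] = v.strip()
    return meta


def write_surface(surface: SurfaceSampling, path) -> Path:
    path = Path(path)
    rows = ["x_mm,y_mm,z_mm"]
    for x, y, z in zip(surface.x, surface.y, surface.z):
        rows.append(",".join(_FMT.format(v) for v in (x, y, z)))
    path.write_text("\n".join(rows) + "\n")
    _write_sidecar(path.with_suffix(path.suffix + ".meta"), {
        "zone_diameter": _FMT.format(surface.zone_diameter),
        "surface_side": surface.surface_side,
        "label": surface.label,
    })
    return path


def read_surface(path) -> SurfaceSampling:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "x_mm,y_mm,z_mm":
        raise ParseError(f"{path}:1: expected header 'x_mm,y_mm,z_mm'")
    xs, ys, zs = [], [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 3:
            raise ParseError(f"{path}:{i}: expected 3 cells, got {len(cells)}")
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric cell in {line!r}") from None
        if any(not np.isfinite(v) for v in vals):
            raise ParseError(f"{path}:{i}: non-finite value in {line!r}")
        xs.append(vals[0]); ys.append(vals[1]); zs.append(vals[2])
    meta = _read_sidecar(path.with_suffix(path.suffix + ".meta"))
    return SurfaceSampling(
        np.array(xs), np.array(ys), np.array(zs),
        surface_side=meta.get("surface_side", "anterior"),
        zone_diameter=float(meta.get("zone_diameter", "9.0")),
        label=meta.get("label", ""),
    )


def write_map(cmap: CurvatureMap, path) -> Path:
    path = Path(path)
    rows = [",".join(_FMT.format(v) for v in row) for row in cmap.values]
    path.write_text("\n".join(rows) + "\n")
    _write_sidecar(path.with_suffix(path.suffix + ".meta"), {
        "thetas_rad": ",".join(_FMT.format(v) for v in cmap.thetas),
        "rs_mm": ",".join(_FMT.format(v) for v in cmap.rs),
        "origin_mm": f"{_FMT.format(cmap.origin[0])},{_FMT.format(cmap.origin[1])}",
        "zone_diameter": _FMT.format(cmap.zone_diameter),
        "surface_side": cmap.surface_side,
        "units": "diopter (sagittal/axial, index step per surface side)",
    })
    return path


def read_map(path) -> CurvatureMap:
    path = Path(path)
    values = np.array([
        [float(c) for c in line.split(",")]
        for line in path.read_text().splitlines() if line.strip()
    ])
    meta = _read_sidecar(path.with_suffix(path.suffix + ".meta"))
    thetas = np.array([float(v) for v in meta["thetas_rad"].split(",")])
    rs = np.array([float(v) for v in meta["rs_mm"].split(",")])
    ox, oy = (float(v) for v in meta["origin_mm"].split(","))
    return CurvatureMap(values, thetas, rs, (ox, oy),
                        float(meta["zone_diameter"]), meta["surface_side"])


def write_mesh(mesh: MembraneMesh, path) -> Path:
    path = Path(path)
    lines = ["OFF", f"{mesh.n_nodes} {mesh.n_elements} 0"]
    for p in mesh.nodes:
        lines.append(" ".join(_FMT.format(v) for v in p))
    for t in mesh.triangles:
        lines.append("3 " + " ".join(str(i) for i in t))
    path.write_text("\n".join(lines) + "\n")
    attr = path.with_suffix(path.suffix + ".attr.csv")
    rows = ["element,thickness_um,stiffness_scale"]
    for e in range(mesh.n_elements):
        rows.append(f"{e},{_FMT.format(mesh.thickness_um[e])},"
                    f"{_FMT.format(mesh.stiffness_scale[e])}")
    attr.write_text("\n".join(rows) + "\n")
    _write_sidecar(path.with_suffix(path.suffix + ".meta"), {
        "material_C1_Pa": _FMT.format(mesh.material.C1),
        "material_C2_Pa": _FMT.format(mesh.material.C2),
        "material_C3_Pa": _FMT.format(mesh.material.C3),
        "material_d": _FMT.format(mesh.material.d),
        "fixed_nodes": ",".join(map(str, mesh.fixed_nodes.tolist())),
        "sliding_nodes": ",".join(map(str, mesh.sliding_nodes.tolist())),
    })
    return path


def read_mesh(path) -> MembraneMesh:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if lines[0].strip() != "OFF":
        raise ParseError(f"{path}:1: expected OFF header")
    n, m, _ = (int(v) for v in lines[1].split())
    nodes = np.array([[float(v) for v in lines[2 + i].split()] for i in range(n)])
    tris = np.array([[int(v) for v in lines[2 + n + i].split()[1:]] for i in range(m)])
    attr = path.with_suffix(path.suffix + ".attr.csv")
    rows = attr.read_text().splitlines()[1:]
    th = np.empty(m)
    sc = np.empty(m)
    for row in rows:
        e, t, s = row.split(",")
        th[int(e)] = float(t)
        sc[int(e)] = float(s)
    meta = _read_sidecar(path.with_suffix(path.suffix + ".meta"))
    mat = YeohMaterial(float(meta["material_C1_Pa"]), float(meta["material_C2_Pa"]),
                       float(meta["material_C3_Pa"]), float(meta["material_d"]))

    def _ids(key):
        v = meta.get(key, "")
        return np.array([int(s) for s in v.split(",") if s], dtype=int)

    return MembraneMesh(nodes, tris, mat, th, sc,
                        fixed_nodes=_ids("fixed_nodes"),
                        sliding_nodes=_ids("sliding_nodes"))
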