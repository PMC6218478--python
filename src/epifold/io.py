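"""Readers and writers: mesh JSON schema, tidy CSV tables, VTK/OBJ surfaces.

Schemas are versioned; every reader validates required fields and raises a
``SchemaError`` naming the offending field.  Mesh JSON round-trips vertex
positions bit-exactly (shortest-repr floats).

CSV formats
-----------
* recoil track: columns t, x1, y1, z1, x2, y2, z2 (separation derived).
* coupled series: columns cell_id, t, a_l, h [, group].
* cross section: columns cell_id, label, dist, layer {apical|basal},
  y0, z0, y1, z1 (one row per cell per layer).
* fold geometry: one row per ramp step with delta, raw and h_tissue-
  normalized parameters, energy and convergence diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ablation import RecoilTrack
from .equilibration import RampStep
from .fluctuation import CoupledSeries
from .geometry import Cell, TissueMesh
from .quantify import CrossSection, SectionCell

MESH_SCHEMA = "epifold-mesh/1"

__all__ = [
    "SchemaError",
    "save_mesh",
    "load_mesh",
    "save_track_csv",
    "load_track_csv",
    "save_series_csv",
    "load_series_csv",
    "save_section_csv",
    "load_section_csv",
    "ramp_to_frame",
    "export_vtk",
    "export_obj",
    "load_config",
    "save_config",
]


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, cols, what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{what}: missing required column {c!r}")


# ----------------------------------------------------------------------
# mesh JSON
# ----------------------------------------------------------------------
def save_mesh(mesh: TissueMesh, path) -> None:
    doc = {
        "schema": MESH_SCHEMA,
        "box": list(mesh.box),
        "n_apical": mesh.n_apical,
        "positions": mesh.positions.tolist(),
        "anchors": None if mesh.anchors is None else mesh.anchors.tolist(),
        "meta": mesh.meta,
        "cells": [
            {
                "id": c.id,
                "apical": c.apical.tolist(),
                "region": c.region,
                "row": c.row,
                "col": c.col,
                "target_volume": c.target_volume,
            }
            for c in mesh.cells
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_mesh(path) -> TissueMesh:
    doc = json.loads(Path(path).read_text())
    for fieldname in ("schema", "box", "n_apical", "positions", "cells"):
        if fieldname not in doc:
            raise SchemaError(f"mesh file: missing required field {fieldname!r}")
    if doc["schema"] != MESH_SCHEMA:
        raise SchemaError(f"mesh file: unsupported schema {doc['schema']!r}")
    na = doc["n_apical"]
    cells = [
        Cell(
            id=c["id"],
            apical=np.array(c["apical"]),
            basal=np.array(c["apical"]) + na,
            region=c.get("region", "neighbor"),
            row=c.get("row"),
            col=c.get("col"),
            target_volume=c.get("target_volume", 1.0),
        )
        for c in doc["cells"]
    ]
    mesh = TissueMesh(
        np.array(doc["positions"]),
        cells,
        tuple(doc["box"]),
        n_apical=na,
        anchors=None if doc.get("anchors") is None else np.array(doc["anchors"]),
    )
    mesh.meta = doc.get("meta", {})
    return mesh


# ----------------------------------------------------------------------
# tracks / series / sections
# ----------------------------------------------------------------------
def save_track_csv(track: RecoilTrack, path) -> None:
    df = pd.DataFrame(
        {
            "t": track.times,
            "x1": track.pos1[:, 0],
            "y1": track.pos1[:, 1],
            "z1": track.pos1[:, 2],
            "x2": track.pos2[:, 0],
            "y2": track.pos2[:, 1],
            "z2": track.pos2[:, 2],
            "separation": track.separation,
        }
    )
    df.to_csv(path, index=False)


def load_track_csv(path, t_ablation: float = 0.0) -> RecoilTrack:
    df = pd.read_csv(path)
    _require(df, ["t", "x1", "y1", "z1", "x2", "y2", "z2"], "recoil track CSV")
    return RecoilTrack(
        times=df["t"].to_numpy(),
        pos1=df[["x1", "y1", "z1"]].to_numpy(),
        pos2=df[["x2", "y2", "z2"]].to_numpy(),
        t_ablation=t_ablation,
    )


def save_series_csv(series: list[CoupledSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {"cell_id": s.cell_id, "t": s.times, "a_l": s.a_l, "h": s.h, "group": s.group}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_series_csv(path) -> list[CoupledSeries]:
    df = pd.read_csv(path)
    _require(df, ["cell_id", "t", "a_l", "h"], "coupled series CSV")
    out = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("t")
        out.append(
            CoupledSeries(
                times=sub["t"].to_numpy(),
                a_l=sub["a_l"].to_numpy(),
                h=sub["h"].to_numpy(),
                cell_id=int(cid),
                group=str(sub["group"].iloc[0]) if "group" in sub else "fold",
            )
        )
    return out


def save_section_csv(section: CrossSection, path) -> None:
    rows = []
    for c in section.cells:
        for layer, seg in (("apical", c.apical), ("basal", c.basal)):
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "label": c.label,
                    "dist": c.dist,
                    "layer": layer,
                    "y0": seg[0, 0],
                    "z0": seg[0, 1],
                    "y1": seg[1, 0],
                    "z1": seg[1, 1],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_section_csv(path) -> CrossSection:
    df = pd.read_csv(path)
    _require(df, ["cell_id", "label", "dist", "layer", "y0", "z0", "y1", "z1"], "section CSV")
    cells = []
    for cid, sub in df.groupby("cell_id", sort=True):
        segs = {}
        for _, r in sub.iterrows():
            segs[r["layer"]] = np.array([[r["y0"], r["z0"]], [r["y1"], r["z1"]]])
        if "apical" not in segs or "basal" not in segs:
            raise SchemaError(f"section CSV: cell {cid} lacks apical or basal row")
        first = sub.iloc[0]
        cells.append(
            SectionCell(
                cell_id=int(cid),
                label=str(first["label"]),
                dist=int(first["dist"]),
                apical=segs["apical"],
                basal=segs["basal"],
            )
        )
    return CrossSection(cells=cells)


def ramp_to_frame(steps: list[RampStep]) -> pd.DataFrame:
    """Tidy per-step table of a ramp: delta, geometry (raw and normalized),
    energy and convergence diagnostics."""
    rows = []
    for s in steps:
        row = {"delta": s.delta}
        row.update(s.geometry.as_dict())
        row.update(
            {
                "energy": s.energy,
                "max_force": s.max_force,
                "max_volume_violation": s.max_volume_violation,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# surface export (VTK legacy polydata / OBJ)
# ----------------------------------------------------------------------
def _surface_polygons(mesh: TissueMesh, surfaces=("apical", "basal", "lateral")):
    """Unwrapped polygons per surface; periodic faces get duplicated points
    so every polygon is contiguous."""
    from .geometry import unwrap_cycle

    polys = []
    for which in surfaces:
        if which == "apical":
            cycles = [c.apical for c in mesh.cells]
        elif which == "basal":
            cycles = [c.basal for c in mesh.cells]
        elif which == "lateral":
            cycles = list(mesh.lateral_faces)
        else:
            raise ValueError(f"unknown surface {which!r}")
        for cyc in cycles:
            polys.append(unwrap_cycle(mesh.positions[np.asarray(cyc)], mesh.box))
    return polys


def export_vtk(mesh: TissueMesh, path, surfaces=("apical", "basal", "lateral")) -> None:
    """Legacy ASCII VTK polydata of the selected surfaces."""
    polys = _surface_polygons(mesh, surfaces)
    pts = np.vstack(polys)
    lines = [
        "# vtk DataFile Version 3.0",
        "epifold tissue surfaces",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} double",
    ]
    lines += [f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in pts]
    size = sum(len(p) + 1 for p in polys)
    lines.append(f"POLYGONS {len(polys)} {size}")
    off = 0
    for p in polys:
        lines.append(str(len(p)) + " " + " ".join(str(off + i) for i in range(len(p))))
        off += len(p)
    Path(path).write_text("\n".join(lines) + "\n")


def export_obj(mesh: TissueMesh, path, surfaces=("apical", "basal", "lateral")) -> None:
    """Wavefront OBJ of the selected surfaces (1-based vertex indices)."""
    polys = _surface_polygons(mesh, surfaces)
    lines = ["# epifold tissue surfaces"]
    off = 1
    faces = []
    for p in polys:
        for v in p:
            lines.append(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
        faces.append("f " + " ".join(str(off + i) for i in range(len(p))))
        off += len(p)
    Path(path).write_text("\n".join(lines + faces) + "\n")


# ----------------------------------------------------------------------
# config
# ----------------------------------------------------------------------
def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
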