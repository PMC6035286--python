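"""File formats: mesh JSON, label-map TIFF, curve CSV, fit JSON.

Raster convention: row-major, origin top-left, pixel centers at integer
coordinates; mesh coordinates are continuous with y increasing downward
so mesh and raster space align.  Label maps use 0 for membrane and
background.  All CSV outputs carry a leading comment line naming columns
and units.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinematics import ElongationSeries
from .mesh import CellMesh
from .model import FitResult, ModelParams, MyosinSchedule

__all__ = [
    "MESH_SCHEMA_VERSION",
    "read_labelmap",
    "write_labelmap",
    "read_mesh",
    "write_mesh",
    "read_series_csv",
    "write_series_csv",
    "write_fit_json",
    "read_fit_json",
]

MESH_SCHEMA_VERSION = 1


# ----------------------------------------------------------------------
# Label maps (single-channel integer TIFF)
# ----------------------------------------------------------------------

def write_labelmap(labels: np.ndarray, path, px_size: float = 1.0) -> None:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label map must have an integer dtype")
    if labels.ndim != 2:
        raise ValueError("label map must be single-channel 2-D")
    tifffile.imwrite(
        str(path), labels, description=json.dumps({"px_size": px_size})
    )


def read_labelmap(path) -> tuple[np.ndarray, float]:
    """Read a label (or grayscale) raster; returns (array, px_size)."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim != 2:
        raise ValueError("expected a single-channel raster")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("expected an integer raster (got float)")
    px_size = None
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict) and "px_size" in meta:
                px_size = float(meta["px_size"])
        except ValueError:
            pass
    if px_size is None:
        warnings.warn("no pixel-size metadata; assuming 1.0 units/px",
                      stacklevel=2)
        px_size = 1.0
    return arr, px_size


# ----------------------------------------------------------------------
# Meshes (JSON, documented schema)
# ----------------------------------------------------------------------

def write_mesh(mesh: CellMesh, path) -> None:
    doc = {
        "schema_version": MESH_SCHEMA_VERSION,
        "frame_time": mesh.frame_time,
        "vertices": [
            {
                "position": mesh.vertex_positions[v].tolist(),
                "cells": sorted(int(c) for c in mesh.vertex_cells[v]),
                "interior": bool(mesh.vertex_interior[v]),
            }
            for v in range(len(mesh.vertex_positions))
        ],
        "cells": [
            {
                "id": int(mesh.cell_ids[i]),
                "centroid": mesh.centroids[i].tolist(),
                "loop": None if mesh.loops is None else list(map(int, mesh.loops[i])),
            }
            for i in range(mesh.n_cells)
        ],
        "adjacency": sorted([int(a), int(b)] for a, b in mesh.adjacency),
    }
    Path(path).write_text(json.dumps(doc))


def read_mesh(path) -> CellMesh:
    """Read a mesh JSON file; validates schema version and invariants."""
    doc = json.loads(Path(path).read_text())
    missing = [k for k in ("schema_version", "vertices", "cells", "adjacency")
               if k not in doc]
    if missing:
        raise ValueError(f"mesh file missing fields: {missing}")
    if doc["schema_version"] != MESH_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported mesh schema version {doc['schema_version']} "
            f"(supported: {MESH_SCHEMA_VERSION})"
        )
    adjacency = set()
    for pair in doc["adjacency"]:
        if len(pair) != 2 or pair[0] == pair[1]:
            raise ValueError(f"invalid adjacency pair {pair}")
        adjacency.add((min(pair), max(pair)))
    cell_ids = np.array([c["id"] for c in doc["cells"]], dtype=np.int64)
    positions = np.array([v["position"] for v in doc["vertices"]], dtype=float)
    if all(c.get("loop") is not None for c in doc["cells"]) and len(doc["cells"]):
        mesh = CellMesh.from_loops(
            cell_ids,
            [c["loop"] for c in doc["cells"]],
            positions,
            frame_time=float(doc.get("frame_time", 0.0)),
        )
        if mesh.adjacency != adjacency:
            raise ValueError(
                "adjacency inconsistent with polygon topology "
                "(asymmetric or stale adjacency record)"
            )
        mesh.validate()
        return mesh
    # measured mesh: no loops
    return CellMesh(
        cell_ids=cell_ids,
        centroids=np.array([c["centroid"] for c in doc["cells"]], dtype=float),
        vertex_positions=positions,
        vertex_cells=[frozenset(v["cells"]) for v in doc["vertices"]],
        vertex_interior=np.array([v.get("interior", True) for v in doc["vertices"]]),
        adjacency=adjacency,
        loops=None,
        frame_time=float(doc.get("frame_time", 0.0)),
    )


# ----------------------------------------------------------------------
# Curves (CSV with unit header comment)
# ----------------------------------------------------------------------

def write_series_csv(series: ElongationSeries, path) -> None:
    df = pd.DataFrame({"t": series.times, "Qxx": series.Qxx, "LmH": series.LmH})
    if series.sd_Qxx is not None:
        df["sd_Qxx"] = series.sd_Qxx
    if series.sd_LmH is not None:
        df["sd_LmH"] = series.sd_LmH
    with open(path, "w") as fh:
        fh.write("# t [h APF], Qxx [-], LmH [-]"
                 + (", sd columns [-]" if series.sd_Qxx is not None else "")
                 + "\n")
        df.to_csv(fh, index=False)


def read_series_csv(path) -> ElongationSeries:
    df = pd.read_csv(path, comment="#")
    return ElongationSeries(
        times=df["t"].to_numpy(),
        Qxx=df["Qxx"].to_numpy(),
        LmH=df["LmH"].to_numpy(),
        sd_Qxx=df["sd_Qxx"].to_numpy() if "sd_Qxx" in df else None,
        sd_LmH=df["sd_LmH"].to_numpy() if "sd_LmH" in df else None,
    )


# ----------------------------------------------------------------------
# Fit results (JSON)
# ----------------------------------------------------------------------

def write_fit_json(result: FitResult, path) -> None:
    doc = {
        "schedule": {
            "t0": result.schedule.t0,
            "t1": result.schedule.t1,
            "t2": result.schedule.t2,
            "magnitude": result.schedule.magnitude,
        },
        "Qxx0": result.Qxx0,
        "mode": result.mode,
        "grid": [
            {
                "tau_s": float(t),
                "zeta_over_2K": float(z),
                "lam": float(l),
                "sse": float(s),
                "converged": bool(c),
            }
            for t, z, l, s, c in zip(
                result.tau_grid, result.zeta_over_2K, result.lam,
                result.sse, result.converged,
            )
        ],
        "best": {
            "tau_s": result.best.tau_s,
            "zeta_over_2K": result.best.zeta_over_2K,
            "lam": result.best.lam,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit_json(path) -> tuple[ModelParams, MyosinSchedule]:
    doc = json.loads(Path(path).read_text())
    sched = MyosinSchedule(**doc["schedule"])
    best = ModelParams(**doc["best"])
    return best, sched
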