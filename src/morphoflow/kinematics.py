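"""Time-resolved analysis: shear rates, rearrangement tensor, event detection.

The tissue's pure-shear rate decomposes, frame by frame, into the rate of
mean cell-elongation change plus the rearrangement contribution:

    vxx(t) = d<Qxx>/dt + Rxx(t),      vxx = 1/2 d(L-H)/dt.

Rxx is thus computed as a residual; with the same finite-difference
operator applied to both series the decomposition identity holds exactly
at every timepoint.  Discrete T1 / T2 / rosette events are detected
topologically on tracked mesh series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CellMesh
from .morphometry import (
    TissueShape,
    mean_elongation,
    tissue_shape,
    triangulate,
)

__all__ = [
    "ElongationSeries",
    "measure_series",
    "EventRecord",
    "EventCounts",
    "natural_strain_series",
    "shear_rate",
    "elongation_rate",
    "rearrangement_shear",
    "detect_events",
]


@dataclass
class ElongationSeries:
    """Time courses of mean cell elongation <Qxx> and tissue strain L-H."""

    times: np.ndarray
    Qxx: np.ndarray
    LmH: np.ndarray
    sd_Qxx: np.ndarray | None = None
    sd_LmH: np.ndarray | None = None
    provenance: str = "measured"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Qxx = np.asarray(self.Qxx, dtype=float)
        self.LmH = np.asarray(self.LmH, dtype=float)
        if not (len(self.times) == len(self.Qxx) == len(self.LmH)):
            raise ValueError("series arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str  # "T1" | "T2" | "rosette"
    cell_ids: tuple[int, ...]


@dataclass
class EventCounts:
    """Counts and per-event records of discrete rearrangement events."""

    n_T1: int
    n_T2: int
    n_rosette: int
    cells_involved: int
    total_cells: int
    events: list[EventRecord] = field(default_factory=list)


def natural_strain_series(shapes: list[TissueShape]):
    """Per-frame natural strains L, H, L-H relative to the first frame."""
    if len(shapes) < 2:
        raise ValueError("need at least 2 frames")
    l0, h0 = shapes[0].l, shapes[0].h
    if l0 <= 0 or h0 <= 0:
        raise ValueError("non-positive reference dimensions")
    L = np.array([np.log(s.l / l0) for s in shapes])
    H = np.array([np.log(s.h / h0) for s in shapes])
    return L, H, L - H


def _ddt(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central differences, second-order one-sided at the boundaries."""
    return np.gradient(np.asarray(y, float), np.asarray(t, float), edge_order=2)


def shear_rate(LmH: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Tissue pure-shear rate vxx = 1/2 d(L-H)/dt."""
    if len(np.atleast_1d(LmH)) < 3:
        raise ValueError("need at least 3 timepoints")
    return 0.5 * _ddt(LmH, times)


def elongation_rate(series: ElongationSeries) -> np.ndarray:
    """d<Qxx>/dt with the same difference operator as shear_rate."""
    return _ddt(series.Qxx, series.times)


def rearrangement_shear(series: ElongationSeries) -> np.ndarray:
    """Rearrangement shear Rxx = 1/2 d(L-H)/dt - d<Qxx>/dt.

    Because an identical finite-difference operator acts on both series,
    vxx - d<Qxx>/dt - Rxx vanishes identically at every timepoint.
    """
    if len(series.times) < 3:
        raise ValueError("need at least 3 timepoints")
    return shear_rate(series.LmH, series.times) - elongation_rate(series)


def measure_series(frames: list[CellMesh]) -> ElongationSeries:
    """Measure <Qxx>(t) and (L-H)(t) on a tracked frame sequence.

    Each frame is triangulated independently; the natural-strain
    reference is the first frame, so LmH[0] = 0 by construction.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.array([f.frame_time for f in frames])
    qxx = np.array([mean_elongation(triangulate(f)).qxx for f in frames])
    shapes = [tissue_shape(f) for f in frames]
    _, _, lmh = natural_strain_series(shapes)
    return ElongationSeries(times=times, Qxx=qxx, LmH=lmh, provenance="measured")


# ----------------------------------------------------------------------
# Discrete event detection on tracked mesh series
# ----------------------------------------------------------------------

def _neighbor_map(mesh: CellMesh) -> dict[int, set[int]]:
    nb: dict[int, set[int]] = {int(c): set() for c in mesh.cell_ids}
    for a, b in mesh.adjacency:
        nb.setdefault(a, set()).add(b)
        nb.setdefault(b, set()).add(a)
    return nb


def detect_events(
    frames: list[CellMesh],
    rosette_min_cells: int = 5,
    t2_area_frames: int = 2,
    t2_area_tol: float = 1.05,
) -> EventCounts:
    """Detect T1, T2 and rosette events on a tracked frame sequence.

    T1: an adjacency pair (c, d) lost between consecutive frames while a
    complementary pair (a, b) of the same quartet (both a and b neighbors
    of c and d before the swap) is gained.

    T2: a cell id present in frame k and absent in k+1, whose area was
    non-increasing over the preceding ``t2_area_frames`` frames (guards
    against tracking loss misclassified as extrusion).

    Rosette: a vertex with >= ``rosette_min_cells`` incident cells in any
    frame (a fourfold vertex is a transient T1 intermediate, not a
    rosette); the same incident-cell set seen in consecutive frames is
    counted once.

    Requires persistent cell ids across frames.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    events: list[EventRecord] = []
    all_ids: set[int] = set()
    seen_rosettes: set[frozenset] = set()
    prev_rosettes: set[frozenset] = set()

    # areas by id per frame, for the T2 shrink guard (loop meshes only)
    areas_by_frame: list[dict[int, float]] = []
    for f in frames:
        try:
            ar = f.areas()
            areas_by_frame.append(
                {int(c): float(a) for c, a in zip(f.cell_ids, ar)}
            )
        except ValueError:
            areas_by_frame.append({})

    for k, f in enumerate(frames):
        all_ids.update(int(c) for c in f.cell_ids)
        ros_here = {
            frozenset(f.vertex_cells[v])
            for v in range(len(f.vertex_positions))
            if len(f.vertex_cells[v]) >= rosette_min_cells
        }
        for ros in ros_here - prev_rosettes:
            if ros not in seen_rosettes:
                events.append(
                    EventRecord(time=f.frame_time, kind="rosette",
                                cell_ids=tuple(sorted(ros)))
                )
                seen_rosettes.add(ros)
        prev_rosettes = ros_here

    for k in range(len(frames) - 1):
        f0, f1 = frames[k], frames[k + 1]
        ids0 = {int(c) for c in f0.cell_ids}
        ids1 = {int(c) for c in f1.cell_ids}
        if not ids0 or not ids1:
            raise ValueError("untracked series: frame without cell ids")
        nb0 = _neighbor_map(f0)
        lost = f0.adjacency - f1.adjacency
        gained = f1.adjacency - f0.adjacency

        # T2: disappearance with preceding monotone area decrease
        for cid in sorted(ids0 - ids1):
            ok = True
            hist = [
                areas_by_frame[j].get(cid)
                for j in range(max(0, k - t2_area_frames), k + 1)
            ]
            hist = [a for a in hist if a is not None]
            if len(hist) >= 2:
                ok = all(
                    b <= a * t2_area_tol for a, b in zip(hist[:-1], hist[1:])
                )
            if ok:
                events.append(
                    EventRecord(time=f1.frame_time, kind="T2", cell_ids=(cid,))
                )

        # T1: lost pair + gained complementary pair within one quartet
        for c, d in sorted(lost):
            if c not in ids1 or d not in ids1:
                continue  # disappearance, not an exchange
            common = nb0.get(c, set()) & nb0.get(d, set())
            for a, b in sorted(gained):
                if {a, b} <= common:
                    events.append(
                        EventRecord(
                            time=f1.frame_time,
                            kind="T1",
                            cell_ids=tuple(sorted((a, b, c, d))),
                        )
                    )
                    break

    involved = set()
    for e in events:
        involved.update(e.cell_ids)
    return EventCounts(
        n_T1=sum(e.kind == "T1" for e in events),
        n_T2=sum(e.kind == "T2" for e in events),
        n_rosette=sum(e.kind == "rosette" for e in events),
        cells_involved=len(involved),
        total_cells=len(all_ids),
        events=events,
    )
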