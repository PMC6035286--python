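"""Synthetic epithelium generators.

Everything the pipeline consumes can be generated here with known ground
truth: polygonal meshes (perturbed hexagonal Voronoi), tracked mesh time
series realizing the continuum kinematics (affine convergent-extension
shear plus planted T1 intercalations), rendered membrane images with
label ground truth, junctional intensities with tunable PD/AP polarity,
1-D surface-coverage profiles, and noisy model-generated elongation
curves for parameter-recovery studies.

Seeds are explicit everywhere; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import find_boundaries

from .kinematics import ElongationSeries, EventRecord
from .mesh import (
    CellMesh,
    apply_pure_shear,
    apply_t1,
    make_cell_mesh,
    merge_vertices,
    remove_cell,
    shrink_cell,
    t1_candidate_edges,
)
from .model import ModelParams, MyosinSchedule, predict_LmH, solve_Qxx_closed
from .morphometry import junction_segments, mean_elongation, triangulate

__all__ = [
    "MeshSeries",
    "SeriesGroundTruth",
    "simulate_tissue_series",
    "plant_event_series",
    "render_membrane_image",
    "synth_elongation_data",
    "synth_junction_intensities",
    "synth_surface_profile",
]


@dataclass
class SeriesGroundTruth:
    """What the generator actually did, for closed-loop checks."""

    sxx_per_interval: np.ndarray
    rearrangement_rate: np.ndarray  # imposed lambda*qbar per interval [1/h]
    events: list[EventRecord] = field(default_factory=list)
    params: ModelParams | None = None
    schedule: MyosinSchedule | None = None
    Qxx0: float = 0.0


@dataclass
class MeshSeries:
    """Tracked time sequence of cell meshes with generation ground truth."""

    frames: list[CellMesh]
    ground_truth: SeriesGroundTruth

    @property
    def times(self) -> np.ndarray:
        t = np.array([f.frame_time for f in self.frames])
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        return t


def _measured_qxx(mesh: CellMesh) -> float:
    return mean_elongation(triangulate(mesh)).qxx


def simulate_tissue_series(
    schedule: MyosinSchedule,
    params: ModelParams,
    Qxx0: float = 0.0,
    dt: float = 0.25,
    t_end: float = 7.0,
    seed: int = 0,
    n_cells: int = 200,
    disorder: float = 0.25,
    max_candidates: int = 16,
) -> MeshSeries:
    """Tracked mesh series realizing the continuum kinematics.

    Per time interval the generator (i) applies the affine pure shear
    that makes the tissue strain L-H track the model solution and (ii)
    plants T1 neighbor exchanges until the *measured* (triangulation)
    mean elongation matches the model's <Qxx>, so that the shear excess
    carried by rearrangements approximates Rxx = lambda * qxx.  Every
    applied shear and event is recorded in the ground truth.

    The T1 budget is measurement-guided: candidate swaps are scored by
    the mean-elongation jump they produce and greedily selected to close
    the gap, which keeps the closed loop honest to the discretization
    (no analytic shortcut stands in for the measurement).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end <= schedule.t0:
        raise ValueError("t_end must exceed the schedule start t0")
    times = schedule.t0 + dt * np.arange(int(np.floor((t_end - schedule.t0) / dt)) + 1)
    q_model = solve_Qxx_closed(params, Qxx0, schedule, times)
    if np.max(np.abs(q_model)) > 0.95:
        raise ValueError(
            "parameters drive |Qxx| toward 1; the triangulation degenerates"
        )
    lmh_model = predict_LmH(params, schedule, times, Qxx0)

    rng = np.random.default_rng(seed)
    mesh = make_cell_mesh(n_cells, disorder, seed=int(rng.integers(2**31)))
    # pre-shear so the measured initial elongation sits at Qxx0
    for _ in range(2):
        mesh = apply_pure_shear(mesh, Qxx0 - _measured_qxx(mesh))
    mesh.frame_time = float(times[0])

    frames = [mesh.clone()]
    events: list[EventRecord] = []
    sxx_list, rr_list = [], []
    for k in range(len(times) - 1):
        t_next = float(times[k + 1])
        s_tot = 0.5 * (lmh_model[k + 1] - lmh_model[k])
        r_int = s_tot - (q_model[k + 1] - q_model[k])  # = lambda * int q dt
        mesh = apply_pure_shear(mesh, s_tot)
        mesh.frame_time = t_next
        sxx_list.append(s_tot)
        rr_list.append(r_int / dt)

        if abs(r_int) > 1e-9:
            target = float(q_model[k + 1])
            used_cells: set[int] = set()
            for _ in range(60):  # per-interval event cap
                deficit = _measured_qxx(mesh) - target
                if abs(deficit) < 1e-3:
                    break
                edges = [
                    e
                    for e in t1_candidate_edges(mesh)
                    if not (set(mesh.vertex_cells[e[0]] | mesh.vertex_cells[e[1]])
                            & used_cells)
                ]
                if not edges:
                    break
                order = rng.permutation(len(edges))[:max_candidates]
                best = None
                for ei in order:
                    try:
                        trial = apply_t1(mesh, edges[ei])
                    except ValueError:
                        continue
                    jump = _measured_qxx(trial) - target
                    if abs(jump) < abs(deficit) and (
                        best is None or abs(jump) < abs(best[1])
                    ):
                        best = (trial, jump, edges[ei])
                        if abs(jump) < 0.25 * abs(deficit):
                            break
                if best is None:
                    break
                trial, _, edge = best
                quartet = tuple(
                    sorted(mesh.vertex_cells[edge[0]] | mesh.vertex_cells[edge[1]])
                )
                used_cells.update(quartet)
                mesh = trial
                mesh.frame_time = t_next
                events.append(EventRecord(time=t_next, kind="T1", cell_ids=quartet))
        frames.append(mesh.clone())

    gt = SeriesGroundTruth(
        sxx_per_interval=np.array(sxx_list),
        rearrangement_rate=np.array(rr_list),
        events=events,
        params=params,
        schedule=schedule,
        Qxx0=Qxx0,
    )
    return MeshSeries(frames=frames, ground_truth=gt)


def plant_event_series(
    n_cells: int = 150,
    disorder: float = 0.2,
    n_frames: int = 8,
    dt: float = 0.25,
    n_t1: int = 4,
    n_t2: int = 3,
    n_rosette: int = 3,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> MeshSeries:
    """Tracked series with a planted plan of T1 / T2 / rosette events.

    Events use disjoint cell sets so each leaves an unambiguous
    topological signature.  ``jitter_sd`` (tissue units; a cell diameter
    is ~1) adds per-frame Gaussian jitter to vertex positions,
    emulating centroid measurement noise.  T2 cells shrink monotonically
    over the two frames preceding extrusion.
    """
    rng = np.random.default_rng(seed)
    mesh = make_cell_mesh(n_cells, disorder, seed=int(rng.integers(2**31)))
    mesh.frame_time = 0.0

    n_events = n_t1 + n_t2 + n_rosette
    if n_frames < 4:
        raise ValueError("need at least 4 frames")
    event_frames = 2 + rng.integers(0, n_frames - 3, size=n_events)
    kinds = ["T1"] * n_t1 + ["T2"] * n_t2 + ["rosette"] * n_rosette
    plan = sorted(zip(event_frames.tolist(), kinds))

    used_cells: set[int] = set()
    events: list[EventRecord] = []
    t2_shrinking: dict[int, int] = {}  # cell id -> frames until removal

    # pre-assign T2 cells so shrinkage can start ahead of the event frame
    t2_sched: dict[int, list[int]] = {}
    interior_cells = sorted(
        {
            c
            for v in range(len(mesh.vertex_positions))
            if mesh.vertex_interior[v]
            for c in mesh.vertex_cells[v]
        }
    )
    for fr, kind in plan:
        if kind != "T2":
            continue
        choices = [
            c for c in interior_cells
            if c not in used_cells and not (mesh.neighbors(c) & used_cells)
        ]
        cid = int(choices[rng.integers(len(choices))])
        used_cells.add(cid)
        used_cells.update(mesh.neighbors(cid))
        t2_sched.setdefault(fr, []).append(cid)

    frames = []
    for k in range(n_frames):
        # begin shrinking two frames before each T2 removal
        for fr, cids in t2_sched.items():
            if fr - 2 <= k < fr:
                for cid in cids:
                    mesh = shrink_cell(mesh, cid, 0.6)
        for fr, kind in plan:
            if fr != k:
                continue
            if kind == "T1":
                edges = [
                    e
                    for e in t1_candidate_edges(mesh)
                    if not (
                        set(mesh.vertex_cells[e[0]] | mesh.vertex_cells[e[1]])
                        & used_cells
                    )
                ]
                if not edges:
                    continue
                edge = edges[rng.integers(len(edges))]
                quartet = tuple(
                    sorted(mesh.vertex_cells[edge[0]] | mesh.vertex_cells[edge[1]])
                )
                try:
                    mesh = apply_t1(mesh, edge)
                except ValueError:
                    continue
                used_cells.update(quartet)
                events.append(
                    EventRecord(time=k * dt, kind="T1", cell_ids=quartet)
                )
            elif kind == "T2":
                for cid in t2_sched.pop(fr, []):
                    involved = tuple(sorted({cid}))
                    mesh = remove_cell(mesh, cid)
                    events.append(
                        EventRecord(time=k * dt, kind="T2", cell_ids=involved)
                    )
        mesh.frame_time = k * dt

        frame = mesh.clone()
        # rosettes live on the frame copy only: transient by construction
        for fr, kind in plan:
            if fr == k and kind == "rosette":
                frame = _plant_rosette(frame, rng, used_cells, events, k * dt)
        if jitter_sd > 0:
            jit = rng.normal(0.0, jitter_sd, size=frame.vertex_positions.shape)
            frame = CellMesh.from_loops(
                frame.cell_ids,
                frame.loops,
                frame.vertex_positions + jit,
                frame_time=frame.frame_time,
            )
        frames.append(frame)

    gt = SeriesGroundTruth(
        sxx_per_interval=np.zeros(n_frames - 1),
        rearrangement_rate=np.zeros(n_frames - 1),
        events=events,
    )
    return MeshSeries(frames=frames, ground_truth=gt)


def _plant_rosette(frame, rng, used_cells, events, time):
    """Merge a vertex with two edge-neighbors to seed a >=5-cell rosette."""
    emap: dict[int, set[int]] = {}
    for loop in frame.loops:
        for i in range(len(loop)):
            u, v = loop[i], loop[(i + 1) % len(loop)]
            emap.setdefault(u, set()).add(v)
            emap.setdefault(v, set()).add(u)
    verts = [
        v
        for v in range(len(frame.vertex_positions))
        if frame.vertex_interior[v]
        and len(frame.vertex_cells[v]) == 3
        and not (frame.vertex_cells[v] & used_cells)
    ]
    rng.shuffle(verts)
    for v in verts:
        nbrs = [
            w
            for w in emap.get(v, set())
            if frame.vertex_interior[w]
            and len(frame.vertex_cells[w]) == 3
            and not (frame.vertex_cells[w] & used_cells)
        ]
        if len(nbrs) < 2:
            continue
        try:
            merged = merge_vertices(frame, v, nbrs[0])
            merged = merge_vertices(merged, v, nbrs[1])
        except ValueError:
            continue
        ros_cells = merged.vertex_cells[v]
        if len(ros_cells) < 5:
            continue
        used_cells.update(ros_cells)
        events.append(
            EventRecord(time=time, kind="rosette",
                        cell_ids=tuple(sorted(ros_cells)))
        )
        return merged
    return frame


# ----------------------------------------------------------------------
# Membrane-image rendering
# ----------------------------------------------------------------------

def render_membrane_image(
    mesh: CellMesh,
    px_per_unit: float = 32.0,
    membrane_width_px: float = 2.0,
    snr: float = np.inf,
    seed: int = 0,
    pad_units: float = 0.5,
    max_pixels: int = 16_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a fluorescent-membrane image plus ground-truth label raster.

    The membrane skeleton (all cell-cell and cell-exterior boundaries)
    carries a Gaussian intensity ridge of ~``membrane_width_px``; cell
    interiors are dark.  Noise is Gaussian read noise plus Poisson shot
    noise with variance split evenly at the membrane, where ``snr`` =
    membrane amplitude / total noise sd.  Labels are ``cell_id + 1``
    (uint16), 0 on membrane and exterior.  Bit-identical for fixed seed.
    """
    if px_per_unit <= 0:
        raise ValueError("px_per_unit must be positive")
    if membrane_width_px < 1:
        raise ValueError("membrane_width_px must be >= 1")
    xmin, ymin, xmax, ymax = mesh.bounds()
    x0, y0 = xmin - pad_units, ymin - pad_units
    W = int(np.ceil((xmax - xmin + 2 * pad_units) * px_per_unit))
    H = int(np.ceil((ymax - ymin + 2 * pad_units) * px_per_unit))
    if H * W > max_pixels:
        raise ValueError(f"raster {H}x{W} exceeds the size cap {max_pixels}")

    labels = np.zeros((H, W), dtype=np.int32)
    for idx, poly in enumerate(mesh.polygons()):
        px = (poly - np.array([x0, y0])) * px_per_unit - 0.5
        rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=labels.shape)
        labels[rr, cc] = int(mesh.cell_ids[idx]) + 1

    membrane = find_boundaries(labels, mode="thick")
    dist = ndi.distance_transform_edt(~membrane)
    sigma = max(membrane_width_px / 2.0, 0.5)
    amp = 1.0
    img = 0.1 + amp * np.exp(-0.5 * (dist / sigma) ** 2)

    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive (or inf for noiseless)")
        rng = np.random.default_rng(seed)
        peak = 0.1 + amp
        gain = 2.0 * peak * snr**2 / amp**2  # shot-noise var = img/gain
        read_sd = amp / (np.sqrt(2.0) * snr)
        img = rng.poisson(img * gain).astype(float) / gain
        img = img + rng.normal(0.0, read_sd, size=img.shape)

    img16 = np.clip(img / 2.0, 0.0, 1.0)
    img16 = (img16 * 60000).astype(np.uint16)

    labels_gt = labels.copy()
    labels_gt[membrane] = 0
    present = set(np.unique(labels_gt)) - {0}
    if len(present) != mesh.n_cells:
        raise ValueError(
            "some cells rendered without interior pixels; increase px_per_unit"
        )
    return img16, labels_gt.astype(np.uint16)


# ----------------------------------------------------------------------
# Curves, junction intensities, surface profiles
# ----------------------------------------------------------------------

def synth_elongation_data(
    params: ModelParams,
    schedule: MyosinSchedule,
    Qxx0: float,
    noise_sd: float,
    timepoints,
    seed: int = 0,
) -> ElongationSeries:
    """Model-generated elongation curves with i.i.d. Gaussian noise.

    (L-H)(t0) is pinned to 0 (the natural-strain reference is the first
    frame, so its strain is zero by definition, noise-free).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints")
    qxx = solve_Qxx_closed(params, Qxx0, schedule, t)
    lmh = predict_LmH(params, schedule, t, Qxx0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        qxx = qxx + rng.normal(0.0, noise_sd, size=len(t))
        lmh = lmh + rng.normal(0.0, noise_sd, size=len(t))
    lmh[0] = 0.0  # strain reference is the first frame
    return ElongationSeries(times=t, Qxx=qxx, LmH=lmh, provenance="synthetic")


def synth_junction_intensities(
    mesh: CellMesh,
    pd_ap_ratio: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    angle_threshold_deg: float = 30.0,
) -> dict[tuple[int, int], float]:
    """Per-junction intensities with a planted AP/PD polarity ratio.

    Junctions within ``angle_threshold_deg`` of the AP (y) axis receive
    intensity ``pd_ap_ratio``; those near the PD (x) axis receive 1;
    oblique junctions interpolate smoothly.  Multiplicative Gaussian
    noise keeps the expected class means (hence the expected polarity
    ratio) unchanged.
    """
    if pd_ap_ratio <= 0:
        raise ValueError("pd_ap_ratio must be positive")
    rng = np.random.default_rng(seed)
    segs = junction_segments(mesh)
    out: dict[tuple[int, int], float] = {}
    for pair, seg in segs.items():
        d = seg[1] - seg[0]
        ang = np.degrees(np.arctan2(d[1], d[0])) % 180.0
        ang = min(ang, 180.0 - ang)  # fold to [0, 90]; 90 = AP-aligned
        if ang >= 90.0 - angle_threshold_deg:
            base = pd_ap_ratio
        elif ang <= angle_threshold_deg:
            base = 1.0
        else:
            w = np.sin(np.radians(ang)) ** 2
            base = 1.0 + (pd_ap_ratio - 1.0) * w
        if noise_sd > 0:
            base *= 1.0 + rng.normal(0.0, noise_sd)
        out[pair] = float(max(base, 1e-6))
    return out


def synth_surface_profile(
    coverage_frac: float,
    n_samples: int = 1000,
    contrast: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.05,
    max_segments: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D surface intensity with contiguous high-intensity covered runs.

    Returns (profile, covered_mask); covered samples sit at ``contrast``
    times the background level, each sample carrying multiplicative
    Gaussian noise of relative sd ``noise_sd``.
    """
    if not 0.0 <= coverage_frac <= 1.0:
        raise ValueError("coverage_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cov = int(round(coverage_frac * n_samples))
    covered = np.zeros(n_samples, dtype=bool)
    if n_cov >= n_samples:
        covered[:] = True
    elif n_cov > 0:
        n_seg = int(rng.integers(1, max_segments + 1))
        n_seg = min(n_seg, n_cov)
        cuts = np.sort(rng.choice(np.arange(1, n_cov), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
        lengths = np.diff(np.concatenate([[0], cuts, [n_cov]])).astype(int)
        free = n_samples - n_cov
        gaps = rng.multinomial(free, np.ones(n_seg + 1) / (n_seg + 1))
        pos = 0
        for g, ln in zip(gaps[:-1], lengths):
            pos += int(g)
            covered[pos : pos + ln] = True
            pos += ln
    levels = np.where(covered, contrast, 1.0).astype(float)
    profile = levels * (1.0 + rng.normal(0.0, noise_sd, size=n_samples))
    return profile, covered
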