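"""Membrane-image segmentation: edge-preserving smoothing, ridge
enhancement, seeded watershed.

The chain mirrors classical fluorescent-membrane pipelines: an
exponential edge-preserving smoother (Shen-Castan ISEF) suppresses
pixel noise while keeping membrane edges sharp; a principal-curvature
(Hessian) ridge filter highlights bright membrane lines; a watershed
seeded at regional minima of the ridge map (after h-minima suppression)
partitions the image into cells, with undersized basins merged into
their lowest-barrier neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter, lfilter_zi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.measure import label as cc_label
from skimage.morphology import h_minima, local_minima
from skimage.segmentation import watershed

__all__ = [
    "SegmentationConfig",
    "smooth_edges",
    "ridge_enhance",
    "watershed_cells",
    "segment",
    "match_labels",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    alpha : ISEF smoothing strength (larger = smoother), > 0.
    ridge_scale : Gaussian scale of the Hessian ridge filter [px].
    h_minima_frac : minima suppression depth, fraction of ridge range.
    min_cell_area_px : basins smaller than this are merged away.
    """

    alpha: float = 3.0
    ridge_scale: float = 2.0
    h_minima_frac: float = 0.08
    min_cell_area_px: int = 300


def _isef_1d(x: np.ndarray, b: float, axis: int) -> np.ndarray:
    """Symmetric first-order exponential filter along one axis.

    Impulse response c*b^|n| with c = (1-b)/(1+b): unit DC gain, applied
    as a causal + anticausal recursive pair (the canonical ISEF form).
    """
    c = (1.0 - b) / (1.0 + b)
    x = np.moveaxis(x, axis, -1)
    zi = lfilter_zi([c], [1.0, -b])  # steady-state init: constants are fixed
    fwd, _ = lfilter([c], [1.0, -b], x, axis=-1, zi=zi * x[..., :1])
    rev = x[..., ::-1]
    bwd, _ = lfilter([c], [1.0, -b], rev, axis=-1, zi=zi * rev[..., :1])
    y = fwd + bwd[..., ::-1] - c * x
    return np.moveaxis(y, -1, axis)


def smooth_edges(image: np.ndarray, alpha: float = 2.0) -> np.ndarray:
    """Shen-Castan (ISEF) edge-preserving smoothing.

    Separable symmetric exponential smoothing with decay b =
    exp(-1/alpha); the heavy-tailed exponential kernel averages flat
    regions strongly while attenuating step edges far less than a
    Gaussian of comparable support.  Preserves the input intensity range
    (positive unit-mass kernel) and fixes constant images.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    b = float(np.exp(-1.0 / alpha))
    # reflect-pad so borders see a full kernel support
    pad = max(4, int(8 * alpha))
    padded = np.pad(img, pad, mode="reflect")
    out = _isef_1d(_isef_1d(padded, b, axis=0), b, axis=1)
    return out[pad:-pad, pad:-pad]


def ridge_enhance(image: np.ndarray, scale: float = 2.0) -> np.ndarray:
    """Bright-ridge strength: largest negative Hessian eigenvalue.

    The Hessian is taken at Gaussian scale ``scale``; on a bright line
    the cross-line curvature is strongly negative, so the response
    -min_eigval (clipped at 0) peaks on membrane centerlines and
    vanishes on flat regions.  Rotationally equivariant.
    """
    if scale < 0.5:
        raise ValueError("scale must be >= 0.5 px")
    img = np.asarray(image, dtype=float)
    H = hessian_matrix(
        img, sigma=scale, order="rc", use_gaussian_derivatives=True,
        mode="reflect",
    )
    eigs = hessian_matrix_eigvals(H)  # sorted descending
    return np.maximum(0.0, -eigs[-1]) * scale**2  # gamma-normalized


def _merge_small(
    basins: np.ndarray, ridge: np.ndarray, min_area: int
) -> dict[int, int]:
    """Union-find merge map: small basins -> lowest-barrier neighbor."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    # barrier height between basin pairs = min ridge value on their contact
    pairs: dict[tuple[int, int], float] = {}
    for a, b, r in (
        (basins[:, :-1], basins[:, 1:], np.minimum(ridge[:, :-1], ridge[:, 1:])),
        (basins[:-1, :], basins[1:, :], np.minimum(ridge[:-1, :], ridge[1:, :])),
    ):
        m = a != b
        for p, q, v in zip(a[m].ravel(), b[m].ravel(), r[m].ravel()):
            key = (int(min(p, q)), int(max(p, q)))
            if v < pairs.get(key, np.inf):
                pairs[key] = float(v)

    sizes = dict(zip(*np.unique(basins, return_counts=True)))
    changed = True
    while changed:
        changed = False
        roots = {find(l) for l in sizes}
        root_size: dict[int, int] = {}
        for l, s in sizes.items():
            root_size[find(l)] = root_size.get(find(l), 0) + int(s)
        for r0 in sorted(roots, key=lambda r: root_size[r]):
            if root_size[r0] >= min_area:
                continue
            best, best_v = None, np.inf
            for (p, q), v in pairs.items():
                rp, rq = find(p), find(q)
                if rp == rq:
                    continue
                if rp == r0 and v < best_v:
                    best, best_v = rq, v
                elif rq == r0 and v < best_v:
                    best, best_v = rp, v
            if best is not None:
                parent[r0] = best
                changed = True
                break
    return {int(l): find(int(l)) for l in sizes}


def watershed_cells(
    ridge: np.ndarray,
    min_cell_area_px: int = 300,
    h_minima_frac: float = 0.08,
) -> np.ndarray:
    """Watershed of the ridge map seeded at suppressed regional minima.

    Basins smaller than ``min_cell_area_px`` are merged into the
    neighbor behind their lowest ridge barrier; the final transform is
    re-run with merged markers so watershed lines (label 0) separate
    exactly the surviving basins.
    """
    ridge = np.asarray(ridge, dtype=float)
    if np.any(ridge < 0):
        raise ValueError("ridge map must be non-negative")
    rng_span = float(ridge.max() - ridge.min())
    if rng_span == 0:
        return np.ones_like(ridge, dtype=np.int32)
    h = h_minima_frac * rng_span
    minima = h_minima(ridge, h) if h > 0 else local_minima(ridge)
    markers = cc_label(minima, connectivity=2)
    if markers.max() == 0:
        return np.ones_like(ridge, dtype=np.int32)
    basins = watershed(ridge, markers)
    merge = _merge_small(basins, ridge, min_cell_area_px)
    if len(set(merge.values())) == 1:
        return np.full_like(basins, 1, dtype=np.int32)
    if any(k != v for k, v in merge.items()):
        remap = np.zeros(basins.max() + 1, dtype=np.int32)
        for k, v in merge.items():
            remap[k] = v
        markers = remap[markers]
        basins = watershed(ridge, markers, watershed_line=True)
    else:
        basins = watershed(ridge, markers, watershed_line=True)
    return basins.astype(np.int32)


def segment(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Full chain: smooth -> ridge -> watershed.  Returns a label map."""
    cfg = config or SegmentationConfig()
    sm = smooth_edges(image, alpha=cfg.alpha)
    ridge = ridge_enhance(sm, scale=cfg.ridge_scale)
    return watershed_cells(
        ridge,
        min_cell_area_px=cfg.min_cell_area_px,
        h_minima_frac=cfg.h_minima_frac,
    )


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

def match_labels(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.8
) -> dict:
    """Greedy 1:1 matching of ground-truth to predicted regions by IoU.

    Returns matched pair list, the matched fraction of ground-truth
    cells, and the mean IoU of matches.  Label 0 (membrane/background)
    is excluded on both sides.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("label maps must share a shape")
    mask = (gt > 0) & (pred > 0)
    pair_ids, pair_counts = np.unique(
        np.stack([gt[mask], pred[mask]]), axis=1, return_counts=True
    )
    gt_sizes = dict(zip(*np.unique(gt[gt > 0], return_counts=True)))
    pr_sizes = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    cands = []
    for (g, p), inter in zip(pair_ids.T, pair_counts):
        union = gt_sizes[g] + pr_sizes[p] - inter
        cands.append((inter / union, int(g), int(p)))
    cands.sort(reverse=True)
    used_g, used_p = set(), set()
    matches = []
    for iou, g, p in cands:
        if iou < iou_threshold or g in used_g or p in used_p:
            continue
        matches.append((g, p, float(iou)))
        used_g.add(g)
        used_p.add(p)
    n_gt = len(gt_sizes)
    return {
        "matches": matches,
        "n_gt": n_gt,
        "n_pred": len(pr_sizes),
        "matched_fraction": len(matches) / n_gt if n_gt else 0.0,
        "mean_iou": float(np.mean([m[2] for m in matches])) if matches else 0.0,
    }
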