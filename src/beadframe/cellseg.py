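"""Nucleus/cell segmentation of 3-channel probability maps and feature extraction.

The probability maps (per-pixel background / nucleus / cytoplasm class
probabilities, produced upstream by a trained network and treated here as an
input contract) are segmented classically: Gaussian smoothing, global (Otsu)
thresholding, distance-transform local maxima to deblend touching nuclei,
and watershed. Whole cells are then segmented by the same procedure on the
sum of the nuclear and cytoplasmic channels, but with the nuclei fed as
watershed seeds — so the cell count equals the nucleus count and each pair
shares its centroid. Per-cell features are mean intensities over every
channel of the multiplexed cube plus areas from the zeroth image moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImcTileSet",
    "tile_image",
    "normalize_channel",
    "segment_nuclei",
    "segment_cells",
    "extract_features",
    "evaluate_segmentation",
    "detection_rate",
]


@dataclass
class ImcTileSet:
    tiles: list[np.ndarray]
    origins: list[tuple[int, int]]       # (x, y)
    tile_size: int
    stride: int
    image_shape: tuple[int, int]


def _tile_origins(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    out = list(range(0, extent - tile + 1, stride))
    if out[-1] != extent - tile:
        out.append(extent - tile)  # final tile shifted inward to fit
    return out


def tile_image(cube: np.ndarray, tile_size: int = 256, stride: int = 50) -> ImcTileSet:
    """Cut a (C, H, W) cube into overlapping tiles with full edge coverage.

    Channel order is fixed upstream (nuclear first, cytoplasm/membrane
    second). Images smaller than a tile yield a single zero-padded tile with
    a warning.
    """
    cube = np.asarray(cube)
    if cube.ndim == 2:
        cube = cube[None]
    _c, h, w = cube.shape
    if h < tile_size or w < tile_size:
        warnings.warn("image smaller than tile size; zero-padding a single tile")
        pad = np.zeros((cube.shape[0], max(h, tile_size), max(w, tile_size)),
                       dtype=cube.dtype)
        pad[:, :h, :w] = cube
        return ImcTileSet(tiles=[pad], origins=[(0, 0)], tile_size=tile_size,
                          stride=stride, image_shape=(h, w))
    tiles, origins = [], []
    for oy in _tile_origins(h, tile_size, stride):
        for ox in _tile_origins(w, tile_size, stride):
            tiles.append(cube[:, oy:oy + tile_size, ox:ox + tile_size])
            origins.append((ox, oy))
    return ImcTileSet(tiles=tiles, origins=origins, tile_size=tile_size,
                      stride=stride, image_shape=(h, w))


def dedup_tile_detections(centroids_per_tile: list[np.ndarray],
                          origins: list[tuple[int, int]], tile_size: int,
                          merge_radius: float = 5.0) -> np.ndarray:
    """Merge per-tile detections of the same object from overlapping tiles.

    Centroids are expressed in image coordinates; within ``merge_radius``
    duplicates, the instance whose centroid lies farthest from its tile's
    border is kept (it is the best-observed copy).
    """
    from scipy.spatial import cKDTree

    pts, border_dist = [], []
    for cents, (ox, oy) in zip(centroids_per_tile, origins):
        for cx, cy in np.atleast_2d(cents) if len(cents) else []:
            lx, ly = cx - ox, cy - oy
            pts.append((cx, cy))
            border_dist.append(min(lx, ly, tile_size - 1 - lx, tile_size - 1 - ly))
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts)
    border_dist = np.asarray(border_dist)
    order = np.argsort(-border_dist)      # most interior first
    tree = cKDTree(pts)
    keep: list[int] = []
    suppressed = np.zeros(len(pts), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(pts[i], merge_radius):
            if j != i:
                suppressed[j] = True
    return pts[sorted(keep)]


def normalize_channel(image: np.ndarray) -> np.ndarray:
    """Linear min-max stretch of a channel onto the 16-bit range.

    A plain linear rescale (explicitly not histogram equalization), so pixel
    ordering is preserved. A constant image has zero dynamic range and maps
    to all zeros with a warning.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite pixels in channel")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        warnings.warn("constant channel: zero dynamic range, output all zeros")
        return np.zeros_like(img, dtype=np.uint16)
    return np.round((img - lo) / (hi - lo) * 65535).astype(np.uint16)


def segment_nuclei(prob_map: np.ndarray, sigma: float = 1.0,
                   min_distance: int = 4, min_area: int = 9):
    """Label nuclei in the nuclear channel of a (3, H, W) probability map.

    Gaussian smooth -> Otsu threshold -> distance-transform peaks ->
    watershed split of touching nuclei. Returns ``(labels, centroids)``
    where centroids is a table (label, x, y). Empty foreground gives zero
    nuclei.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian, threshold_otsu
    from skimage.segmentation import watershed

    nuc = np.asarray(prob_map)[1].astype(float)
    sm = gaussian(nuc, sigma=sigma, preserve_range=True)
    if sm.max() <= sm.min():
        return np.zeros(nuc.shape, np.int32), pd.DataFrame(columns=["label", "x", "y"])
    thr = threshold_otsu(sm)
    binary = sm > thr
    if not binary.any():
        return np.zeros(nuc.shape, np.int32), pd.DataFrame(columns=["label", "x", "y"])
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=binary,
                           exclude_border=False)
    markers = np.zeros(nuc.shape, dtype=np.int32)
    for k, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = k
    labels = watershed(-dist, markers, mask=binary).astype(np.int32)

    # drop specks and relabel contiguously
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    drop = set(ids[counts < min_area].tolist())
    if drop:
        labels[np.isin(labels, list(drop))] = 0
    ids = np.unique(labels[labels > 0])
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    labels = remap[labels]

    cents = ndimage.center_of_mass(np.ones_like(labels), labels,
                                   np.arange(1, labels.max() + 1))
    centroids = pd.DataFrame([dict(label=i + 1, x=c[1], y=c[0])
                              for i, c in enumerate(cents)],
                             columns=["label", "x", "y"])
    return labels, centroids


def segment_cells(prob_map: np.ndarray, nucleus_labels: np.ndarray,
                  sigma: float = 1.0) -> np.ndarray:
    """Whole-cell watershed on nucleus+cytoplasm, seeded at the nuclei.

    Seeding guarantees exactly as many cells as nuclei, sharing centroids.
    A seed falling outside the foreground degenerates to its nucleus mask
    (logged via warning).
    """
    from skimage.filters import gaussian, threshold_otsu
    from skimage.segmentation import watershed

    pm = np.asarray(prob_map)
    combined = gaussian(pm[1].astype(float) + pm[2].astype(float), sigma=sigma,
                        preserve_range=True)
    thr = threshold_otsu(combined) if combined.max() > combined.min() else np.inf
    mask = combined > thr
    orphan = (nucleus_labels > 0) & ~mask
    if orphan.any():
        warnings.warn(f"{int(orphan.sum())} seed pixels outside foreground; "
                      "affected cells keep their nucleus mask")
    mask = mask | (nucleus_labels > 0)     # every seed must live in the mask
    cells = watershed(-combined, nucleus_labels.astype(np.int32), mask=mask)
    # enforce nucleus-within-cell containment exactly
    cells = np.where(nucleus_labels > 0, nucleus_labels, cells).astype(np.int32)
    return cells


def extract_features(nucleus_labels: np.ndarray, cell_labels: np.ndarray,
                     cube: np.ndarray, channel_names=None) -> pd.DataFrame:
    """Per-cell feature table: centroid, areas (zeroth moment), channel means."""
    cube = np.asarray(cube, dtype=float)
    if cube.ndim == 2:
        cube = cube[None]
    if cube.shape[1:] != cell_labels.shape:
        raise ValueError("label image and channel cube shapes do not match")
    ids = np.unique(cell_labels[cell_labels > 0])
    if channel_names is None:
        channel_names = [f"ch{c}" for c in range(cube.shape[0])]
    cents = ndimage.center_of_mass(np.ones_like(cell_labels), cell_labels, ids)
    cell_area = ndimage.sum_labels(np.ones_like(cell_labels), cell_labels, ids)
    nuc_area = ndimage.sum_labels(np.ones_like(nucleus_labels), nucleus_labels, ids)
    rows = dict(cell_id=ids,
                centroid_x=[c[1] for c in cents],
                centroid_y=[c[0] for c in cents],
                nucleus_area=nuc_area.astype(int),
                cell_area=cell_area.astype(int))
    for name, ch in zip(channel_names, cube):
        rows[f"mean_{name}_cell"] = ndimage.mean(ch, cell_labels, ids)
        rows[f"mean_{name}_nucleus"] = ndimage.mean(ch, nucleus_labels, ids)
    return pd.DataFrame(rows)


def _label_sets(labels: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    for obj, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        out[obj] = sl
    return out


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray,
                          iou_threshold: float = 0.5) -> dict:
    """Pixel-wise and object-wise F1 of a predicted label image vs ground truth.

    Objects match one-to-one when IoU > ``iou_threshold``, assigned greedily
    by descending IoU. Empty predictions score F1 = 0 by convention.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")

    # pixel-wise on foreground
    pf, tf = pred > 0, truth > 0
    tp = float(np.sum(pf & tf))
    prec_px = tp / pf.sum() if pf.sum() else 0.0
    rec_px = tp / tf.sum() if tf.sum() else 0.0
    pixel_f1 = 2 * prec_px * rec_px / (prec_px + rec_px) if prec_px + rec_px else 0.0

    pred_ids = np.unique(pred[pred > 0])
    truth_ids = np.unique(truth[truth > 0])
    if len(pred_ids) == 0 or len(truth_ids) == 0:
        return dict(pixel_f1=pixel_f1, object_f1=0.0, precision=0.0, recall=0.0,
                    n_matched=0, n_pred=len(pred_ids), n_truth=len(truth_ids))

    # candidate overlaps via joint histogram
    both = (pred.astype(np.int64) * (truth.max() + 1) + truth)[pf & tf]
    combos, counts = np.unique(both, return_counts=True)
    pred_area = dict(zip(*np.unique(pred[pf], return_counts=True)))
    truth_area = dict(zip(*np.unique(truth[tf], return_counts=True)))
    cand = []
    for combo, inter in zip(combos, counts):
        p_id = combo // (truth.max() + 1)
        t_id = combo % (truth.max() + 1)
        if p_id == 0 or t_id == 0:
            continue
        union = pred_area[p_id] + truth_area[t_id] - inter
        iou = inter / union
        if iou > iou_threshold:
            cand.append((iou, int(p_id), int(t_id)))
    cand.sort(reverse=True)
    used_p, used_t = set(), set()
    n_matched = 0
    for iou, p_id, t_id in cand:
        if p_id in used_p or t_id in used_t:
            continue
        used_p.add(p_id); used_t.add(t_id)
        n_matched += 1
    precision = n_matched / len(pred_ids)
    recall = n_matched / len(truth_ids)
    object_f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return dict(pixel_f1=pixel_f1, object_f1=object_f1, precision=precision,
                recall=recall, n_matched=n_matched, n_pred=len(pred_ids),
                n_truth=len(truth_ids))


def detection_rate(centroids: pd.DataFrame, truth_cell_labels: np.ndarray) -> float:
    """Fraction of true cells containing at least one predicted nucleus centroid."""
    truth_ids = np.unique(truth_cell_labels[truth_cell_labels > 0])
    if len(truth_ids) == 0:
        raise ValueError("no ground-truth cells")
    h, w = truth_cell_labels.shape
    hit = set()
    for r in centroids.itertuples():
        x, y = int(round(r.x)), int(round(r.y))
        if 0 <= x < w and 0 <= y < h:
            lbl = truth_cell_labels[y, x]
            if lbl > 0:
                hit.add(int(lbl))
    return len(hit) / len(truth_ids)
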