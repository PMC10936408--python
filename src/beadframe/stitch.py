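"""Tile-to-tile registration and confidence-weighted mosaic assembly.

Pairwise displacements between overlapping tiles are found by exhaustive
integer search minimizing the confidence-weighted mean squared intensity
difference over the overlap (equivalent to masked phase correlation, but
exact on masked arrays). Displacements stay integer at this stage so no
subpixel resampling is needed. Overlaps that carry too little information
(no beads or tissue in the overlap strip) fall back to the
microscope-reported offset.

Global placement starts from the tile with the highest mean intensity
(always inside the biological sample), lays out its neighbors from the
pairwise displacements, and proceeds breadth-first; tiles reachable along
several paths get positioning-error-weighted averaged positions. The mosaic
is then accumulated as intensity*confidence and confidence stage buffers;
dividing the two averages overlap regions with no further blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import Tile

__all__ = [
    "PairwiseOffset",
    "StageMosaic",
    "pairwise_offset",
    "find_neighbors",
    "global_placement",
    "assemble_mosaic",
    "stitch_slice",
]


@dataclass
class PairwiseOffset:
    """Integer displacement of tile_b relative to tile_a (px, (x, y))."""

    tile_a: int
    tile_b: int
    displacement: tuple[int, int]
    score: float                 # weighted mean squared residual at optimum
    from_microscope: bool = False
    weight: float = 1.0          # positioning-error proxy (inverse residual)


@dataclass
class StageMosaic:
    intensity: np.ndarray
    confidence: np.ndarray
    tile_positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    origin: tuple[float, float] = (0.0, 0.0)


class NoOverlapError(ValueError):
    pass


def _overlap_views(a: np.ndarray, b: np.ndarray, dx: int, dy: int):
    """Views of a and b where b, placed at (dx, dy) relative to a, overlaps a."""
    ha, wa = a.shape
    hb, wb = b.shape
    ax0, ax1 = max(0, dx), min(wa, dx + wb)
    ay0, ay1 = max(0, dy), min(ha, dy + hb)
    if ax0 >= ax1 or ay0 >= ay1:
        return None
    bx0, by0 = ax0 - dx, ay0 - dy
    return (a[ay0:ay1, ax0:ax1],
            b[by0:by0 + (ay1 - ay0), bx0:bx0 + (ax1 - ax0)])


def masked_ssd(tile_a, conf_a, tile_b, conf_b, displacement):
    """Confidence-weighted mean squared difference of the overlap.

    ``displacement`` is the integer (x, y) position of tile_b relative to
    tile_a. Returns ``(score, weight_sum)``; ``(inf, 0)`` when there is no
    overlap or no valid weight.
    """
    a = np.asarray(tile_a, float)
    b = np.asarray(tile_b, float)
    wa = np.ones_like(a) if conf_a is None else np.asarray(conf_a, float)
    wb = np.ones_like(b) if conf_b is None else np.asarray(conf_b, float)
    dx, dy = int(displacement[0]), int(displacement[1])
    ov = _overlap_views(a, b, dx, dy)
    if ov is None:
        return np.inf, 0.0
    oa, ob = ov
    ow = _overlap_views(wa, wb, dx, dy)
    w = ow[0] * ow[1]
    wsum = w.sum()
    if wsum <= 0:
        return np.inf, 0.0
    return float((w * (oa - ob) ** 2).sum() / wsum), float(wsum)


def _ssd_surface_fft(a, wa, b, wb):
    """Masked SSD and total weight for *all* displacements via FFT.

    Exactly the masked-SSD statistic, expanded into three cross-correlations:
    ``sum(wa*wb*(a-b)^2) = corr(wa*a^2, wb) + corr(wa, wb*b^2)
    - 2*corr(wa*a, wb*b)``. Returns arrays indexed by displacement
    ``(dx, dy)`` with ``surface[dy + hb - 1, dx + wb - 1]``.
    """
    from scipy.signal import fftconvolve

    def corr(f, g):
        return fftconvolve(f, g[::-1, ::-1], mode="full")

    num = corr(wa * a * a, wb) + corr(wa, wb * b * b) - 2 * corr(wa * a, wb * b)
    den = corr(wa, wb)
    return num, den


def pairwise_offset(tile_a, conf_a, tile_b, conf_b, reported_offset,
                    search_window: int = 16,
                    min_weight_frac: float = 0.05,
                    min_contrast: float = 1e-3,
                    poisson_factor: float = 0.0,
                    tile_a_id: int = 0, tile_b_id: int = 1) -> PairwiseOffset:
    """Best integer displacement of tile_b relative to tile_a.

    ``reported_offset`` is the microscope's (x, y) displacement estimate;
    the search covers ``+-search_window`` px around it. The residual
    statistic is ``sum(w_a w_b (a-b)^2) / sum(w_a w_b)``, minimized
    exhaustively (an FFT evaluates the whole search surface; the best
    candidates are re-scored directly, so the result is identical to a
    direct exhaustive search). Ties are broken toward the reported offset.

    The microscope offset is retained (``from_microscope=True``) when the
    overlap is information-poor — weighted variance below ``min_contrast``
    times the squared intensity scale *or* below ``poisson_factor`` times
    the mean (indistinguishable from pure counting noise), almost no valid
    overlap weight, or an optimum pinned to the search boundary.
    """
    a = np.asarray(tile_a, float)
    b = np.asarray(tile_b, float)
    wa = np.ones_like(a) if conf_a is None else np.asarray(conf_a, float)
    wb = np.ones_like(b) if conf_b is None else np.asarray(conf_b, float)
    rx, ry = int(round(reported_offset[0])), int(round(reported_offset[1]))
    hb, wb_n = b.shape

    num, den = _ssd_surface_fft(a, wa, b, wb)
    dxs = np.arange(rx - search_window, rx + search_window + 1)
    dys = np.arange(ry - search_window, ry + search_window + 1)
    ix = dxs + wb_n - 1
    iy = dys + hb - 1
    valid_x = (ix >= 0) & (ix < num.shape[1])
    valid_y = (iy >= 0) & (iy < num.shape[0])
    if not valid_x.any() or not valid_y.any():
        raise NoOverlapError("tiles do not overlap under any displacement "
                             "in the search window")
    sub_n = num[np.ix_(iy[valid_y], ix[valid_x])]
    sub_d = den[np.ix_(iy[valid_y], ix[valid_x])]
    with np.errstate(invalid="ignore", divide="ignore"):
        surf = np.where(sub_d > 1e-9, sub_n / np.where(sub_d > 1e-9, sub_d, 1),
                        np.inf)
    if not np.isfinite(surf).any():
        raise NoOverlapError("tiles do not overlap under any displacement "
                             "in the search window")
    # re-score the best FFT candidates directly: bit-identical to brute force
    flat = np.argsort(surf, axis=None)[:25]
    best = None
    for k in flat:
        yy_i, xx_i = np.unravel_index(k, surf.shape)
        dx = int(dxs[valid_x][xx_i])
        dy = int(dys[valid_y][yy_i])
        score, wsum = masked_ssd(a, wa if conf_a is not None else None,
                                 b, wb if conf_b is not None else None, (dx, dy))
        if not np.isfinite(score):
            continue
        key = (score, abs(dx - rx) + abs(dy - ry))
        if best is None or key < best[0]:
            best = (key, (dx, dy), wsum)
    if best is None:
        raise NoOverlapError("tiles do not overlap under any displacement "
                             "in the search window")
    key, disp, wsum = best
    score = key[0]
    ov = _overlap_views(a, b, *disp)
    oa, _ob = ov
    w = _overlap_views(wa, wb, *disp)
    w = w[0] * w[1]
    # information content of the overlap at the optimum: weighted variance
    mean = (w * oa).sum() / wsum
    var = float((w * (oa - mean) ** 2).sum() / wsum)
    scale = max(mean, 1.0)
    full_weight = min(wa.size, wb.size)
    noise_floor = max(min_contrast * scale ** 2, poisson_factor * mean)
    on_boundary = (abs(disp[0] - rx) >= search_window
                   or abs(disp[1] - ry) >= search_window)
    if wsum < min_weight_frac * full_weight or var < noise_floor or on_boundary:
        return PairwiseOffset(tile_a_id, tile_b_id, (rx, ry), score,
                              from_microscope=True, weight=1e-3)
    return PairwiseOffset(tile_a_id, tile_b_id, disp, score,
                          from_microscope=False,
                          weight=1.0 / (score + 1e-9))


def find_neighbors(tiles: list[Tile], max_gap_frac: float = 0.35) -> list[tuple[int, int]]:
    """Index pairs of tiles whose reported positions make them adjacent."""
    pairs = []
    for i, ti in enumerate(tiles):
        hi, wi = ti.data.shape
        for j in range(i + 1, len(tiles)):
            tj = tiles[j]
            dx = tj.reported_origin[0] - ti.reported_origin[0]
            dy = tj.reported_origin[1] - ti.reported_origin[1]
            if abs(dx) < wi * (1 - 0.01) and abs(dy) < hi * (1 - 0.01):
                # overlapping or nearly so; require real overlap area
                if abs(dx) < wi and abs(dy) < hi:
                    pairs.append((i, j))
    return pairs


def global_placement(tiles: list[Tile], offsets: list[PairwiseOffset],
                     reported_positions=None) -> pd.DataFrame:
    """Absolute tile positions from pairwise displacements.

    Breadth-first placement seeded at the tile with the highest mean
    intensity; a tile adjacent to several already-placed tiles receives the
    weighted average of the positions each neighbor implies, with the
    pairwise positioning-error proxies as weights. Disconnected tiles fall
    back to their reported positions (consistently shifted into the placed
    frame).
    """
    if not tiles:
        raise ValueError("no tiles to place")
    n = len(tiles)
    adj: dict[int, list[tuple[int, np.ndarray, float]]] = {i: [] for i in range(n)}
    for off in offsets:
        d = np.asarray(off.displacement, float)
        adj[off.tile_a].append((off.tile_b, d, off.weight))
        adj[off.tile_b].append((off.tile_a, -d, off.weight))

    seed = int(np.argmax([t.data.mean() for t in tiles]))
    pos = {seed: np.asarray(tiles[seed].reported_origin, float)}
    frontier = [seed]
    while frontier:
        candidates: dict[int, list[tuple[np.ndarray, float]]] = {}
        for u in frontier:
            for v, d, w in adj[u]:
                if v in pos:
                    continue
                candidates.setdefault(v, []).append((pos[u] + d, w))
        if not candidates:
            break
        next_frontier = []
        for v, ests in candidates.items():
            # include estimates from *all* already-placed neighbors, not just
            # the frontier, so multi-path tiles average over every path
            ests = [(pos[u] + d, w) for u, d, w in
                    [(uu, -dd, ww) for uu, dd, ww in adj[v] if uu in pos]]
            w = np.array([e[1] for e in ests])
            p = np.array([e[0] for e in ests])
            pos[v] = (p * w[:, None]).sum(axis=0) / w.sum()
            next_frontier.append(v)
        frontier = next_frontier

    if len(pos) < n:
        # disconnected tiles: use reported positions shifted into the placed frame
        shift = pos[seed] - np.asarray(tiles[seed].reported_origin, float)
        for i in range(n):
            if i not in pos:
                pos[i] = np.asarray(tiles[i].reported_origin, float) + shift

    rows = []
    err = {i: [] for i in range(n)}
    for off in offsets:
        err[off.tile_a].append(1.0 / off.weight)
        err[off.tile_b].append(1.0 / off.weight)
    for i, t in enumerate(tiles):
        rows.append(dict(tile_id=t.tile_id, x=pos[i][0], y=pos[i][1],
                         reported_x=t.reported_origin[0],
                         reported_y=t.reported_origin[1],
                         positioning_error=float(np.mean(err[i])) if err[i] else np.nan))
    return pd.DataFrame(rows)


def assemble_mosaic(tiles: list[Tile], positions: pd.DataFrame,
                    stage_shape: tuple[int, int] | None = None) -> StageMosaic:
    """Accumulate tiles into intensity and confidence stage buffers.

    Positions are rounded to integers (displacements are integer at this
    stage). ``mosaic = sum(I*C) / sum(C)`` wherever confidence > 0, which
    averages overlap regions with no nonlinear blending.
    """
    pos = positions.set_index("tile_id")
    xs = np.round(pos.x.to_numpy()).astype(int)
    ys = np.round(pos.y.to_numpy()).astype(int)
    x0, y0 = xs.min(), ys.min()
    if stage_shape is None:
        w = int(xs.max() - x0 + max(t.data.shape[1] for t in tiles))
        h = int(ys.max() - y0 + max(t.data.shape[0] for t in tiles))
    else:
        h, w = stage_shape
    acc_i = np.zeros((h, w))
    acc_c = np.zeros((h, w))
    for t in tiles:
        px = int(round(pos.loc[t.tile_id, "x"])) - x0
        py = int(round(pos.loc[t.tile_id, "y"])) - y0
        th, tw = t.data.shape
        # clip to the (possibly padded/common) stage bounds
        gy0, gy1 = max(py, 0), min(py + th, h)
        gx0, gx1 = max(px, 0), min(px + tw, w)
        if gy0 >= gy1 or gx0 >= gx1:
            continue
        ty0, tx0 = gy0 - py, gx0 - px
        dat = t.data[ty0:ty0 + (gy1 - gy0), tx0:tx0 + (gx1 - gx0)]
        cnf = t.confidence[ty0:ty0 + (gy1 - gy0), tx0:tx0 + (gx1 - gx0)]
        acc_i[gy0:gy1, gx0:gx1] += dat * cnf
        acc_c[gy0:gy1, gx0:gx1] += cnf
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(acc_c > 0, acc_i / np.where(acc_c > 0, acc_c, 1), 0.0)
    return StageMosaic(intensity=intensity, confidence=acc_c,
                       tile_positions=positions, origin=(float(x0), float(y0)))


def stitch_slice(tiles: list[Tile], search_window: int = 16,
                 stage_shape: tuple[int, int] | None = None,
                 min_contrast: float = 1e-3,
                 poisson_factor: float = 3.0) -> StageMosaic:
    """Full stitching chain for one slice: pairwise offsets -> placement -> mosaic.

    Tiles are assumed to hold raw counts (ADU), so the default information
    floor treats overlap variance at the Poisson level as featureless.
    """
    pairs = find_neighbors(tiles)
    offsets = []
    for i, j in pairs:
        rep = (tiles[j].reported_origin[0] - tiles[i].reported_origin[0],
               tiles[j].reported_origin[1] - tiles[i].reported_origin[1])
        offsets.append(pairwise_offset(tiles[i].data, tiles[i].confidence,
                                       tiles[j].data, tiles[j].confidence,
                                       rep, search_window=search_window,
                                       min_contrast=min_contrast,
                                       poisson_factor=poisson_factor,
                                       tile_a_id=i, tile_b_id=j))
    positions = global_placement(tiles, offsets)
    return assemble_mosaic(tiles, positions, stage_shape=stage_shape)
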