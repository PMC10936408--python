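"""Removal of instrumental effects from raw tiles.

Three corrections, in the order they are applied:

* additive dark/background level, estimated from low-signal statistics of a
  tile stack (disabled by default for slide-scanner-like modalities, where
  thermal background is negligible);
* multiplicative flatfield: the per-pixel response of the optical system,
  estimated as a location statistic (median by default) over a stack of
  tiles with spatially uncorrelated content, normalized to median 1;
* geometric distortion: a grade-3 bivariate polynomial displacement field
  (separate coefficients per axis) constrained to zero value and zero
  gradient at the field center, calibrated from tile pairs acquired at 50%
  overlap by minimizing residual intensity misalignment.

Distortion-corrected tiles acquire empty pixels near squeezed corners; the
returned confidence map marks these with weight 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FlatfieldFrame",
    "DistortionModel",
    "measure_dark",
    "estimate_flatfield",
    "calibrate_distortion",
    "correct_tile",
]


@dataclass
class FlatfieldFrame:
    """Per-pixel multiplicative response, median-normalized to 1."""

    response: np.ndarray
    n_tiles_used: int = 0

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.response <= 0):
            raise ValueError("flatfield response must be strictly positive")


# grade-3 bivariate basis with zero value and gradient at the origin
_POLY_POWERS = [(2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]


@dataclass
class DistortionModel:
    """Displacement field mapping corrected (world) pixel -> raw pixel.

    A raw pixel ``p`` actually observed the scene at ``c(p) = center +
    M (p - center) + D(p)`` where ``M = diag(magnification_x,
    magnification_y)`` and ``D`` is a grade-3 polynomial in coordinates
    normalized by ``scale`` about ``center``. Distortion vanishes (value and
    gradient) at the field center and grows toward the corners.
    """

    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    center: tuple[float, float]
    scale: float
    magnification_x: float = 1.0
    magnification_y: float = 1.0

    def __post_init__(self) -> None:
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float).reshape(len(_POLY_POWERS))
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float).reshape(len(_POLY_POWERS))

    @classmethod
    def zero(cls, tile_size: int) -> "DistortionModel":
        c = (tile_size - 1) / 2
        return cls(np.zeros(7), np.zeros(7), (c, c), tile_size / 2)

    @classmethod
    def synthetic(cls, tile_size: int, corner_displacement_px: float,
                  seed: int = 0) -> "DistortionModel":
        """A random smooth grade-3 field with roughly the given corner amplitude."""
        rng = np.random.default_rng([seed, 0xD157])
        m = cls.zero(tile_size)
        cx = rng.normal(0, 1, 7)
        cy = rng.normal(0, 1, 7)
        m.coeffs_x, m.coeffs_y = cx, cy
        corner = np.array([[0.0, 0.0], [0.0, tile_size - 1.0],
                           [tile_size - 1.0, 0.0], [tile_size - 1.0, tile_size - 1.0]])
        dx, dy = m.displacement(corner[:, 0], corner[:, 1])
        amp = np.max(np.hypot(dx, dy))
        m.coeffs_x = cx * corner_displacement_px / amp
        m.coeffs_y = cy * corner_displacement_px / amp
        return m

    def _basis(self, x, y) -> np.ndarray:
        u = (np.asarray(x, float) - self.center[0]) / self.scale
        v = (np.asarray(y, float) - self.center[1]) / self.scale
        return np.stack([u ** a * v ** b for a, b in _POLY_POWERS], axis=-1)

    def displacement(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Polynomial displacement (dx, dy) at world pixel coordinates."""
        phi = self._basis(x, y)
        return phi @ self.coeffs_x, phi @ self.coeffs_y

    def distort(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """World coordinate a raw pixel at (x, y) actually observed."""
        dx, dy = self.displacement(x, y)
        cx, cy = self.center
        return (cx + self.magnification_x * (np.asarray(x, float) - cx) + dx,
                cy + self.magnification_y * (np.asarray(y, float) - cy) + dy)

    def undistort(self, x, y, n_iter: int = 4) -> tuple[np.ndarray, np.ndarray]:
        """Invert :meth:`distort` by fixed-point iteration (sub-0.01 px)."""
        cx, cy = self.center
        xr = np.array(x, dtype=float, copy=True)
        yr = np.array(y, dtype=float, copy=True)
        for _ in range(n_iter):
            dx, dy = self.displacement(xr, yr)
            xr = cx + (np.asarray(x, float) - dx - cx) / self.magnification_x
            yr = cy + (np.asarray(y, float) - dy - cy) / self.magnification_y
        return xr, yr

    def max_corner_displacement(self, tile_size: int) -> float:
        corner = np.array([[0.0, 0.0], [0.0, tile_size - 1.0],
                           [tile_size - 1.0, 0.0], [tile_size - 1.0, tile_size - 1.0]])
        dx, dy = self.displacement(corner[:, 0], corner[:, 1])
        return float(np.max(np.hypot(dx, dy)))

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return dict(coeffs_x=self.coeffs_x.tolist(), coeffs_y=self.coeffs_y.tolist(),
                    center=list(self.center), scale=self.scale,
                    magnification_x=self.magnification_x,
                    magnification_y=self.magnification_y)

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionModel":
        return cls(np.array(d["coeffs_x"]), np.array(d["coeffs_y"]),
                   tuple(d["center"]), d["scale"],
                   d.get("magnification_x", 1.0), d.get("magnification_y", 1.0))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DistortionModel":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------


def measure_dark(tiles, sigma: float = 3.0, n_iter: int = 5,
                 max_pixels: int = 2_000_000) -> float:
    """Estimate the additive dark/background level from a tile stack.

    Uses an iteratively sigma-clipped mean over pooled pixels: bright sample
    structure is clipped away, leaving the additive pedestal. Suitable for a
    photomultiplier-style detector where thermal noise is a constant offset.
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    data = np.concatenate([np.asarray(t, dtype=float).ravel() for t in tiles])
    if data.size > max_pixels:
        data = data[:: data.size // max_pixels + 1]
    clipped = data
    for _ in range(n_iter):
        mu, sd = clipped.mean(), clipped.std()
        keep = np.abs(clipped - mu) <= sigma * max(sd, 1e-12)
        if keep.all():
            break
        clipped = clipped[keep]
    return float(clipped.mean())


def estimate_flatfield(tiles, min_tiles: int = 20,
                       statistic: str = "median",
                       fallback: FlatfieldFrame | None = None) -> FlatfieldFrame:
    """Per-pixel response from a stack of tiles with uncorrelated content.

    Each pixel of the stack sees a random draw of the intensity distribution,
    so the per-pixel median (or mean) across enough tiles is proportional to
    the system response at that pixel. The result is normalized to median 1.

    With fewer than ``min_tiles`` tiles a stored calibration may be supplied
    as ``fallback`` (the response is stable over days/weeks); otherwise a
    warning is issued and the estimate proceeds with whatever is available.
    """
    stack = np.stack([np.asarray(t, dtype=float) for t in tiles])
    if stack.shape[0] < min_tiles:
        if fallback is not None:
            warnings.warn(f"only {stack.shape[0]} tiles (<{min_tiles}); "
                          "using stored flatfield calibration")
            return fallback
        warnings.warn(f"only {stack.shape[0]} tiles (<{min_tiles}); "
                      "flatfield estimate may be unreliable")
    if statistic == "median":
        resp = np.median(stack, axis=0)
    elif statistic == "mean":
        resp = stack.mean(axis=0)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    med = np.median(resp)
    if med <= 0:
        raise ValueError("degenerate tile stack: non-positive median response")
    resp = resp / med
    resp = np.clip(resp, 1e-3, None)
    return FlatfieldFrame(response=resp, n_tiles_used=stack.shape[0])


def _local_shifts(img_a: np.ndarray, img_b: np.ndarray, shift: tuple[int, int],
                  patch: int, step: int):
    """Sub-pixel local misalignment of 50%-overlap tile pairs on a patch grid.

    ``shift`` is the nominal (x, y) pixel offset of tile B relative to
    tile A. Yields ``(px, py, dx, dy)``: patch center in A coordinates and
    measured residual shift of the B patch relative to nominal.
    """
    from skimage.registration import phase_cross_correlation

    h, w = img_a.shape
    sx, sy = shift
    out = []
    half = patch // 2
    # Hann apodization suppresses the patch-edge discontinuity that biases
    # the correlation peak on smooth scenes
    win = np.outer(np.hanning(patch), np.hanning(patch))
    for py in range(half, h - half, step):
        for px in range(half, w - half, step):
            qx, qy = px - sx, py - sy
            if not (half <= qx < w - half and half <= qy < h - half):
                continue
            pa = img_a[py - half:py + half, px - half:px + half]
            pb = img_b[qy - half:qy + half, qx - half:qx + half]
            if pa.std() < 1e-6 or pb.std() < 1e-6:
                continue
            pa = (pa - pa.mean()) * win
            pb = (pb - pb.mean()) * win
            (dy, dx), err, _ = phase_cross_correlation(pa, pb, upsample_factor=50,
                                                       normalization=None)
            # the returned value registers pb onto pa; the misalignment
            # D(p) - D(p - s) is its negative
            dx, dy = -dx, -dy
            if abs(dx) > patch / 4 or abs(dy) > patch / 4:
                continue
            out.append((px, py, float(dx), float(dy), float(err)))
    return out


def calibrate_distortion(tile_pairs, tile_size: int | None = None,
                         patch: int = 32, step: int = 8,
                         min_samples: int = 40) -> DistortionModel:
    """Fit the grade-3 distortion field from tile pairs at 50% overlap.

    ``tile_pairs`` is a sequence of ``(img_a, img_b, shift)`` with ``shift``
    the nominal (x, y) offset of B relative to A — half the field along one
    axis. Each overlapping patch pair constrains ``D(p) - D(p - shift)``
    plus an unknown per-pair constant (the pair's true offset error), so the
    model coefficients and per-pair constants are solved jointly by linear
    least squares. Only the nonlinear part of the field is observable from
    overlaps; the fit pins value and gradient at the field center.
    """
    if not tile_pairs:
        raise ValueError("need at least one tile pair")
    if tile_size is None:
        tile_size = tile_pairs[0][0].shape[0]
    model = DistortionModel.zero(tile_size)

    rows_a, rows_b, rhs = [], [], []
    n_pairs = len(tile_pairs)
    n_coef = len(_POLY_POWERS)
    for ipair, (img_a, img_b, shift) in enumerate(tile_pairs):
        samples = _local_shifts(np.asarray(img_a, float), np.asarray(img_b, float),
                                (int(shift[0]), int(shift[1])), patch, step)
        for px, py, dx, dy, _err in samples:
            phi_p = model._basis(px, py)
            phi_q = model._basis(px - shift[0], py - shift[1])
            base = phi_p - phi_q
            row = np.zeros(2 * n_coef + 2 * n_pairs)
            row[:n_coef] = base
            row[2 * n_coef + 2 * ipair] = 1.0
            rows_a.append(row)
            rhs.append(dx)
            row = np.zeros(2 * n_coef + 2 * n_pairs)
            row[n_coef:2 * n_coef] = base
            row[2 * n_coef + 2 * ipair + 1] = 1.0
            rows_a.append(row)
            rhs.append(dy)
    if len(rhs) < 2 * min_samples:
        raise ValueError(
            f"featureless input: only {len(rhs) // 2} usable patch measurements")
    A = np.asarray(rows_a)
    b = np.asarray(rhs)
    sol, residuals, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 2 * n_coef:
        raise ValueError("ill-conditioned distortion fit (featureless or "
                         "degenerate overlap geometry)")
    model.coeffs_x = sol[:n_coef]
    model.coeffs_y = sol[n_coef:2 * n_coef]
    return model


def correct_tile(tile: np.ndarray, dark: float = 0.0,
                 flatfield: FlatfieldFrame | np.ndarray | None = None,
                 distortion: DistortionModel | None = None,
                 order: int = 1):
    """Apply dark subtraction, flatfield division and distortion unwarp.

    Returns ``(corrected, confidence)``. The unwarp is pull-based: the
    corrected pixel ``q`` samples the raw tile at the position that observed
    world coordinate ``q``; pixels mapping outside the raw frame get
    confidence 0. ``order=1`` is bilinear (smooth images); ``order=0``
    preserves integer labels.
    """
    data = np.asarray(tile, dtype=float)
    if flatfield is not None:
        resp = flatfield.response if isinstance(flatfield, FlatfieldFrame) else np.asarray(flatfield, float)
        if resp.shape != data.shape:
            raise ValueError("flatfield shape does not match tile")
        if np.any(resp <= 0):
            raise ValueError("non-positive flatfield pixels")
        out = (data - dark) / resp
    else:
        out = data - dark

    if distortion is None:
        return out, np.ones_like(out)

    h, w = out.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # raw pixel p observed world coord c(p); world pixel q was therefore
    # recorded at the raw position solving c(p) = q, i.e. p = c^{-1}(q)
    rx, ry = distortion.undistort(xx, yy)
    inside = (rx >= 0) & (rx <= w - 1) & (ry >= 0) & (ry <= h - 1)
    warped = ndimage.map_coordinates(out, [ry, rx], order=order, mode="nearest")
    conf = inside.astype(float)
    warped[~inside] = 0.0
    return warped, conf
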