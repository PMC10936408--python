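"""Affine transforms, orientation flips and confidence-map algebra.

Conventions used throughout the package:

* pixel coordinates are 0-based, ``(x, y)`` with ``x`` the column and ``y``
  the row, and refer to pixel centers;
* an :class:`AffineTransform` maps source-frame points into a target frame as
  ``p' = L @ p + t`` with ``L`` a 2x2 linear part and ``t`` a translation in
  target-frame pixels;
* a confidence map is a per-pixel weight in ``[0, 1]`` where 0 marks pixels
  carrying no valid data (e.g. created by distortion correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AffineTransform",
    "Orientation",
    "fit_affine",
    "AffineFitResult",
]

#: determinant floor below which a linear part is considered singular
_DET_FLOOR = 1e-12


@dataclass(frozen=True)
class AffineTransform:
    """A 6-degree-of-freedom planar affine mapping ``p -> linear @ p + translation``.

    Parameters
    ----------
    linear
        2x2 matrix (dimensionless); must be invertible.
    translation
        2-vector ``(tx, ty)`` in target-frame pixels.
    src_frame, dst_frame
        Optional frame labels used when compounding transform chains
        across modalities.
    """

    linear: np.ndarray
    translation: np.ndarray
    src_frame: str = ""
    dst_frame: str = ""

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        tra = np.asarray(self.translation, dtype=float).reshape(2)
        if not (np.all(np.isfinite(lin)) and np.all(np.isfinite(tra))):
            raise ValueError("affine coefficients must be finite")
        if abs(np.linalg.det(lin)) <= _DET_FLOOR:
            raise ValueError("linear part is singular (|det| <= 1e-12)")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tra)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def identity(cls, src_frame: str = "", dst_frame: str = "") -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2), src_frame, dst_frame)

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "AffineTransform":
        return cls(np.eye(2), np.array([tx, ty], dtype=float))

    @classmethod
    def from_rotation(cls, theta: float, center: Sequence[float] = (0.0, 0.0)) -> "AffineTransform":
        """Rotation by ``theta`` radians about ``center`` (counter-clockwise)."""
        c, s = np.cos(theta), np.sin(theta)
        lin = np.array([[c, -s], [s, c]])
        ctr = np.asarray(center, dtype=float)
        return cls(lin, ctr - lin @ ctr)

    # -- algebra --------------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map ``points`` (array-like of shape (n, 2) or (2,)) into the target frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite input points")
        return pts @ self.linear.T + self.translation

    def invert(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation,
                               src_frame=self.dst_frame, dst_frame=self.src_frame)

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """Return the transform equivalent to applying ``inner`` first, then ``self``."""
        return AffineTransform(
            self.linear @ inner.linear,
            self.linear @ inner.translation + self.translation,
            src_frame=inner.src_frame, dst_frame=self.dst_frame,
        )

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "src_frame": self.src_frame,
            "dst_frame": self.dst_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["linear"]), np.array(d["translation"]),
                   d.get("src_frame", ""), d.get("dst_frame", ""))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "AffineTransform":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"AffineTransform(linear={self.linear.tolist()}, "
                f"translation={self.translation.tolist()}, "
                f"src={self.src_frame!r}, dst={self.dst_frame!r})")


@dataclass(frozen=True)
class Orientation:
    """One of the four axis-flip states of a slide on a glass slide.

    A physical section deposited on a slide can land "face-up" or
    "bottom-up" and rotated, so the rendered image may be mirrored
    left/right and/or top/bottom relative to the volume frame.
    """

    flip_x: bool = False
    flip_y: bool = False

    def apply_to_image(self, image: np.ndarray) -> np.ndarray:
        out = image
        if self.flip_x:
            out = out[..., ::-1]
        if self.flip_y:
            out = out[..., ::-1, :]
        return out

    def as_affine(self, width: float, height: float) -> AffineTransform:
        """Affine equivalent of the flip for an image of the given size.

        Uses the pixel-center convention: flipping an image of ``width``
        columns maps column x to ``width - 1 - x``.
        """
        sx = -1.0 if self.flip_x else 1.0
        sy = -1.0 if self.flip_y else 1.0
        tx = (width - 1.0) if self.flip_x else 0.0
        ty = (height - 1.0) if self.flip_y else 0.0
        return AffineTransform(np.diag([sx, sy]), np.array([tx, ty]))

    @classmethod
    def all(cls) -> list["Orientation"]:
        return [cls(fx, fy) for fx in (False, True) for fy in (False, True)]


@dataclass
class AffineFitResult:
    """A fitted affine plus its per-point residuals (target-frame px)."""

    transform: AffineTransform
    residuals: np.ndarray
    rms: float = field(init=False)

    def __post_init__(self) -> None:
        self.rms = float(np.sqrt(np.mean(self.residuals ** 2))) if self.residuals.size else 0.0


def fit_affine(src, dst, weights=None,
               src_frame: str = "", dst_frame: str = "") -> AffineFitResult:
    """Weighted least-squares affine fit mapping ``src`` points onto ``dst``.

    The x and y rows of the transform are solved as two independent
    3-parameter linear systems (displacements along the two axes are treated
    as independent). ``weights``, when given, are used as inverse-variance
    weights.

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are supplied or the source points are
        (numerically) collinear.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[-1] != 2:
        raise ValueError("src and dst must both have shape (n, 2)")
    n = src.shape[0]
    if n < 3:
        raise ValueError("affine fit needs at least 3 point pairs")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise ValueError("non-finite input points")

    design = np.column_stack([src, np.ones(n)])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        design_w = design * w[:, None]
        dst_w = dst * w[:, None]
    else:
        design_w, dst_w = design, dst

    # collinearity check on the (weighted) design matrix
    if np.linalg.matrix_rank(design_w, tol=1e-9 * max(1.0, np.abs(design_w).max())) < 3:
        raise ValueError("degenerate geometry: source points are collinear")

    coef, *_ = np.linalg.lstsq(design_w, dst_w, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    t = AffineTransform(linear, translation, src_frame, dst_frame)
    resid = np.linalg.norm(t.apply(src) - dst, axis=1)
    return AffineFitResult(t, resid)


def fit_rigid(src, dst, weights=None,
              src_frame: str = "", dst_frame: str = "") -> AffineFitResult:
    """Weighted rigid (rotation + translation) fit of ``src`` onto ``dst``.

    Solved in closed form by weighted Procrustes (SVD of the weighted
    cross-covariance, reflection excluded). Preferable to the full affine
    when only a handful of point pairs are available (e.g. a small
    second-modality field with critically few beads).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[-1] != 2:
        raise ValueError("src and dst must both have shape (n, 2)")
    if src.shape[0] < 2:
        raise ValueError("rigid fit needs at least 2 point pairs")
    w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu_s = (src * w[:, None]).sum(axis=0)
    mu_d = (dst * w[:, None]).sum(axis=0)
    cov = (dst - mu_d).T @ ((src - mu_s) * w[:, None])
    u, _s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    t = AffineTransform(rot, mu_d - rot @ mu_s, src_frame, dst_frame)
    resid = np.linalg.norm(t.apply(src) - dst, axis=1)
    return AffineFitResult(t, resid)


def make_confidence(shape, valid: np.ndarray | None = None) -> np.ndarray:
    """Return a confidence map of ``shape``: 1 where valid (default everywhere)."""
    conf = np.ones(shape, dtype=float)
    if valid is not None:
        conf[~valid] = 0.0
    return conf


def validate_confidence(conf: np.ndarray) -> np.ndarray:
    conf = np.asarray(conf, dtype=float)
    if conf.min() < 0 or conf.max() > 1:
        raise ValueError("confidence values must lie in [0, 1]")
    return conf
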