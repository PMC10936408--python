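"""Detection and physical profile fitting of spherical fiducial beads.

Beads (~90 um agarose spheres) embedded in the substrate around the sample
are visible in several consecutive slices; their centers stay fixed with
depth and act as point-source fiducials for slice-to-slice and cross-modal
registration. The default detector is classical (smoothing -> global
threshold -> distance-transform watershed split); an externally produced
detection mask (e.g. from a trained segmentation network) can be supplied
instead.

Each detection is fitted with the physical layer-emission model of
:mod:`beadframe.beadmodel` by maximum likelihood under Poisson statistics,
yielding sub-pixel centers, the 3D sphere radius, and the depth of the
optical surface relative to the bead. Small tissue fragments that leak
through detection fit poorly to the polar-symmetric model and end up with
unrealistically large radii; they are flagged as false positives when the
fitted radius exceeds 5x the catalog average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .beadmodel import OpticsParams, bead_profile

__all__ = [
    "BeadDetection",
    "BeadFit",
    "DetectorConfig",
    "detect_beads",
    "fit_bead_profile",
    "fit_catalog",
    "flag_false_positives",
]

#: fit_quality value marking a failed/non-converged fit
FAILED_FIT = np.inf


@dataclass
class BeadDetection:
    label_id: int
    bbox: tuple[int, int, int, int]      # (y0, x0, y1, x1)
    mask: np.ndarray
    area: int
    centroid: tuple[float, float]        # (x, y)


@dataclass
class BeadFit:
    center_xy: tuple[float, float]       # sub-pixel, px, mosaic frame
    radius_3d: float                     # sphere radius R, um
    depth: float                         # optical-surface depth of center, um
    amplitude: float
    background: float
    snr: float
    fit_quality: float                   # mean Pearson chi^2 per pixel; inf = failed
    label_id: int = -1
    converged: bool = True

    @property
    def failed(self) -> bool:
        return not np.isfinite(self.fit_quality)


@dataclass
class DetectorConfig:
    smooth_sigma: float = 2.0
    #: 'sigma' = sigma-clipped background + nsigma*sd (robust when bright
    #: extended tissue dominates the histogram); 'otsu' or a number also work
    threshold: str | float = "sigma"
    nsigma: float = 4.0
    min_area_px: int = 30
    max_area_px: int | None = None       # drop components too big to be beads
    min_peak_separation_px: int = 8


def detect_beads(mosaic: np.ndarray, confidence: np.ndarray | None = None,
                 config: DetectorConfig | None = None,
                 external_mask: np.ndarray | None = None) -> list[BeadDetection]:
    """Candidate bead detections as disjoint labeled masks.

    With ``external_mask`` supplied (e.g. a network-produced detection mask),
    only the watershed split into individual beads is performed.
    """
    from skimage.filters import gaussian, threshold_otsu
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    cfg = config or DetectorConfig()
    img = np.asarray(mosaic, dtype=float)
    valid = confidence > 0 if confidence is not None else np.ones_like(img, bool)

    if external_mask is not None:
        binary = np.asarray(external_mask) > 0
    else:
        sm = gaussian(img, sigma=cfg.smooth_sigma, preserve_range=True)
        vals = sm[valid]
        if vals.size == 0 or vals.max() <= vals.min():
            return []
        if cfg.threshold == "otsu":
            thr = threshold_otsu(vals)
        elif cfg.threshold == "sigma":
            # median/MAD background: robust even when bright extended tissue
            # covers a sizable fraction of the field
            med = np.median(vals)
            mad_sd = 1.4826 * np.median(np.abs(vals - med))
            thr = med + cfg.nsigma * max(mad_sd, 1e-12)
        else:
            thr = float(cfg.threshold)
        binary = (sm > thr) & valid
    if not binary.any():
        return []

    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=cfg.min_peak_separation_px,
                           labels=binary, exclude_border=False)
    markers = np.zeros_like(img, dtype=np.int32)
    for k, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = k
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)

    out = []
    for lbl in range(1, labels.max() + 1):
        mask = labels == lbl
        area = int(mask.sum())
        if area < cfg.min_area_px:
            continue
        if cfg.max_area_px is not None and area > cfg.max_area_px:
            continue
        ys, xs = np.nonzero(mask)
        bbox = (ys.min(), xs.min(), ys.max() + 1, xs.max() + 1)
        out.append(BeadDetection(label_id=lbl, bbox=bbox, mask=mask,
                                 area=area,
                                 centroid=(float(xs.mean()), float(ys.mean()))))
    return out


def _poisson_nll(mu: np.ndarray, k: np.ndarray) -> float:
    mu = np.clip(mu, 1e-9, None)
    return float(np.sum(mu - k * np.log(mu)))


def fit_bead_profile(cutout: np.ndarray, pixel_scale_um: float,
                     optics: OpticsParams | None = None,
                     initial_guess: dict | None = None,
                     origin: tuple[float, float] = (0.0, 0.0),
                     max_radius_um: float | None = None) -> BeadFit:
    """Poisson maximum-likelihood fit of the bead emission model to a cutout.

    Free parameters: center (x0, y0), sphere radius R, center depth zc,
    emissivity amplitude and background; the excitation-layer and substrate
    constants (``optics``) are per-sample and held fixed. Optimization is a
    derivative-free simplex refinement from a moment-based initial guess
    (background from the border, centroid and equivalent-area radius from
    the thresholded signal).

    Non-convergence or degenerate input yields a flagged fit
    (``fit_quality = inf``), never an exception.
    """
    optics = optics or OpticsParams()
    data = np.asarray(cutout, dtype=float)
    h, w = data.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    border = np.concatenate([data[0], data[-1], data[:, 0], data[:, -1]])
    bg0 = float(np.median(border))
    signal = data - bg0
    peak = float(signal.max())
    noise_floor = max(np.sqrt(max(bg0, 1.0)), 1e-3)
    if peak < 3 * noise_floor:
        return BeadFit(center_xy=origin, radius_3d=0.0, depth=0.0,
                       amplitude=0.0, background=bg0, snr=0.0,
                       fit_quality=FAILED_FIT, converged=False)

    mask = signal > 0.3 * peak
    area = float(mask.sum())
    cx = float((xx * mask * signal.clip(0)).sum() / (mask * signal.clip(0)).sum())
    cy = float((yy * mask * signal.clip(0)).sum() / (mask * signal.clip(0)).sum())
    r_eq_px = np.sqrt(area / np.pi)
    r_eq_um = r_eq_px * pixel_scale_um
    r0 = max(r_eq_um * 1.05, 2 * pixel_scale_um)
    zc0 = optics.z_mid  # start with the surface cutting through the center

    def model(p):
        x0, y0, r_um, zc, amp, bg = p
        return bead_profile(xx, yy, x0, y0, r_um, zc, amp, bg, optics,
                            pixel_scale_um)

    # scale amplitude so the model peak matches the observed peak
    probe = bead_profile(np.array([cx]), np.array([cy]), cx, cy, r0, zc0,
                         1.0, 0.0, optics, pixel_scale_um)[0]
    amp0 = peak / max(probe, 1e-9)
    p0 = np.array([cx, cy, r0, zc0, amp0, max(bg0, 1e-3)])
    if initial_guess:
        keys = ["x0", "y0", "radius_um", "depth_um", "amplitude", "background"]
        for i, k in enumerate(keys):
            if k in initial_guess:
                p0[i] = initial_guess[k]

    rmax = max_radius_um or 4 * max(r0, 10 * pixel_scale_um)

    def objective(p):
        x0, y0, r_um, zc, amp, bg = p
        if not (0 < r_um < rmax and amp > 0 and bg >= 0):
            return 1e30
        if not (-2 * w < x0 < 3 * w and -2 * h < y0 < 3 * h):
            return 1e30
        return _poisson_nll(model(p), data)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(objective, p0, method="Nelder-Mead",
                                options=dict(maxiter=1500, xatol=1e-3,
                                             fatol=1e-8 * max(data.sum(), 1.0)))
        # restart the simplex from the first optimum: breaks out of the
        # collapsed simplex the R/depth degeneracy tends to produce
        res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                options=dict(maxiter=1500, xatol=1e-5,
                                             fatol=1e-10 * max(data.sum(), 1.0)))
    p = res.x
    mu = np.clip(model(p), 1e-9, None)
    quality = float(np.mean((data - mu) ** 2 / mu))
    converged = np.isfinite(quality) and res.fun < 1e29
    x0, y0, r_um, zc, amp, bg = p
    peak_fit = float(mu.max() - bg)
    snr = peak_fit * np.sqrt(max(area, 1.0)) / np.sqrt(max(bg + peak_fit, 1e-9))
    # a "bead" collapsing to sub-pixel size is a noise spike, not a sphere
    if not converged or r_um <= 1.5 * pixel_scale_um:
        quality = FAILED_FIT
        converged = False
    return BeadFit(center_xy=(x0 + origin[0], y0 + origin[1]),
                   radius_3d=float(r_um), depth=float(zc),
                   amplitude=float(amp), background=float(bg),
                   snr=float(snr), fit_quality=quality,
                   converged=converged)


def fit_catalog(mosaic: np.ndarray, detections: list[BeadDetection],
                pixel_scale_um: float, optics: OpticsParams | None = None,
                pad_px: int = 8, max_cutout_px: int = 96,
                slice_index: int = 0) -> pd.DataFrame:
    """Fit every detection and return the slice bead catalog as a table.

    Cutouts are clamped to ``max_cutout_px`` around the detection centroid
    so oversized (non-bead) components stay cheap to reject.
    """
    h, w = mosaic.shape
    rows = []
    for det in detections:
        y0, x0, y1, x1 = det.bbox
        y0, x0 = max(0, y0 - pad_px), max(0, x0 - pad_px)
        y1, x1 = min(h, y1 + pad_px), min(w, x1 + pad_px)
        if y1 - y0 > max_cutout_px or x1 - x0 > max_cutout_px:
            cx, cy = det.centroid
            half = max_cutout_px // 2
            x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half)
            y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half)
        fit = fit_bead_profile(mosaic[y0:y1, x0:x1], pixel_scale_um,
                               optics=optics, origin=(x0, y0))
        rows.append(dict(slice=slice_index, label=det.label_id,
                         x=fit.center_xy[0], y=fit.center_xy[1],
                         r_um=fit.radius_3d, depth_um=fit.depth,
                         snr=fit.snr, flux=fit.amplitude,
                         fit_quality=fit.fit_quality,
                         converged=fit.converged))
    cols = ["slice", "label", "x", "y", "r_um", "depth_um", "snr", "flux",
            "fit_quality", "converged"]
    return pd.DataFrame(rows, columns=cols)


def flag_false_positives(catalog: pd.DataFrame,
                         radius_factor: float = 5.0) -> pd.DataFrame:
    """Flag fits whose radius exceeds ``radius_factor`` times the average.

    Failed fits are flagged outright. Returns a copy with a boolean
    ``false_positive`` column; the flagged fraction (of usable fits) is
    stored in ``df.attrs['false_positive_fraction']``.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    cat = catalog.copy()
    ok = cat["converged"] & np.isfinite(cat["fit_quality"]) if "converged" in cat else \
        np.isfinite(cat["fit_quality"])
    mean_r = cat.loc[ok, "r_um"].mean()
    cat["false_positive"] = (~ok) | (cat["r_um"] > radius_factor * mean_r)
    n_ok = int(ok.sum())
    cat.attrs["false_positive_fraction"] = float(
        (cat.loc[ok, "r_um"] > radius_factor * mean_r).sum() / max(n_ok, 1))
    return cat
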