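"""Federation of single-slice modalities into the volume reference frame.

A physical section imaged on a slide scanner (and later, in part, by
imaging mass cytometry) must be placed back into the 3D volume: find which
volume slice it came from, the affine mapping between pixel frames, and the
registration error. The model is strictly affine (6 degrees of freedom),
anchored on the fiducial bead centers which are visible in every modality.

Steps:

* a coarse intensity match between the downsampled slide image and the
  downsampled median volume image over the four flip hypotheses gives the
  left/right / top/bottom orientation and an initial transform;
* per volume slice, the transform is refined by iterating nearest-neighbor
  bead matching and weighted affine fitting to a fixed point; the per-slice
  matched-bead count N(Z) is fitted with a Gaussian and the best slice is
  the one closest to the fitted maximum (a flat profile marks an orphan
  slide that has no volume counterpart);
* transforms compound across modalities (e.g. small-field -> slide ->
  volume) and may be refined once more against the volume beads;
* errors are the Cartesian distances (um) between volume bead centers and
  the reprojected modality centers: per-pair distances, their cumulative
  distribution, and the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

from .geometry import AffineTransform, Orientation, fit_affine, fit_rigid

__all__ = [
    "OrphanSlideError",
    "SliceMatchProfile",
    "FederationResult",
    "coarse_orientation_match",
    "refine_affine_by_beads",
    "match_slide_to_slice",
    "compound_chain",
    "registration_error",
]


class OrphanSlideError(ValueError):
    """No acceptable match between the slide and any volume slice."""


@dataclass
class SliceMatchProfile:
    n_matches: np.ndarray                 # N(Z) per volume slice
    gaussian: tuple[float, float, float, float] | None  # amp, mean, sigma, floor
    best_z: int | None
    confidence: float
    orphan: bool = False
    transforms: dict = field(default_factory=dict)  # z -> (transform, n, resid)


@dataclass
class FederationResult:
    chain: list[AffineTransform]
    compound: AffineTransform
    distances_um: np.ndarray
    median_um: float

    def cdf(self) -> pd.DataFrame:
        d = np.sort(self.distances_um)
        return pd.DataFrame(dict(distance_um=d,
                                 fraction=(np.arange(len(d)) + 1) / len(d)))


def _block_reduce_mean(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape
    hh, ww = h - h % f, w - w % f
    return img[:hh, :ww].reshape(hh // f, f, ww // f, f).mean(axis=(1, 3))


def _ncc_at_shift(a: np.ndarray, b: np.ndarray, dx: int, dy: int) -> float:
    """Pearson correlation of the overlap of b shifted by (dx, dy) over a."""
    ha, wa = a.shape
    hb, wb = b.shape
    ax0, ax1 = max(0, dx), min(wa, dx + wb)
    ay0, ay1 = max(0, dy), min(ha, dy + hb)
    if ax1 - ax0 < 8 or ay1 - ay0 < 8:
        return -1.0
    oa = a[ay0:ay1, ax0:ax1]
    ob = b[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
    sa, sb = oa.std(), ob.std()
    if sa < 1e-9 or sb < 1e-9:
        return -1.0
    return float(((oa - oa.mean()) * (ob - ob.mean())).mean() / (sa * sb))


def _masked_ncc_surface(a: np.ndarray, b: np.ndarray,
                        min_overlap_frac: float = 0.25):
    """Normalized cross-correlation of b against a for every displacement.

    Computed exactly over each overlap via five FFT cross-correlations
    (counts, sums, sums of squares, cross term); displacements whose
    overlap is below ``min_overlap_frac`` of the smaller image are scored
    ``-inf``. Returns ``(ncc, (dys, dxs))`` index arrays.
    """
    from scipy.signal import fftconvolve

    def corr(f, g):
        return fftconvolve(f, g[::-1, ::-1], mode="full")

    one_a, one_b = np.ones_like(a), np.ones_like(b)
    n = corr(one_a, one_b)
    sa, sb = corr(a, one_b), corr(one_a, b)
    saa, sbb = corr(a * a, one_b), corr(one_a, b * b)
    sab = corr(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.where(n > 1, n, 1)
        cov = sab / n_safe - (sa / n_safe) * (sb / n_safe)
        var_a = saa / n_safe - (sa / n_safe) ** 2
        var_b = sbb / n_safe - (sb / n_safe) ** 2
        ncc = cov / np.sqrt(np.clip(var_a, 1e-12, None)
                            * np.clip(var_b, 1e-12, None))
    ncc[n < min_overlap_frac * min(a.size, b.size)] = -np.inf
    hb, wb = b.shape
    dys = np.arange(n.shape[0]) - (hb - 1)
    dxs = np.arange(n.shape[1]) - (wb - 1)
    return ncc, (dys, dxs)


def coarse_orientation_match(slide_image: np.ndarray,
                             volume_median_image: np.ndarray,
                             downsample: int = 32,
                             min_correlation: float = 0.2,
                             return_candidates: bool = False):
    """Resolve the flip state and an initial transform by intensity matching.

    Both images are block-averaged by ``downsample``; each of the four flip
    hypotheses of the slide is scored by exact masked normalized
    cross-correlation over all displacements, and the best peak wins.
    Returns ``(orientation, initial_transform, score)`` with the transform
    mapping slide px -> volume px, or — with ``return_candidates=True`` — the
    full score-ranked list of ``(orientation, transform, score)`` hypotheses
    (near-symmetric samples can leave the flip ambiguous at the intensity
    level; downstream bead matching then disambiguates). All-poor
    correlations raise :class:`OrphanSlideError`.
    """
    if slide_image.size == 0 or volume_median_image.size == 0:
        raise ValueError("empty image")
    sl = _block_reduce_mean(np.asarray(slide_image, float), downsample)
    vol = _block_reduce_mean(np.asarray(volume_median_image, float), downsample)
    h_s, w_s = slide_image.shape

    candidates = []
    for orient in Orientation.all():
        cand = orient.apply_to_image(sl)
        ncc, (dys, dxs) = _masked_ncc_surface(vol, cand)
        k = np.argmax(ncc)
        iy, ix = np.unravel_index(k, ncc.shape)
        score = float(ncc[iy, ix])
        flip = orient.as_affine(w_s, h_s)
        shift = AffineTransform.from_translation(dxs[ix] * downsample,
                                                 dys[iy] * downsample)
        t = shift.compose(flip)
        t = AffineTransform(t.linear, t.translation,
                            src_frame="slide", dst_frame="volume")
        candidates.append((orient, t, score))
    candidates.sort(key=lambda c: -c[2])
    best_score = candidates[0][2]
    if best_score < min_correlation:
        raise OrphanSlideError(
            f"no orientation correlates above {min_correlation} "
            f"(best {best_score:.2f})")
    if return_candidates:
        return candidates
    orient, initial, score = candidates[0]
    return orient, initial, score


def refine_affine_by_beads(src_beads, dst_beads, initial: AffineTransform,
                           match_radius: float, refine_radius: float | None = None,
                           max_iter: int = 10, min_matches: int = 3,
                           model: str = "affine"):
    """Iterate bead match -> affine fit -> re-match to a fixed point.

    ``model='rigid'`` restricts each fit to translation + rotation — the
    simplified path for fields with critically few beads, later compounded
    with a well-determined transform to the volume.

    ``match_radius`` is used for the first match; after the first fit the
    radius shrinks to ``refine_radius`` (default: a third of the initial).
    The best iteration by (match count, -median residual) is kept, so the
    returned match count never decreases relative to any earlier iteration.

    Returns ``(transform, n_matches, pairs)`` with ``pairs`` an index array
    (n, 2) of matched (src, dst) rows.
    """
    src = np.atleast_2d(np.asarray(src_beads, float))
    dst = np.atleast_2d(np.asarray(dst_beads, float))
    if len(src) < min_matches or len(dst) < min_matches:
        raise ValueError("need at least 3 beads on each side")
    if refine_radius is None:
        refine_radius = match_radius / 3.0
    tree = cKDTree(dst)

    t = initial
    best = None
    prev_pairs = None
    for it in range(max_iter):
        radius = match_radius if it == 0 else refine_radius
        proj = t.apply(src)
        d, nn = tree.query(proj, k=1, distance_upper_bound=radius)
        ok = np.isfinite(d) & (nn < len(dst))
        # one-to-one: keep the closest src for each dst
        pairs = {}
        for i in np.nonzero(ok)[0]:
            j = nn[i]
            if j not in pairs or d[i] < d[pairs[j]]:
                pairs[j] = i
        match = np.array([(i, j) for j, i in sorted(pairs.items())], dtype=int)
        if len(match) < min_matches:
            break
        fitter = fit_rigid if model == "rigid" else fit_affine
        fit = fitter(src[match[:, 0]], dst[match[:, 1]])
        t = AffineTransform(fit.transform.linear, fit.transform.translation,
                            src_frame=initial.src_frame,
                            dst_frame=initial.dst_frame)
        resid = np.median(fit.residuals) if len(fit.residuals) else np.inf
        key = (len(match), -resid)
        if best is None or key > best[0]:
            best = (key, t, match)
        if prev_pairs is not None and len(match) == len(prev_pairs) \
                and np.array_equal(match, prev_pairs):
            break
        prev_pairs = match
    if best is None:
        raise ValueError("degenerate: fewer than 3 bead matches at convergence")
    _, t, match = best
    return t, len(match), match


def match_slide_to_slice(slide_beads, per_slice_catalogs: list,
                         initial: AffineTransform, match_radius: float,
                         min_peak_matches: int = 4) -> SliceMatchProfile:
    """Find the volume slice a slide came from by maximizing bead matches.

    Runs the bead refinement against every slice catalog to build N(Z),
    fits a Gaussian with a constant floor, and returns the available slice
    index closest to the fitted maximum. A flat or empty profile yields an
    orphan result (``orphan=True``), not an exception.
    """
    n_z = len(per_slice_catalogs)
    if n_z < 2:
        raise ValueError("need at least 2 slices")
    counts = np.zeros(n_z)
    transforms = {}
    for z, cat in enumerate(per_slice_catalogs):
        pts = cat[["x", "y"]].to_numpy(float) if isinstance(cat, pd.DataFrame) \
            else np.asarray(cat, float)
        if len(pts) < 3:
            continue
        try:
            t, n, match = refine_affine_by_beads(slide_beads, pts, initial,
                                                 match_radius)
        except ValueError:
            continue
        counts[z] = n
        transforms[z] = (t, n, match)

    if counts.max() < min_peak_matches or counts.max() <= np.median(counts) + 1:
        return SliceMatchProfile(n_matches=counts, gaussian=None, best_z=None,
                                 confidence=0.0, orphan=True,
                                 transforms=transforms)

    z = np.arange(n_z, dtype=float)
    amp0 = counts.max() - counts.min()
    mu0 = float(np.argmax(counts))
    floor0 = float(np.median(counts))

    def gauss(zz, amp, mu, sig, floor):
        return floor + amp * np.exp(-0.5 * ((zz - mu) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(gauss, z, counts,
                                     p0=[amp0, mu0, 2.0, floor0],
                                     maxfev=5000)
        amp, mu, sig, floor = popt
        sig = abs(sig)
    except RuntimeError:
        amp, mu, sig, floor = amp0, mu0, 2.0, floor0
    if not (0 - 1 <= mu <= n_z):  # peak outside the sampled range -> orphan
        return SliceMatchProfile(n_matches=counts, gaussian=(amp, mu, sig, floor),
                                 best_z=None, confidence=0.0, orphan=True,
                                 transforms=transforms)
    avail = np.array(sorted(transforms.keys()))
    best_z = int(avail[np.argmin(np.abs(avail - mu))])
    conf = float(amp / (floor + 1.0))
    return SliceMatchProfile(n_matches=counts, gaussian=(amp, mu, sig, floor),
                             best_z=best_z, confidence=conf, orphan=False,
                             transforms=transforms)


def compound_chain(transforms: list[AffineTransform],
                   reference_beads=None, moving_beads=None,
                   refine_radius: float | None = None) -> AffineTransform:
    """Compose a frame-contiguous transform chain (first applied first).

    ``transforms[k]`` must map frame k -> frame k+1 (``dst_frame`` of k
    equals ``src_frame`` of k+1 when frames are labeled). If
    ``moving_beads``/``reference_beads`` are supplied, one refinement pass
    against the reference updates the compound.
    """
    if not transforms:
        raise ValueError("empty chain")
    for a, b in zip(transforms, transforms[1:]):
        if a.dst_frame and b.src_frame and a.dst_frame != b.src_frame:
            raise ValueError(f"frame mismatch in chain: {a.dst_frame!r} != "
                             f"{b.src_frame!r}")
    comp = transforms[0]
    for t in transforms[1:]:
        comp = t.compose(comp)
    if reference_beads is not None and moving_beads is not None:
        radius = refine_radius if refine_radius is not None else 10.0
        try:
            comp, _, _ = refine_affine_by_beads(moving_beads, reference_beads,
                                                comp, radius, radius)
        except ValueError:
            # too few / degenerate matches: the unrefined compound is still
            # the best available estimate
            import warnings
            warnings.warn("compound refinement degenerate; returning the "
                          "unrefined compound transform")
    return comp


def registration_error(reference_beads, reprojected_beads,
                       pixel_scale_um: float = 1.0,
                       chain: list[AffineTransform] | None = None,
                       compound: AffineTransform | None = None) -> FederationResult:
    """Cartesian distances (um) between reference and reprojected bead centers."""
    ref = np.atleast_2d(np.asarray(reference_beads, float))
    rep = np.atleast_2d(np.asarray(reprojected_beads, float))
    if ref.shape != rep.shape or len(ref) == 0:
        raise ValueError("need matched, equal-length point sets")
    d = np.linalg.norm(ref - rep, axis=1) * pixel_scale_um
    return FederationResult(chain=chain or [],
                            compound=compound or AffineTransform.identity(),
                            distances_um=d, median_um=float(np.median(d)))
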