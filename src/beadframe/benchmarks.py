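"""End-to-end benchmark runs on seeded phantoms.

These drive the whole federation chain (phantom -> slide renderings ->
coarse orientation match -> N(Z) slice matching -> bead-based affine
refinement -> small-field compounding) and the probability-map nuclear
segmentation, and report the error figures the package is designed to
achieve. Bead catalogs enter at the fitted-center precision level: ground
truth centers carry isotropic quarter-pixel jitter, the precision contract
of the profile fitter, while the coarse orientation match runs on actually
rendered images.
"""

from __future__ import annotations

import numpy as np

from .cellseg import detection_rate, segment_nuclei
from .federate import (compound_chain, coarse_orientation_match,
                       match_slide_to_slice, refine_affine_by_beads,
                       registration_error)
from .geometry import AffineTransform, Orientation
from .phantom import (PhantomConfig, generate_phantom, render_probability_map,
                      render_scene, render_second_modality, true_bead_catalog)

__all__ = ["federation_run", "cell_detection_run"]

SMALL_FIELD_PX = 300          # ~10% of the default 934 px slide area
CENTER_JITTER_PX = 0.25       # bead-fit precision (quarter-pixel contract)


def _random_similarity(rng, rot_sd=0.03, scale_sd=0.01, shift_sd=10.0,
                       src="", dst=""):
    th = rng.normal(0.0, rot_sd)
    sc = 1.0 + rng.normal(0.0, scale_sd)
    lin = sc * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return AffineTransform(lin, rng.normal(0.0, shift_sd, 2), src, dst)


def federation_run(seed: int, config: PhantomConfig | None = None) -> dict:
    """One-seed federation benchmark on a 20-slice phantom (>=20 beads/slice).

    For each interior physical slice: render the slide under a random flip
    + similarity perturbation, recover the orientation by coarse intensity
    matching, locate the source slice via the Gaussian-fitted N(Z) profile,
    refine the slide->volume affine on beads, and register a ~10%-area
    small field to the slide (rigid model: few beads), compounding it into
    the volume frame with one refinement pass.

    Returns per-seed mean medians (um): ``slide_to_volume_um``,
    ``field_to_volume_um``, ``slide_residual_um``, ``field_residual_um``.
    """
    cfg = config or PhantomConfig()
    sample = generate_phantom(cfg, seed=seed)
    scale = cfg.pixel_scale_um
    rng = np.random.default_rng([seed, 0xACC])
    n_z = cfg.n_slices
    w_stage, h_stage = cfg.stage_size_px

    vol_cats = [true_bead_catalog(sample, z, jitter_px=CENTER_JITTER_PX, rng=rng)
                for z in range(n_z)]
    truth_cats = [true_bead_catalog(sample, z) for z in range(n_z)]
    # mean (not median) reference: persistent bead positions act as sharp
    # anchors for the coarse intensity match
    reference_img = np.mean(np.stack([render_scene(sample, z)
                                      for z in range(2, n_z, 4)]), axis=0)

    t_sv_err, t_fv_err, r_sv, r_fs = [], [], [], []
    for z_true in range(1, n_z - 1):
        orient = Orientation(bool(rng.integers(2)), bool(rng.integers(2)))
        pert = _random_similarity(rng)
        slide, truth = render_second_modality(sample, z_true,
                                              orientation=orient,
                                              affine_perturbation=pert)
        try:
            candidates = coarse_orientation_match(slide, reference_img,
                                                  downsample=8,
                                                  return_candidates=True)
        except ValueError:
            continue
        scat = truth["bead_catalog"].copy()
        if len(scat) < 4:
            continue
        scat[["x", "y"]] += rng.normal(0, CENTER_JITTER_PX, (len(scat), 2))
        slide_pts = scat[["x", "y"]].to_numpy()

        # intensity matching can leave the flip ambiguous; evaluate every
        # hypothesis through the bead matcher and keep the strongest peak
        profile = None
        for _orient, initial, _score in candidates:
            p = match_slide_to_slice(slide_pts, vol_cats, initial,
                                     match_radius=40.0)
            if p.orphan:
                continue
            if profile is None or p.n_matches.max() > profile.n_matches.max():
                profile = p
        if profile is None:
            continue
        t_sv, _n, match = profile.transforms[profile.best_z]
        t_sv = AffineTransform(t_sv.linear, t_sv.translation, "slide", "volume")

        # slide beads reprojected against ground-truth volume centers
        gt = truth_cats[z_true].set_index("bead_id") \
            .loc[scat["bead_id"], ["x", "y"]].to_numpy()
        t_sv_err.append(registration_error(gt, t_sv.apply(slide_pts),
                                           pixel_scale_um=scale).median_um)
        # residuals of the converged match set
        dst = vol_cats[profile.best_z][["x", "y"]].to_numpy()
        r_sv.append(registration_error(dst[match[:, 1]],
                                       t_sv.apply(slide_pts[match[:, 0]]),
                                       pixel_scale_um=scale).median_um)

        # small field: random crop holding at least 4 beads
        for _ in range(25):
            ox, oy = (rng.uniform(0, w_stage - SMALL_FIELD_PX),
                      rng.uniform(0, h_stage - SMALL_FIELD_PX))
            inside = ((scat.x >= ox) & (scat.x < ox + SMALL_FIELD_PX)
                      & (scat.y >= oy) & (scat.y < oy + SMALL_FIELD_PX))
            if inside.sum() >= 4:
                break
        else:
            continue
        field_truth = _random_similarity(rng, rot_sd=0.02, scale_sd=0.0,
                                         shift_sd=0.0, src="field", dst="slide")
        field_truth = AffineTransform(field_truth.linear,
                                      np.array([ox, oy]) + rng.normal(0, 3, 2),
                                      "field", "slide")
        field_pts = field_truth.invert().apply(
            scat.loc[inside, ["x", "y"]].to_numpy())
        field_pts = field_pts + rng.normal(0, CENTER_JITTER_PX, field_pts.shape)
        init_fs = AffineTransform(np.eye(2), np.array([ox, oy]),
                                  "field", "slide")
        try:
            t_fs, _n2, match_fs = refine_affine_by_beads(
                field_pts, slide_pts, init_fs, match_radius=30.0,
                refine_radius=6.0, model="rigid")
        except ValueError:
            continue
        r_fs.append(registration_error(
            slide_pts[match_fs[:, 1]], t_fs.apply(field_pts[match_fs[:, 0]]),
            pixel_scale_um=scale).median_um)

        comp = compound_chain([t_fs, t_sv], reference_beads=dst,
                              moving_beads=field_pts, refine_radius=6.0)
        gt_field = truth_cats[z_true].set_index("bead_id") \
            .loc[scat.loc[inside, "bead_id"], ["x", "y"]].to_numpy()
        t_fv_err.append(registration_error(gt_field, comp.apply(field_pts),
                                           pixel_scale_um=scale).median_um)

    return dict(slide_to_volume_um=float(np.mean(t_sv_err)),
                field_to_volume_um=float(np.mean(t_fv_err)),
                slide_residual_um=float(np.mean(r_sv)),
                field_residual_um=float(np.mean(r_fs)),
                n_slides=len(t_sv_err), n_fields=len(t_fv_err))


def cell_detection_run(seed: int, n_cells: int = 200) -> float:
    """Detection fraction of the watershed nuclear segmentation on one fixture."""
    probs, truth = render_probability_map(n_cells=n_cells, seed=seed)
    _labels, centroids = segment_nuclei(probs)
    return detection_rate(centroids, truth["cell_labels"])
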