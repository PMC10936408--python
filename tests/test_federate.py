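"""Cross-modal federation: orientation, slice matching, refinement, errors."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from beadframe.federate import (OrphanSlideError, coarse_orientation_match,
                                compound_chain, match_slide_to_slice,
                                refine_affine_by_beads, registration_error)
from beadframe.geometry import AffineTransform, Orientation, fit_affine


def _blobby_image(rng, shape=(256, 256)):
    img = ndimage.gaussian_filter(rng.normal(0, 1, shape), 12)
    return img / img.std() * 100 + 150


class TestCoarseMatch:
    def test_unflipped_copy_gives_identity(self, rng):
        img = _blobby_image(rng)
        orient, t, score = coarse_orientation_match(img, img, downsample=8)
        assert (orient.flip_x, orient.flip_y) == (False, False)
        assert np.allclose(t.linear, np.eye(2))
        assert np.abs(t.translation).max() <= 8
        assert score > 0.9

    @pytest.mark.parametrize("fx,fy", [(True, False), (False, True), (True, True)])
    def test_known_flip_recovered(self, rng, fx, fy):
        """Oracle: exhaustive 4-orientation correlation."""
        img = _blobby_image(rng)
        orient = Orientation(fx, fy)
        slide = orient.apply_to_image(img)
        got, _t, _s = coarse_orientation_match(slide, img, downsample=8)
        assert (got.flip_x, got.flip_y) == (fx, fy)

    def test_flip_and_translation_recovered(self, rng):
        img = _blobby_image(rng, (256, 256))
        shifted = np.roll(img, (16, -24), axis=(0, 1))  # dy=16, dx=-24
        slide = Orientation(True, False).apply_to_image(shifted)
        orient, t, _s = coarse_orientation_match(slide, img, downsample=8)
        assert orient.flip_x and not orient.flip_y
        # the transform maps slide pixels onto volume pixels: probe a point
        probe = np.array([[100.0, 100.0]])
        mapped = t.apply(probe)[0]
        expect = np.array([255 - 100 + 24, 100 - 16])
        assert np.abs(mapped - expect).max() <= 2 * 8  # 2 px at downsample 8

    def test_uncorrelated_images_raise_orphan(self, rng):
        a = _blobby_image(rng)
        b = rng.normal(0, 1, (256, 256))
        with pytest.raises(OrphanSlideError):
            coarse_orientation_match(a, b, downsample=8, min_correlation=0.5)


class TestRefine:
    def test_exact_recovery_without_noise(self, rng):
        t = AffineTransform(np.array([[1.01, 0.03], [-0.02, 0.99]]),
                            np.array([5.0, -8.0]))
        src = rng.uniform(0, 400, (30, 2))
        dst = t.apply(src)
        got, n, match = refine_affine_by_beads(src, dst,
                                               AffineTransform.identity(),
                                               match_radius=30.0)
        assert n == 30
        # oracle: direct fit on the true correspondences
        oracle = fit_affine(src, dst).transform
        assert np.abs(got.apply(src) - oracle.apply(src)).max() < 1e-6

    def test_identity_case_matches_everything(self, rng):
        pts = rng.uniform(0, 300, (15, 2))
        got, n, _ = refine_affine_by_beads(pts, pts, AffineTransform.identity(),
                                           match_radius=10.0)
        assert n == 15
        assert np.abs(got.linear - np.eye(2)).max() < 1e-9

    def test_match_count_never_decreases(self, rng):
        """The returned fixed point is at least as good as any iteration."""
        t = AffineTransform(np.eye(2), np.array([6.0, 2.0]))
        src = rng.uniform(0, 500, (40, 2))
        dst = t.apply(src) + rng.normal(0, 0.5, (40, 2))
        counts = []
        for radius in (8.0, 15.0, 25.0):
            _g, n, _m = refine_affine_by_beads(src, dst,
                                               AffineTransform.identity(),
                                               match_radius=radius)
            counts.append(n)
        assert counts[-1] == 40
        assert all(c <= 40 for c in counts)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            refine_affine_by_beads([(0, 0), (1, 1)], [(0, 0), (1, 1)],
                                   AffineTransform.identity(), 5.0)

    def test_rigid_model_within_2x_of_affine(self, rng):
        """Simplified translation+rotation path on a critically small field
        stays within 2x of the full-affine residuals."""
        theta = 0.02
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        t = AffineTransform(rot, np.array([10.0, -5.0]))
        src = rng.uniform(0, 150, (6, 2))
        dst = t.apply(src) + rng.normal(0, 0.4, (6, 2))
        res = {}
        for model in ("affine", "rigid"):
            got, _n, match = refine_affine_by_beads(
                src, dst, AffineTransform.identity(), match_radius=20.0,
                model=model)
            res[model] = np.median(np.linalg.norm(
                got.apply(src[match[:, 0]]) - dst[match[:, 1]], axis=1))
        assert res["rigid"] <= 2 * max(res["affine"], 0.2)


class TestSliceMatching:
    def _catalogs(self, rng, n_z=12, n=25):
        """Per-slice catalogs sharing beads across a few neighbors."""
        beads = rng.uniform(0, 600, (80, 2))
        z_center = rng.uniform(0, n_z - 1, 80)
        cats = []
        for z in range(n_z):
            sel = np.abs(z_center - z) < 2.5
            cats.append(pd.DataFrame(beads[sel], columns=["x", "y"]))
        return cats

    def test_slide_from_known_slice_found(self, rng):
        cats = self._catalogs(rng)
        z_true = 7
        slide = cats[z_true][["x", "y"]].to_numpy() + rng.normal(0, 0.3,
                                                                 (len(cats[z_true]), 2))
        prof = match_slide_to_slice(slide, cats, AffineTransform.identity(),
                                    match_radius=8.0)
        assert not prof.orphan
        assert abs(prof.best_z - z_true) <= 1

    def test_triangular_profile_peaks_at_center(self, rng):
        """Synthetic symmetric N(Z): best slice at the apex."""
        beads = rng.uniform(0, 500, (40, 2))
        cats = []
        n_z, z_star = 11, 5
        for z in range(n_z):
            k = max(40 - 7 * abs(z - z_star), 4)
            cats.append(pd.DataFrame(beads[:k], columns=["x", "y"]))
        slide = beads + rng.normal(0, 0.1, beads.shape)
        prof = match_slide_to_slice(slide, cats, AffineTransform.identity(),
                                    match_radius=5.0)
        assert prof.best_z == z_star

    def test_orphan_slide_flagged_not_raised(self, rng):
        cats = self._catalogs(rng)
        stranger = rng.uniform(2000, 3000, (20, 2))
        prof = match_slide_to_slice(stranger, cats, AffineTransform.identity(),
                                    match_radius=8.0)
        assert prof.orphan
        assert prof.best_z is None

    def test_invariant_under_slice_relabeling(self, rng):
        """Permuting the slice order permutes N(Z) accordingly."""
        cats = self._catalogs(rng)
        z_true = 4
        slide = cats[z_true][["x", "y"]].to_numpy()
        prof = match_slide_to_slice(slide, cats, AffineTransform.identity(),
                                    match_radius=8.0)
        perm = list(reversed(range(len(cats))))
        prof_r = match_slide_to_slice(slide, [cats[p] for p in perm],
                                      AffineTransform.identity(),
                                      match_radius=8.0)
        assert np.array_equal(prof_r.n_matches, prof.n_matches[perm])


class TestCompound:
    def test_chain_of_identities(self):
        ident = AffineTransform.identity("a", "a")
        c = compound_chain([ident, ident, ident])
        assert np.allclose(c.linear, np.eye(2))

    def test_compound_agrees_with_direct_fit(self, rng):
        """Compounded transform vs direct fit on the same correspondences."""
        t1 = AffineTransform(np.array([[1.02, 0.01], [0.0, 0.99]]),
                             np.array([3.0, 4.0]), "imc", "slide")
        t2 = AffineTransform(np.array([[0.98, -0.03], [0.02, 1.01]]),
                             np.array([-7.0, 2.0]), "slide", "volume")
        src = rng.uniform(0, 300, (25, 2))
        dst = t2.apply(t1.apply(src))
        comp = compound_chain([t1, t2])
        direct = fit_affine(src, dst).transform
        assert np.abs(comp.apply(src) - direct.apply(src)).max() < 1e-6

    def test_frame_mismatch_rejected(self):
        t1 = AffineTransform.identity("imc", "slide")
        t2 = AffineTransform.identity("volume", "stage")
        with pytest.raises(ValueError, match="frame mismatch"):
            compound_chain([t1, t2])

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            compound_chain([])


class TestRegistrationError:
    def test_identical_point_sets(self):
        pts = np.array([[0.0, 0.0], [10.0, 5.0]])
        res = registration_error(pts, pts)
        assert res.median_um == 0.0
        assert np.all(res.distances_um == 0)

    def test_uniform_offset(self):
        pts = np.zeros((8, 2))
        res = registration_error(pts, pts + [3.0, 0.0], pixel_scale_um=1.0)
        assert res.median_um == pytest.approx(3.0)

    def test_isotropic_jitter_median(self, rng):
        """Median distance under per-axis jitter agrees with an empirical
        Monte-Carlo oracle."""
        sigma = 2.0
        pts = np.zeros((4000, 2))
        res = registration_error(pts, rng.normal(0, sigma, (4000, 2)))
        oracle = np.median(np.linalg.norm(
            rng.normal(0, sigma, (200000, 2)), axis=1))
        assert res.median_um == pytest.approx(oracle, rel=0.05)

    def test_cdf_is_monotone_and_complete(self, rng):
        res = registration_error(np.zeros((50, 2)),
                                 rng.normal(0, 1, (50, 2)))
        cdf = res.cdf()
        assert cdf.fraction.iloc[-1] == 1.0
        assert (cdf.distance_um.diff().dropna() >= 0).all()

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            registration_error(np.zeros((3, 2)), np.zeros((4, 2)))
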