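"""Probability-map segmentation, tiling, normalization, features, scoring."""

import numpy as np
import pytest

from beadframe.cellseg import (detection_rate, dedup_tile_detections,
                               evaluate_segmentation, extract_features,
                               normalize_channel, segment_cells,
                               segment_nuclei, tile_image)
from beadframe.phantom import render_probability_map


class TestTiling:
    def test_single_tile_image(self):
        cube = np.zeros((2, 256, 256))
        ts = tile_image(cube, tile_size=256, stride=50)
        assert len(ts.tiles) == 1
        assert ts.origins == [(0, 0)]

    @pytest.mark.parametrize("width", [256, 300, 306, 410])
    def test_origin_arithmetic(self, width):
        """Origins are {0, 50, ...} with the final tile shifted inward;
        oracle: direct tiling arithmetic."""
        cube = np.zeros((1, 256, width))
        ts = tile_image(cube, tile_size=256, stride=50)
        xs = sorted({o[0] for o in ts.origins})
        expect = list(range(0, width - 256 + 1, 50))
        if expect[-1] != width - 256:
            expect.append(width - 256)
        assert xs == expect
        # full coverage
        cover = np.zeros(width, int)
        for x in xs:
            cover[x:x + 256] += 1
        assert cover.min() >= 1

    def test_small_image_zero_padded_with_warning(self):
        with pytest.warns(UserWarning, match="smaller than tile"):
            ts = tile_image(np.ones((1, 40, 40)), tile_size=64, stride=50)
        assert len(ts.tiles) == 1
        assert ts.tiles[0].shape == (1, 64, 64)
        assert ts.tiles[0][0, 50, 50] == 0.0

    def test_dedup_keeps_most_interior_instance(self):
        """Duplicated detections from overlapping tiles collapse to the copy
        farthest from its tile border (oracle: single-pass segmentation)."""
        # one object at image coords (60, 30), seen by tiles at 0 and 50
        per_tile = [np.array([[60.0, 30.0]]), np.array([[60.5, 30.0]])]
        origins = [(0, 0), (50, 0)]
        kept = dedup_tile_detections(per_tile, origins, tile_size=64,
                                     merge_radius=5.0)
        assert kept.shape == (1, 2)
        # tile at origin 0: border distance min(60, 30, 3, 33) = 3
        # tile at origin 50: min(10.5, 30, 53.5, 33) = 10.5 -> kept
        assert kept[0, 0] == 60.5

    def test_dedup_matches_untiled_segmentation(self):
        probs, truth = render_probability_map(n_cells=40, shape=(300, 300),
                                              seed=3)
        _labels, cents = segment_nuclei(probs)
        ts = tile_image(probs, tile_size=160, stride=50)
        per_tile, origins = [], []
        for tile, (ox, oy) in zip(ts.tiles, ts.origins):
            _l, c = segment_nuclei(tile)
            pts = c[["x", "y"]].to_numpy()
            if len(pts):
                pts = pts + [ox, oy]
            per_tile.append(pts)
            origins.append((ox, oy))
        kept = dedup_tile_detections(per_tile, origins, tile_size=160,
                                     merge_radius=6.0)
        assert abs(len(kept) - len(cents)) <= 0.1 * len(cents)


class TestNormalize:
    def test_endpoints_of_stretch(self):
        out = normalize_channel(np.array([[10.0, 20.0]]))
        assert out.dtype == np.uint16
        assert out[0, 0] == 0 and out[0, 1] == 65535

    def test_full_range_input_unchanged(self):
        img = np.array([[0.0, 65535.0], [32767.0, 16383.0]])
        out = normalize_channel(img)
        assert np.abs(out.astype(float) - img).max() <= 1.0

    def test_monotone(self, rng):
        img = rng.uniform(0, 1000, (40, 40))
        out = normalize_channel(img).astype(float)
        i = np.argsort(img.ravel())
        assert (np.diff(out.ravel()[i]) >= 0).all()

    def test_constant_image_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="zero dynamic range"):
            out = normalize_channel(np.full((8, 8), 3.0))
        assert not out.any()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_channel(np.array([[1.0, np.nan]]))


class TestSegmentNuclei:
    def test_one_isolated_blob(self):
        probs, _ = render_probability_map(n_cells=1, shape=(80, 80),
                                          noise=0.0, seed=4)
        labels, cents = segment_nuclei(probs)
        assert labels.max() == 1
        assert len(cents) == 1

    def test_two_touching_blobs_split(self):
        """Two overlapping nuclei with distinct distance-transform peaks
        (oracle: peak count of the noiseless truth) split into two."""
        from scipy import ndimage as ndi
        yy, xx = np.mgrid[0:80, 0:80]
        nuc = (np.exp(-(((xx - 33) ** 2 + (yy - 40) ** 2) / 36) ** 2)
               + np.exp(-(((xx - 47) ** 2 + (yy - 40) ** 2) / 36) ** 2))
        nuc = np.clip(nuc, 0, 1)
        probs = np.stack([1 - nuc, nuc, np.zeros_like(nuc)])
        # truth: two local maxima in the distance map of the support
        from skimage.feature import peak_local_max
        dist = ndi.distance_transform_edt(nuc > 0.3)
        n_peaks = len(peak_local_max(dist, min_distance=4))
        labels, cents = segment_nuclei(probs, min_distance=4)
        assert labels.max() == len(cents) == n_peaks == 2

    def test_empty_foreground_zero_nuclei(self):
        probs = np.stack([np.ones((40, 40)), np.zeros((40, 40)),
                          np.zeros((40, 40))])
        labels, cents = segment_nuclei(probs)
        assert labels.max() == 0 and cents.empty

    def test_detection_rate_against_ground_truth(self):
        rates = []
        for seed in range(3):
            probs, truth = render_probability_map(n_cells=200, seed=seed)
            _labels, cents = segment_nuclei(probs)
            rates.append(detection_rate(cents, truth["cell_labels"]))
        assert np.mean(rates) >= 0.89


class TestSegmentCells:
    def test_cell_count_equals_seed_count(self):
        for seed in range(3):
            probs, _ = render_probability_map(n_cells=60, shape=(300, 300),
                                              seed=seed)
            nuclei, _ = segment_nuclei(probs)
            cells = segment_cells(probs, nuclei)
            assert set(np.unique(cells)) == set(np.unique(nuclei))

    def test_nucleus_contained_in_cell(self):
        probs, _ = render_probability_map(n_cells=50, shape=(300, 300), seed=1)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        inside = nuclei > 0
        assert np.array_equal(cells[inside], nuclei[inside])

    def test_single_cell_annulus(self):
        probs, _ = render_probability_map(n_cells=1, shape=(80, 80),
                                          noise=0.0, seed=2)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        assert cells.max() == 1
        assert (cells > 0).sum() > (nuclei > 0).sum()

    def test_adjacent_cells_split_at_ridge(self):
        """Each of two adjacent cells contains exactly its own seed; the
        boundary follows the nearest-seed partition on a symmetric fixture."""
        probs, truth = render_probability_map(
            n_cells=2, shape=(90, 160), min_separation_px=26, noise=0.0, seed=6)
        nuclei, cents = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        assert cells.max() == 2
        for r in cents.itertuples():
            assert cells[int(round(r.y)), int(round(r.x))] == r.label


class TestFeatures:
    def test_uniform_channel_gives_uniform_means(self):
        probs, _ = render_probability_map(n_cells=20, shape=(200, 200), seed=7)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        cube = np.full((1, 200, 200), 4.5)
        table = extract_features(nuclei, cells, cube)
        assert np.allclose(table["mean_ch0_cell"], 4.5)
        assert np.allclose(table["mean_ch0_nucleus"], 4.5)

    def test_known_per_cell_values_exact(self):
        """Oracle: direct per-label mean on a painted channel."""
        from scipy import ndimage as ndi
        probs, _ = render_probability_map(n_cells=15, shape=(200, 200), seed=8)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        paint = cells.astype(float) * 3.0  # value = 3 * label inside each cell
        table = extract_features(nuclei, cells, paint[None])
        ids = table.cell_id.to_numpy()
        oracle = ndi.mean(paint, cells, ids)
        assert np.allclose(table["mean_ch0_cell"], oracle)
        assert np.allclose(table["mean_ch0_cell"], 3.0 * ids)

    def test_nucleus_area_not_larger_than_cell_area(self):
        probs, _ = render_probability_map(n_cells=40, shape=(250, 250), seed=9)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        table = extract_features(nuclei, cells, probs[1][None])
        assert (table.nucleus_area <= table.cell_area).all()

    def test_means_invariant_to_label_renumbering(self, rng):
        probs, _ = render_probability_map(n_cells=10, shape=(150, 150), seed=10)
        nuclei, _ = segment_nuclei(probs)
        cells = segment_cells(probs, nuclei)
        cube = rng.uniform(0, 100, (1, 150, 150))
        t1 = extract_features(nuclei, cells, cube)
        # renumber labels with a permutation
        perm = rng.permutation(np.arange(1, cells.max() + 1))
        remap = np.zeros(cells.max() + 1, int)
        remap[1:] = perm
        t2 = extract_features(remap[nuclei], remap[cells], cube)
        merged = t1.assign(new_id=perm[t1.cell_id - 1]).merge(
            t2, left_on="new_id", right_on="cell_id", suffixes=("", "_r"))
        assert np.allclose(merged["mean_ch0_cell"], merged["mean_ch0_cell_r"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 4), int), np.zeros((4, 4), int),
                             np.zeros((1, 5, 5)))


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = np.zeros((30, 30), int)
        truth[5:10, 5:10] = 1
        truth[20:26, 18:25] = 2
        res = evaluate_segmentation(truth, truth)
        assert res["object_f1"] == 1.0 and res["pixel_f1"] == 1.0

    def test_empty_prediction_scores_zero(self):
        truth = np.zeros((20, 20), int)
        truth[3:8, 3:8] = 1
        res = evaluate_segmentation(np.zeros_like(truth), truth)
        assert res["object_f1"] == 0.0

    def test_two_of_three_with_one_false_positive(self):
        """2 TPs of 3 truth objects + 1 FP: P = R = object F1 = 2/3."""
        truth = np.zeros((40, 60), int)
        truth[2:10, 2:10] = 1
        truth[2:10, 20:28] = 2
        truth[2:10, 40:48] = 3
        pred = np.zeros_like(truth)
        pred[2:10, 2:10] = 1          # exact match
        pred[3:10, 20:28] = 2         # IoU 7/8 > 0.5 -> match
        pred[25:33, 40:48] = 3        # off-target: false positive
        res = evaluate_segmentation(pred, truth)
        assert res["precision"] == pytest.approx(2 / 3)
        assert res["recall"] == pytest.approx(2 / 3)
        assert res["object_f1"] == pytest.approx(2 / 3)

    def test_iou_threshold_is_strict(self):
        truth = np.zeros((20, 20), int)
        truth[0:10, 0:10] = 1
        pred = np.zeros_like(truth)
        pred[0:10, 0:10] = 1
        pred[0:5, 0:10] = 0           # IoU = 50/100 = 0.5, not > 0.5
        res = evaluate_segmentation(pred, truth)
        assert res["n_matched"] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((4, 4), int), np.zeros((5, 5), int))
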