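"""Pairwise tile registration, global placement and mosaic assembly."""

import numpy as np
import pytest
from scipy import ndimage

from beadframe.phantom import (PhantomConfig, Tile, generate_phantom,
                               render_scene, render_stpt_slice)
from beadframe.stitch import (NoOverlapError, PairwiseOffset, assemble_mosaic,
                              global_placement, masked_ssd, pairwise_offset,
                              stitch_slice)


def _scene(rng, shape=(200, 200), scale=3.0):
    img = ndimage.gaussian_filter(rng.normal(0, 1, shape), scale)
    return img / img.std() * 100 + 120


def brute_force_offset(a, wa, b, wb, reported, window):
    """Independent oracle: exhaustive masked-SSD minimization."""
    rx, ry = int(round(reported[0])), int(round(reported[1]))
    best = None
    for dy in range(ry - window, ry + window + 1):
        for dx in range(rx - window, rx + window + 1):
            score, _ = masked_ssd(a, wa, b, wb, (dx, dy))
            if not np.isfinite(score):
                continue
            key = (score, abs(dx - rx) + abs(dy - ry))
            if best is None or key < best[0]:
                best = (key, (dx, dy))
    return best[1]


class TestPairwiseOffset:
    def test_recovers_known_shift_exactly(self, rng):
        scene = _scene(rng)
        a = scene[10:10 + 128, 5:5 + 128]
        b = scene[7:7 + 128, 12:12 + 128]  # b at (7, -3) relative to a
        off = pairwise_offset(a, None, b, None, (5, -1), search_window=8)
        assert off.displacement == (7, -3)
        assert not off.from_microscope

    def test_zero_shift_for_identical_tiles(self, rng):
        a = _scene(rng, (96, 96))
        off = pairwise_offset(a, None, a, None, (0, 0), search_window=6)
        assert off.displacement == (0, 0)

    def test_agrees_with_exhaustive_search(self, rng):
        """FFT-accelerated search == brute-force masked SSD, exactly."""
        for trial in range(5):
            scene = _scene(rng, (220, 220))
            tx, ty = rng.integers(60, 100), rng.integers(-10, 10)
            a = scene[20:20 + 96, 20:20 + 96]
            b = scene[20 + ty:20 + ty + 96, 20 + tx:20 + tx + 96]
            b = b + rng.normal(0, 2, b.shape)
            conf_a = np.ones_like(a)
            conf_a[:10] = 0.0  # masked stripe
            rep = (int(tx + rng.integers(-3, 4)), int(ty + rng.integers(-3, 4)))
            off = pairwise_offset(a, conf_a, b, None, rep, search_window=6)
            oracle = brute_force_offset(a, conf_a, b, np.ones_like(b), rep, 6)
            assert off.displacement == oracle

    def test_blank_overlap_falls_back_to_microscope(self, rng):
        a = np.full((64, 64), 10.0) + rng.normal(0, 0.01, (64, 64))
        b = np.full((64, 64), 10.0) + rng.normal(0, 0.01, (64, 64))
        off = pairwise_offset(a, None, b, None, (57, 0), search_window=5,
                              poisson_factor=3.0)
        assert off.from_microscope
        assert off.displacement == (57, 0)

    def test_no_overlap_raises(self, rng):
        a = _scene(rng, (32, 32))
        with pytest.raises(NoOverlapError):
            pairwise_offset(a, None, a, None, (500, 500), search_window=3)


class TestGlobalPlacement:
    def test_single_tile_keeps_reported_position(self):
        t = Tile(data=np.ones((8, 8)), confidence=np.ones((8, 8)),
                 reported_origin=(12.0, 34.0), tile_id=0)
        pos = global_placement([t], [])
        assert (pos.x.iloc[0], pos.y.iloc[0]) == (12.0, 34.0)

    def test_consistent_grid_recovered_exactly(self, rng):
        """Self-consistent synthetic offsets on a 3x3 grid: positions are
        exact relative to the seed (oracle: spanning-tree integration)."""
        true_pos = {(i, j): np.array([100.0 * i + rng.integers(-4, 5),
                                      100.0 * j + rng.integers(-4, 5)])
                    for i in range(3) for j in range(3)}
        tiles, idx = [], {}
        for k, ((i, j), p) in enumerate(sorted(true_pos.items())):
            data = np.full((16, 16), 1.0 + (i == 1 and j == 1))  # center brightest
            tiles.append(Tile(data=data, confidence=np.ones((16, 16)),
                              reported_origin=(100.0 * i, 100.0 * j), tile_id=k))
            idx[(i, j)] = k
        offsets = []
        for (i, j), k in idx.items():
            for di, dj in ((1, 0), (0, 1)):
                if (i + di, j + dj) in idx:
                    k2 = idx[(i + di, j + dj)]
                    d = true_pos[(i + di, j + dj)] - true_pos[(i, j)]
                    offsets.append(PairwiseOffset(k, k2, (int(d[0]), int(d[1])),
                                                  score=1.0, weight=1.0))
        pos = global_placement(tiles, offsets)
        seed_k = idx[(1, 1)]
        shift = (pos.set_index("tile_id").loc[seed_k, ["x", "y"]].to_numpy()
                 - true_pos[(1, 1)])
        for (i, j), k in idx.items():
            got = pos.set_index("tile_id").loc[k, ["x", "y"]].to_numpy() - shift
            assert np.allclose(got, true_pos[(i, j)], atol=1e-9)

    def test_seed_is_brightest_tile(self):
        tiles = [Tile(data=np.full((8, 8), v), confidence=np.ones((8, 8)),
                      reported_origin=(float(i * 8), 0.0), tile_id=i)
                 for i, v in enumerate([1.0, 5.0, 2.0])]
        # no offsets: everything resolves via the seed's reported frame
        pos = global_placement(tiles, [])
        # seed keeps its reported position; others follow the reported frame
        assert np.allclose(pos.x.to_numpy(), [0.0, 8.0, 16.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_placement([], [])


class TestAssemble:
    @staticmethod
    def _tile(data, origin, tid, conf=None):
        return Tile(data=np.asarray(data, float),
                    confidence=np.ones_like(np.asarray(data, float))
                    if conf is None else conf,
                    reported_origin=origin, tile_id=tid)

    def test_constant_tiles_average_to_constant(self):
        import pandas as pd
        tiles = [self._tile(np.full((16, 16), 5.0), (0.0, 0.0), 0),
                 self._tile(np.full((16, 16), 5.0), (8.0, 0.0), 1)]
        pos = pd.DataFrame(dict(tile_id=[0, 1], x=[0.0, 8.0], y=[0.0, 0.0]))
        m = assemble_mosaic(tiles, pos)
        covered = m.confidence > 0
        assert np.allclose(m.intensity[covered], 5.0)

    def test_overlap_of_10_and_20_averages_to_15(self):
        import pandas as pd
        tiles = [self._tile(np.full((8, 8), 10.0), (0.0, 0.0), 0),
                 self._tile(np.full((8, 8), 20.0), (4.0, 0.0), 1)]
        pos = pd.DataFrame(dict(tile_id=[0, 1], x=[0.0, 4.0], y=[0.0, 0.0]))
        m = assemble_mosaic(tiles, pos)
        assert np.allclose(m.intensity[:8, 4:8], 15.0)
        assert np.allclose(m.intensity[:8, :4], 10.0)
        assert np.allclose(m.intensity[:8, 8:12], 20.0)

    def test_mosaic_invariant_to_tile_order(self, rng):
        import pandas as pd
        tiles = [self._tile(rng.uniform(0, 1, (12, 12)), (6.0 * i, 0.0), i)
                 for i in range(3)]
        pos = pd.DataFrame(dict(tile_id=[0, 1, 2], x=[0.0, 6.0, 12.0],
                                y=[0.0, 0.0, 0.0]))
        m1 = assemble_mosaic(tiles, pos)
        m2 = assemble_mosaic(tiles[::-1], pos)
        assert np.array_equal(m1.intensity, m2.intensity)
        assert np.array_equal(m1.confidence, m2.confidence)

    def test_flat_seams_on_constant_scene(self):
        """No nonlinear blending: seams of a flat-fielded constant scene are
        exactly flat."""
        import pandas as pd
        tiles = [self._tile(np.full((10, 10), 3.0), (0.0, 0.0), 0),
                 self._tile(np.full((10, 10), 3.0), (7.0, 0.0), 1),
                 self._tile(np.full((10, 10), 3.0), (0.0, 7.0), 2)]
        pos = pd.DataFrame(dict(tile_id=[0, 1, 2], x=[0.0, 7.0, 0.0],
                                y=[0.0, 0.0, 7.0]))
        m = assemble_mosaic(tiles, pos)
        assert np.all(m.intensity[m.confidence > 0] == 3.0)


class TestFullChain:
    def test_phantom_mosaic_matches_scene(self):
        """Noise-free assembly at true positions reproduces the scene to
        <1% of the dynamic range."""
        import pandas as pd
        cfg = PhantomConfig(n_tiles=(4, 4), tile_size_px=96, tile_overlap=0.25,
                            n_slices=8, n_beads=40, texture_amplitude=40.0,
                            n_blobs=2, blob_amplitude=700.0,
                            positioning_error_um=0.0, poisson_noise=False)
        s = generate_phantom(cfg, seed=21)
        tiles = render_stpt_slice(s, 4)
        pos = pd.DataFrame([dict(tile_id=t.tile_id,
                                 x=t.true_origin[0], y=t.true_origin[1])
                            for t in tiles])
        scene = render_scene(s, 4) + cfg.dark_level
        w, h = cfg.stage_size_px
        m = assemble_mosaic(tiles, pos, stage_shape=(h, w))
        covered = m.confidence > 0
        err = (m.intensity - scene)[covered]
        assert np.sqrt(np.mean(err ** 2)) < 0.01 * np.ptp(scene)

    def test_recovered_positions_beat_reported(self, small_phantom):
        """After stitching, position errors fall below the injected 5-10 um
        positioning error."""
        tiles = render_stpt_slice(small_phantom, 4)
        m = stitch_slice(tiles, search_window=16)
        pos = m.tile_positions.set_index("tile_id")
        true = np.array([t.true_origin for t in tiles])
        got = pos.loc[np.arange(len(tiles)), ["x", "y"]].to_numpy()
        rep = np.array([t.reported_origin for t in tiles])
        err_got = got - true
        err_rep = rep - true
        err_got -= err_got.mean(axis=0)
        err_rep -= err_rep.mean(axis=0)
        assert (np.hypot(*err_got.T).mean() < np.hypot(*err_rep.T).mean())
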