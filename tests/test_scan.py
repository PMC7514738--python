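"""Sliding-tile scanning and the preprocessing chain."""

import numpy as np
import pytest

from strentropy import (
    TileSpec,
    entropy_point,
    fixed_tiling,
    half_ellipsoid,
    polyp_model,
    preprocess,
    slide_scan,
    split_channels,
    straight_wave,
)
from strentropy.scan import (
    mean_filter_background,
    remove_offset,
    remove_reflections,
    stretch_histogram,
    subtract_background,
)


class TestSplitChannels:
    def test_grayscale_single_grid(self):
        channels = split_channels(np.full((10, 10), 100, dtype=np.uint8))
        assert list(channels) == ["gray"]

    def test_rgb_three_grids(self):
        image = np.random.default_rng(0).integers(
            1, 255, (10, 12, 3), dtype=np.uint16
        )
        channels = split_channels(image)
        assert list(channels) == ["R", "G", "B"]
        assert all(g.shape == (10, 12) for g in channels.values())
        assert np.array_equal(channels["G"], image[:, :, 1].astype(float))

    def test_all_black_channel_excluded(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        image[:, :, 0] = 50
        channels = split_channels(image)
        assert list(channels) == ["R"]

    def test_unsupported_depth_rejected(self):
        with pytest.raises(ValueError, match="bit depth"):
            split_channels(np.zeros((4, 4), dtype=np.int64))


class TestPreprocessingSteps:
    def test_remove_offset(self):
        out = remove_offset(np.array([[5.0, 7.0, 9.0]]))
        assert np.allclose(out, [[0, 2, 4]])

    def test_remove_offset_already_zero(self):
        grid = np.array([[0.0, 2.0], [1.0, 3.0]])
        assert np.array_equal(remove_offset(grid), grid)

    def test_remove_offset_constant_becomes_zero(self):
        assert np.all(remove_offset(np.full((3, 3), 4.2)) == 0)

    def test_mean_filter_constant_invariant(self):
        grid = np.full((20, 20), 3.3)
        assert np.allclose(mean_filter_background(grid, 7), grid)

    def test_mean_filter_identity_k1(self):
        grid = np.random.default_rng(1).random((10, 10))
        assert np.allclose(mean_filter_background(grid, 1), grid)

    def test_mean_filter_impulse(self):
        grid = np.zeros((21, 21))
        grid[10, 10] = 1.0
        filtered = mean_filter_background(grid, 5)
        assert filtered[10, 10] == pytest.approx(1 / 25)

    def test_mean_filter_too_large_rejected(self):
        with pytest.raises(ValueError, match="filter size"):
            mean_filter_background(np.ones((10, 10)), 11)

    def test_subtract_background_flattens_ramp(self):
        """A large filter removes most of a pure ramp away from borders."""
        x = np.arange(200, dtype=float)
        ramp = np.tile(x, (200, 1))
        flat = subtract_background(ramp, 151)
        interior = flat[:, 40:160]
        assert np.ptp(interior) < 0.1 * np.ptp(ramp)

    def test_subtract_background_constant_zero(self):
        assert np.all(subtract_background(np.full((10, 10), 2.0), 5) == 0)

    def test_small_filter_suppresses_polyp(self):
        """A filter near the polyp diameter flattens the bump; a larger
        one preserves its prominence."""
        scene = polyp_model((240, 240), radius=60, height=120, depth=60, offset=80)
        center = (120, 120)
        small = subtract_background(scene, 61)
        large = subtract_background(scene, 201)

        def prominence(grid):
            return grid[center] - np.median(grid)

        assert prominence(small) < 0.5 * prominence(large)

    def test_stretch_histogram(self):
        out = stretch_histogram(np.array([[0.0, 2.0, 4.0]]), out_max=255)
        assert np.allclose(out, [[0, 127.5, 255]])

    def test_stretch_idempotent(self):
        grid = np.array([[0.0, 100.0, 255.0]])
        once = stretch_histogram(grid, 255)
        assert np.allclose(stretch_histogram(once, 255), once)

    def test_stretch_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stretch_histogram(np.full((4, 4), 9.0))

    def test_stretch_changes_point_iff_min_positive(self):
        shifted = np.array([[10.0, 12.0], [14.0, 18.0]])
        pt_before = entropy_point(shifted)
        pt_after = entropy_point(stretch_histogram(shifted, 255))
        assert abs(pt_after.s_str - pt_before.s_str) > 1e-6
        zero_min = shifted - 10.0
        pt0 = entropy_point(zero_min)
        pt1 = entropy_point(stretch_histogram(zero_min, 255))
        assert pt1.s_str == pytest.approx(pt0.s_str, abs=1e-12)


class TestRemoveReflections:
    def test_no_saturation_identity(self):
        grid = np.full((10, 10), 50.0)
        grid[0, 0] = 60.0
        cleaned, mask = remove_reflections(grid, range_max=255)
        assert np.array_equal(cleaned, grid)
        assert not mask.any()

    def test_single_saturated_pixel_in_flat_field(self):
        grid = np.full((11, 11), 40.0)
        grid[5, 5] = 255.0
        cleaned, mask = remove_reflections(grid, range_max=255)
        assert mask.sum() == 1
        assert cleaned[5, 5] == pytest.approx(40.0)

    def test_glare_disc_on_wave(self):
        """Masked area tracks the synthetic glare disc."""
        wave = 100 * straight_wave((60, 60), wavelength_x=30)
        x, y = np.meshgrid(np.arange(60) - 30, np.arange(60) - 30)
        disc = x**2 + y**2 < 8**2
        glared = wave.copy()
        glared[disc] = 255.0
        cleaned, mask = remove_reflections(glared, range_max=255)
        assert mask.sum() == disc.sum()
        assert cleaned[disc].max() < 250
        # surrounding wave untouched
        assert np.array_equal(cleaned[~disc], glared[~disc])

    def test_mostly_saturated_rejected(self):
        grid = np.full((10, 10), 255.0)
        grid[0, :3] = 10.0
        with pytest.raises(ValueError, match="unusable"):
            remove_reflections(grid, range_max=255)


class TestSlideScan:
    def test_uniform_image_all_origin(self):
        curve = slide_scan(np.full((60, 80), 7.0), TileSpec(tile_size=50))
        assert len(curve) == 31
        assert np.allclose(curve.s_str, 0, atol=1e-10)
        assert np.allclose(curve.ln_q, 0, atol=1e-10)

    def test_position_count_formula(self):
        grid = np.random.default_rng(2).random((60, 100))
        assert len(slide_scan(grid, TileSpec(tile_size=50))) == 51
        assert len(slide_scan(grid, TileSpec(tile_size=50, stride=10))) == 6

    def test_column_axis(self):
        grid = np.random.default_rng(3).random((100, 60))
        curve = slide_scan(grid, TileSpec(tile_size=50, axis="column"))
        assert len(curve) == 51

    def test_positions_strictly_increasing(self):
        curve = slide_scan(
            np.random.default_rng(4).random((60, 90)), TileSpec(tile_size=20)
        )
        assert np.all(np.diff(curve.positions) > 0)

    def test_wave_scan_periodicity(self):
        """Scanning normal to fronts with T = 2 x tile gives a periodic
        Sstr(position) with period T (+- 1 px)."""
        scene = straight_wave((80, 350), wavelength_x=100)
        curve = slide_scan(scene, TileSpec(tile_size=50))
        s = curve.s_str
        assert np.allclose(s[:100], s[100:200], atol=1e-6)
        # autocorrelation-free direct check at one-period lag
        assert np.max(np.abs(s[:-100] - s[100:])) < 1e-6

    def test_translation_consistency(self):
        """Scanning a translated scene shifts the curve by the translation."""
        scene = polyp_model((120, 300), radius=40, height=1, depth=0.5, offset=0.8)
        shifted = np.roll(scene, 17, axis=1)
        a = slide_scan(scene, TileSpec(tile_size=50)).s_str
        b = slide_scan(shifted, TileSpec(tile_size=50)).s_str
        # compare on the overlapping interior
        assert np.allclose(a[40:200], b[57:217], atol=1e-9)

    def test_degenerate_tiles_excluded(self):
        grid = np.zeros((40, 120))
        grid[:, 100:] = 1.0  # left tiles are all-zero
        curve = slide_scan(grid, TileSpec(tile_size=40))
        assert len(curve.excluded) > 0
        assert len(curve) + len(curve.excluded) == 81

    def test_bounds_hold_on_scan(self):
        scene = polyp_model((100, 200), radius=30, height=1, depth=0.5, offset=0.1)
        curve = slide_scan(scene, TileSpec(tile_size=50))
        assert np.all(curve.s_str >= 0)
        assert np.all(curve.s_str + curve.ln_q <= 1e-10)

    def test_tile_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            slide_scan(np.ones((30, 30)), TileSpec(tile_size=50))

    def test_dataframe_round_trip(self, tmp_path):
        curve = slide_scan(
            straight_wave((60, 120), wavelength_x=40), TileSpec(tile_size=50)
        )
        curve.channel = "G"
        path = tmp_path / "scan.csv"
        curve.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == len(curve)
        assert np.allclose(frame["q"], frame["D"] / frame["N"], atol=1e-9)


class TestFixedTiling:
    def test_tile_count(self):
        tiles = fixed_tiling(np.random.default_rng(5).random((100, 100)), 50)
        assert len(tiles) == 4
        assert [coords for coords, _ in tiles] == [
            (0, 0), (0, 50), (50, 0), (50, 50)
        ]

    def test_partial_tiles_dropped(self):
        tiles = fixed_tiling(np.random.default_rng(6).random((120, 70)), 50)
        assert len(tiles) == 2

    def test_uniform_image_at_origin(self):
        tiles = fixed_tiling(np.full((100, 100), 2.0), 50)
        assert all(pt.s_str == pytest.approx(0, abs=1e-10) for _, pt in tiles)
        assert all(pt.q == pytest.approx(1.0) for _, pt in tiles)

    def test_hemisphere_and_wave_tiles_separate(self):
        """Tiles holding a full hemisphere have much lower Sstr than wave
        tiles: the flat dark surround carries no shape information."""
        scene = np.zeros((100, 200))
        scene[:100, :100] = half_ellipsoid(100, radius=30, background=1e-10)
        scene[:100, 100:] = straight_wave(100, wavelength_x=25)
        tiles = fixed_tiling(scene, 100)
        assert len(tiles) == 2
        (c0, hemi_pt), (c1, wave_pt) = tiles
        assert hemi_pt.s_str < 0.06
        assert wave_pt.s_str > 0.09
        assert hemi_pt.s_str < 0.6 * wave_pt.s_str


class TestPreprocessChain:
    def test_metadata_records_order(self):
        scene = 200 * polyp_model(
            (220, 220), radius=50, height=1, depth=0.5, offset=0.6
        )
        _, meta = preprocess(scene, background_size=100)
        assert meta["steps"] == [
            "remove_reflections",
            "stretch_histogram",
            "subtract_background",
        ]
        assert meta["background_size"] == 100

    def test_interior_idempotence(self):
        """Re-running the chain barely changes interior entropy points."""
        rng = np.random.default_rng(7)
        scene = 150 * straight_wave((300, 300), wavelength_x=80) + rng.random(
            (300, 300)
        )
        once, _ = preprocess(scene, background_size=100, saturation_fraction=1.0)
        twice, _ = preprocess(once, background_size=100, saturation_fraction=1.0)
        crop = slice(100, 200)
        pt1 = entropy_point(once[crop, crop] + 1e-9)
        pt2 = entropy_point(twice[crop, crop] + 1e-9)
        assert pt2.s_str == pytest.approx(pt1.s_str, abs=5e-3)
        assert pt2.ln_q == pytest.approx(pt1.ln_q, abs=5e-3)

    def test_polyp_scene_scan_forms_loop(self):
        """Scan across a polyp channel: the (ln q, Sstr) path returns to
        its start (closed loop / hook) around the polyp position."""
        from strentropy import curve_features

        scene = polyp_model((160, 400), radius=60, height=120, depth=60, offset=80)
        curve = slide_scan(scene, TileSpec(tile_size=50))
        feats = curve_features(curve, closure_tol=0.05)
        assert feats.loop_closed
        assert feats.extent_s_str > 0.005
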