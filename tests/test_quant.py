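"""Image quantification: projections, Otsu, particles, colocalization, YAP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stemmech.quant import (
    analyze_fa_particles,
    max_intensity_project,
    measure_cell,
    otsu_segment,
    otsu_threshold,
    pearson_colocalization,
    quantify_cell,
    yap_nc_ratio,
)


def brute_force_otsu(image: np.ndarray) -> float:
    """Independent oracle: try every 8-bit threshold, keep the best (lowest)."""
    vals = image.ravel().astype(float)
    best_t, best_v = None, -np.inf
    for t in range(int(vals.min()), int(vals.max())):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return float(best_t)


class TestMip:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        assert np.array_equal(max_intensity_project(img), img[0])

    def test_disjoint_spots_union(self):
        a = np.zeros((5, 5)); a[1, 1] = 9
        b = np.zeros((5, 5)); b[3, 3] = 7
        mip = max_intensity_project(np.stack([a, b]))
        assert mip[1, 1] == 9 and mip[3, 3] == 7

    def test_constant_planes(self):
        stack = np.stack([np.full((4, 4), v) for v in (10.0, 20.0, 15.0)])
        assert np.array_equal(max_intensity_project(stack), np.full((4, 4), 20.0))

    @given(hnp.arrays(np.float64, (4, 6, 6), elements=st.floats(0, 1e6)))
    @settings(max_examples=25, deadline=None)
    def test_projection_bounds_every_plane(self, stack):
        mip = max_intensity_project(stack)
        assert np.all(mip[None] >= stack)


class TestOtsu:
    def test_bimodal_separation(self):
        img = np.array([10] * 50 + [200] * 50).reshape(10, 10)
        t = otsu_threshold(img)
        assert 10 <= t < 200
        assert otsu_segment(img).sum() == 50

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((5, 5), 7))

    def test_eight_level_toy_histogram_matches_brute_force(self):
        rng = np.random.default_rng(0)
        img = rng.choice([0, 30, 60, 90, 120, 150, 200, 250],
                         size=(16, 16), p=[0.3, 0.2, 0.1, 0.05, 0.05, 0.1, 0.1, 0.1])
        assert otsu_threshold(img) == brute_force_otsu(img)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_random_8bit_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(24, 24))
        if img.min() == img.max():
            return
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_generated_cell_scene_dice(self, cell_scene):
        _, channels, truth = cell_scene
        mask = otsu_segment(channels["actin"])
        dice = 2 * (mask & truth.cell_mask).sum() / (mask.sum() + truth.cell_mask.sum())
        assert dice >= 0.9


class TestMeasureCell:
    def test_area_arithmetic(self):
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:100] = True
        area, _ = measure_cell(np.ones((20, 20)), mask, pixel_size_um=0.2)
        assert area == pytest.approx(4.0)

    def test_integrated_intensity(self):
        img = np.zeros((10, 10))
        mask = np.zeros((10, 10), bool)
        img[:5, :10] = 7.0
        mask[:5, :10] = True
        _, integrated = measure_cell(img, mask, 1.0)
        assert integrated == pytest.approx(350.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_cell(np.ones((5, 5)), np.zeros((5, 5), bool), 0.2)

    def test_area_recovery_on_generated_scene(self, cell_scene):
        cfg, channels, truth = cell_scene
        mask = otsu_segment(channels["actin"])
        area, _ = measure_cell(channels["actin"], mask, cfg.pixel_size_um)
        true_area = truth.cell_mask.sum() * cfg.pixel_size_um**2
        assert area == pytest.approx(true_area, rel=0.05)


class TestFaParticles:
    def test_separated_puncta_counted_exactly(self, cell_scene):
        cfg, channels, truth = cell_scene
        mask = otsu_segment(channels["actin"])
        regions = analyze_fa_particles(channels["fa"], mask, cfg.pixel_size_um)
        assert regions.count == truth.n_fa_true
        assert len(regions.areas_um2) == regions.count

    def test_size_filter_can_exclude_everything(self, cell_scene):
        cfg, channels, _ = cell_scene
        mask = otsu_segment(channels["actin"])
        regions = analyze_fa_particles(channels["fa"], mask, cfg.pixel_size_um,
                                       size_range_um2=(100.0, 200.0))
        assert regions.count == 0 and regions.areas_um2 == []

    def test_total_area_round_trip(self, cell_scene):
        cfg, channels, truth = cell_scene
        mask = otsu_segment(channels["actin"])
        regions = analyze_fa_particles(channels["fa"], mask, cfg.pixel_size_um)
        drawn = truth.n_fa_true * truth.fa_area_um2_true
        assert sum(regions.areas_um2) == pytest.approx(drawn, rel=0.15)

    def test_widening_size_range_never_decreases_count(self, cell_scene):
        cfg, channels, _ = cell_scene
        mask = otsu_segment(channels["actin"])
        counts = [
            analyze_fa_particles(channels["fa"], mask, cfg.pixel_size_um, (lo, hi)).count
            for lo, hi in [(0.5, 2.0), (0.3, 5.0), (0.1, 15.0), (0.0, 100.0)]
        ]
        assert counts == sorted(counts)


class TestPearson:
    def test_identical_channels(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(30, 30))
        mask = np.ones((30, 30), bool)
        assert pearson_colocalization(img, img, mask) == pytest.approx(1.0)

    def test_inverted_channel(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(30, 30))
        mask = np.ones((30, 30), bool)
        assert pearson_colocalization(img, 5.0 - img, mask) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        mask = np.ones((100, 100), bool)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = pearson_colocalization(rng.normal(size=(100, 100)),
                                       rng.normal(size=(100, 100)), mask)
            assert abs(r) < 0.05

    def test_constant_channel_gives_nan(self):
        mask = np.ones((10, 10), bool)
        r = pearson_colocalization(np.ones((10, 10)), np.random.default_rng(0).normal(size=(10, 10)), mask)
        assert np.isnan(r)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="3 pixels"):
            pearson_colocalization(np.ones((5, 5)), np.ones((5, 5)), mask)


class TestYapRatio:
    def test_worked_example_sum_formula(self):
        # nuc: 100 px summing 2000; cyto: 200 px summing 1500; background mean 5
        yap = np.zeros((30, 30))
        nuc = np.zeros((30, 30), bool); nuc[:10, :10] = True
        cyto = np.zeros((30, 30), bool); cyto[15:25, 5:25] = True
        bg = np.zeros((30, 30), bool); bg[28:, :] = True
        yap[nuc] = 20.0    # 100 px × 20 = 2000
        yap[cyto] = 7.5    # 200 px × 7.5 = 1500
        yap[bg] = 5.0
        r = yap_nc_ratio(yap, nuc, cyto, bg)
        assert r == pytest.approx((2000 - 5 * 100) / (1500 - 5 * 200))  # = 3.0

    def test_zero_background_equal_sums_unit_ratio(self):
        yap = np.zeros((20, 20))
        nuc = np.zeros((20, 20), bool); nuc[:5, :8] = True
        cyto = np.zeros((20, 20), bool); cyto[10:15, :8] = True
        bg = np.zeros((20, 20), bool); bg[18:, :] = True
        yap[nuc] = 3.0
        yap[cyto] = 3.0
        assert yap_nc_ratio(yap, nuc, cyto, bg) == pytest.approx(1.0)

    def test_overlapping_masks_rejected(self):
        m = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="overlap"):
            yap_nc_ratio(np.ones((5, 5)), m, m, m)

    def test_nonpositive_denominator_flagged_nan(self):
        yap = np.zeros((10, 10))
        nuc = np.zeros((10, 10), bool); nuc[0, :3] = True
        cyto = np.zeros((10, 10), bool); cyto[5, :3] = True
        bg = np.zeros((10, 10), bool); bg[9, :] = True
        yap[nuc] = 10.0
        yap[bg] = 5.0  # cytosol darker than background
        assert np.isnan(yap_nc_ratio(yap, nuc, cyto, bg))

    def test_prescribed_ratio_round_trip(self, cell_scene):
        cfg, channels, truth = cell_scene
        metrics = quantify_cell(channels, cfg.pixel_size_um)
        assert metrics.yap_nc_ratio == pytest.approx(truth.yap_nc_ratio_true, rel=0.05)


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.25, 3.0])
    def test_ratio_and_pearson_invariant_under_intensity_scaling(self, cell_scene, scale):
        cfg, channels, truth = cell_scene
        scaled = {k: v * scale for k, v in channels.items()}
        m1 = quantify_cell(channels, cfg.pixel_size_um, coloc_channels=("fa", "actin"))
        m2 = quantify_cell(scaled, cfg.pixel_size_um, coloc_channels=("fa", "actin"))
        assert m2.yap_nc_ratio == pytest.approx(m1.yap_nc_ratio, rel=1e-6)
        assert m2.pearson_r == pytest.approx(m1.pearson_r, abs=1e-9)
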