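"""ImageJ-macro primitives and the Distribution Index."""

import numpy as np
import pytest

from conftest import flood_fill_count, huang_threshold_oracle
from lamina.imaging_di import (
    GroupedDI,
    aggregate_individuals,
    analyze_particles,
    auto_threshold,
    binary_morph,
    compute_di,
    make_roi,
    median_filter,
    to_8bit,
)
from lamina.synthetic_data import synth_nucleus_image


class TestTo8bit:
    def test_full_range_8bit_image_unchanged(self):
        img = np.array([[0, 128], [200, 255]], dtype=np.uint8)
        assert np.array_equal(to_8bit(img), img)

    def test_16bit_ramp_scales_linearly(self):
        ramp = np.arange(1024, dtype=np.uint16).reshape(32, 32)
        out = to_8bit(ramp)
        assert out.ravel()[0] == 0 and out.ravel()[-1] == 255
        assert out.ravel()[512] == round(512 * 255 / 1023)

    def test_constant_image_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = to_8bit(np.full((4, 4), 77))
        assert (out == 0).all()


class TestAutoThreshold:
    def test_two_delta_peaks_split_between_them(self):
        img = np.array([[50] * 8, [200] * 8], dtype=np.uint8)
        for method in ("huang", "mean"):
            res = auto_threshold(img, method)
            assert 50 <= res.threshold < 200
            assert np.array_equal(res.mask, img == 200)
            assert not res.degenerate

    def test_mean_threshold_is_image_mean(self):
        img = np.array([[0] * 8, [100] * 8], dtype=np.uint8)
        res = auto_threshold(img, "mean")
        assert res.threshold == pytest.approx(50.0)
        assert np.array_equal(res.mask, img == 100)

    def test_constant_image_flagged_degenerate(self):
        res = auto_threshold(np.full((4, 4), 9, dtype=np.uint8), "huang")
        assert res.degenerate

    def test_huang_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            vals = rng.choice(256, size=rng.integers(2, 6), replace=False)
            img = rng.choice(vals, size=(24, 24)).astype(np.uint8)
            res = auto_threshold(img, "huang")
            assert res.threshold == pytest.approx(huang_threshold_oracle(img))


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 42, dtype=np.uint8)
        assert np.array_equal(median_filter(img), img)

    def test_single_impulse_removed(self):
        img = np.full((11, 11), 10, dtype=np.uint8)
        img[5, 5] = 250
        assert (median_filter(img) == 10).all()

    def test_hand_grid_brute_force_medians(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = median_filter(img, radius=2)
        # brute force: disc offsets with Euclidean distance <= 2 (13 px),
        # edge replication by clamping
        offsets = [(dy, dx) for dy in range(-2, 3) for dx in range(-2, 3)
                   if dy * dy + dx * dx <= 4]
        assert len(offsets) == 13
        for i in range(5):
            for j in range(5):
                neigh = [img[min(max(i + dy, 0), 4), min(max(j + dx, 0), 4)]
                         for dy, dx in offsets]
                assert out[i, j] == np.median(neigh)


class TestBinaryMorph:
    def test_erode_3x3_block_leaves_center(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        out = binary_morph(m, "erode", iterations=1, count=1)
        expected = np.zeros((5, 5), bool)
        expected[2, 2] = True
        assert np.array_equal(out, expected)

    def test_erode_empty_mask_stays_empty(self):
        assert not binary_morph(np.zeros((6, 6), bool), "erode", 3, 1).any()

    def test_closing_is_superset_of_interior(self):
        m = np.zeros((50, 50), bool)
        m[10:40, 10:40] = True
        closed = binary_morph(binary_morph(m, "dilate", 5, 1), "erode", 5, 1)
        assert (closed & m).sum() == m.sum()  # original fully recovered

    def test_count_parameter_relaxes_erosion(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        # count=8: only pixels with all 8 neighbors background are removed
        out = binary_morph(m, "erode", iterations=1, count=8)
        assert np.array_equal(out, m)


class TestAnalyzeParticles:
    def test_size_filter_in_calibrated_units(self):
        m = np.zeros((120, 260), bool)
        m[10:74, 10:74] = True  # 64x64 px = 40.96 um^2 at 0.1 um/px
        m[10:42, 150:182] = True  # 32x32 px = 10.24 um^2
        ps = analyze_particles(m, min_size=30, pixel_size_um=0.1)
        assert len(ps) == 1 and ps.particles[0].area == pytest.approx(40.96)

    def test_edge_touching_component_excluded(self):
        m = np.zeros((20, 20), bool)
        m[0:5, 0:5] = True
        m[10:15, 10:15] = True
        assert len(analyze_particles(m, exclude_edge_touching=True)) == 1
        assert len(analyze_particles(m, exclude_edge_touching=False)) == 2

    def test_hole_filling_includes_hole_area(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        m[10:20, 10:20] = False  # annulus
        filled = analyze_particles(m, fill_holes=True, pixel_size_um=None)
        open_ = analyze_particles(m, fill_holes=False, pixel_size_um=None)
        assert filled.particles[0].area == 400
        assert open_.particles[0].area == 300

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        for density in (0.2, 0.4, 0.6):
            m = rng.random((64, 64)) < density
            ps = analyze_particles(m, min_size=0, pixel_size_um=None,
                                   exclude_edge_touching=False, fill_holes=False)
            assert len(ps) == flood_fill_count(m)


class TestMakeRoiAndDi:
    def test_rois_contained_in_their_nuclei(self):
        img, truth = synth_nucleus_image(n_nuclei=3, h=0.3, noise_sd=2.0, seed=3)
        rois, img8 = make_roi(img, protocol="lamin")
        assert len(rois) == 3
        for roi in rois:
            parent = max(truth.masks, key=lambda m: (roi & m).sum())
            assert (roi & ~parent).sum() == 0  # strictly inside (eroded)
            assert roi.sum() < parent.sum()

    def test_edge_touching_nucleus_produces_no_roi(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[(yy - 2) ** 2 + (xx - 50) ** 2 <= 40**2] = 150.0  # clipped at edge
        with pytest.warns(UserWarning, match="zero ROIs"):
            rois, _ = make_roi(img, protocol="lamin")
        assert rois == []

    def test_costain_rois_equal_lamin_rois_of_source(self):
        src, _ = synth_nucleus_image(n_nuclei=2, h=0.2, noise_sd=1.0, seed=9)
        target = np.sqrt(src + 3.0)
        lamin_rois, _ = make_roi(src, protocol="lamin")
        co_rois, img8 = make_roi(target, protocol="costain", roi_source_image=src)
        assert len(co_rois) == len(lamin_rois)
        for a, b in zip(co_rois, lamin_rois):
            assert np.array_equal(a, b)
        assert img8.dtype == np.uint8 and img8.shape == target.shape

    def test_npc_protocol_finds_nuclei(self):
        img, truth = synth_nucleus_image(n_nuclei=2, h=0.2, noise_sd=2.0, seed=13)
        rois, _ = make_roi(img, protocol="npc")
        assert len(rois) == 2

    def test_constant_roi_gives_zero_di(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        roi = np.ones((10, 10), bool)
        assert compute_di(img, roi).di == 0.0

    def test_half_half_roi_di_value(self):
        img = np.concatenate([np.full(2500, 100), np.full(2500, 200)])
        res = compute_di(img.reshape(50, 100).astype(np.uint8),
                         np.ones((50, 100), bool))
        assert res.mean == pytest.approx(150.0)
        assert res.sd == pytest.approx(50.005, abs=1e-3)
        assert res.di == pytest.approx(0.3334, abs=1e-4)

    def test_di_invariant_under_intensity_scaling(self):
        rng = np.random.default_rng(4)
        img = rng.integers(50, 120, (20, 20)).astype(float)
        roi = np.ones((20, 20), bool)
        a = compute_di(img, roi).di
        b = compute_di(img * 2, roi).di
        assert a == pytest.approx(b)

    def test_empty_roi_and_zero_mean_raise(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty ROI"):
            compute_di(img, np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="zero mean"):
            compute_di(img, np.ones((5, 5), bool))


class TestAggregateIndividuals:
    def grouped(self, shift=0.0):
        rng = np.random.default_rng(7)
        values, groups = {}, {}
        for g, label in ((0.0, "wt"), (shift, "mut")):
            for i in range(3):
                key = f"{label}{i}"
                values[key] = list(0.25 + g + rng.normal(0, 0.01, 10))
                groups[key] = label
        return GroupedDI(values=values, groups=groups)

    def test_individual_means_and_warning_on_count(self):
        gd = GroupedDI(values={"a": [0.2, 0.3], "b": [0.4] * 10,
                               "c": [0.1] * 10, "d": [0.2] * 10},
                       groups={"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        with pytest.warns(UserWarning, match="expected 10-12"):
            means, _ = aggregate_individuals(gd)
        assert means["a"] == pytest.approx(0.25)

    def test_two_identical_groups_give_p_one(self):
        gd = GroupedDI(values={"a": [0.2] * 10, "b": [0.3] * 10,
                               "c": [0.2] * 10, "d": [0.3] * 10},
                       groups={"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        _, res = aggregate_individuals(gd)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_three_groups_tukey_flags_only_shifted_pairs(self):
        rng = np.random.default_rng(8)
        values, groups = {}, {}
        for label, mu in (("g1", 0.25), ("g2", 0.25), ("g3", 0.60)):
            for i in range(4):
                key = f"{label}_{i}"
                values[key] = list(rng.normal(mu, 0.01, 10))
                groups[key] = label
        _, res = aggregate_individuals(GroupedDI(values, groups))
        # groups ordered g1, g2, g3
        assert res.pairwise[(0, 1)] > 0.05
        assert res.pairwise[(0, 2)] < 0.05 and res.pairwise[(1, 2)] < 0.05

    def test_group_with_single_individual_raises(self):
        gd = GroupedDI(values={"a": [0.2] * 10, "b": [0.3] * 10},
                       groups={"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match="fewer than 2"):
            aggregate_individuals(gd)
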