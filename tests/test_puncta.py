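"""Image normalization, Phansalkar thresholding, segmentation, counting."""

import numpy as np
import pytest

from cmaquant import puncta, synthetic


class TestNormalize:
    def test_linear_rescale(self):
        out = puncta.normalize_image(np.array([[0.0, 10.0], [20.0, 40.0]]))
        assert np.allclose(out, [[0.0, 0.25], [0.5, 1.0]])

    def test_constant_image_maps_to_zeros(self):
        assert np.all(puncta.normalize_image(np.full((4, 4), 3.7)) == 0.0)

    def test_unit_range_image_unchanged(self):
        img = np.array([[0.0, 0.5], [0.25, 1.0]])
        assert np.allclose(puncta.normalize_image(img), img)

    def test_input_not_mutated(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        puncta.normalize_image(img)
        assert np.array_equal(img, [[1.0, 2.0], [3.0, 4.0]])

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            puncta.normalize_image(np.array([[np.nan, 1.0]]))


class TestPhansalkar:
    def test_constant_patch_closed_form(self):
        """On a constant 0.5 patch m=0.5, s=0: t = 0.5*(1 + 2e^-5 - 0.25),
        which is below 0.5, so the whole patch is foreground."""
        img = np.full((40, 40), 0.5)
        t = puncta.phansalkar_surface(img)
        expected = 0.5 * (1.0 + 2.0 * np.exp(-5.0) - 0.25)
        assert np.allclose(t, expected, atol=1e-9)
        assert expected == pytest.approx(0.381738, abs=1e-6)
        assert puncta.phansalkar_threshold(img).all()

    def test_all_zero_image_gives_empty_mask(self):
        assert not puncta.phansalkar_threshold(np.zeros((40, 40))).any()

    def test_spot_on_dim_background_noiseless(self):
        """A bright Gaussian spot on a 0.1 background: spot foreground,
        background fully suppressed (the dark-region boost of the q-term
        raises t above the background level)."""
        yy, xx = np.mgrid[0:64, 0:64]
        img = 0.1 + 0.8 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 1.5**2))
        mask = puncta.phansalkar_threshold(img)
        assert mask[32, 32]
        far = (yy - 32) ** 2 + (xx - 32) ** 2 > 400
        assert not mask[far].any()

    def test_radius_must_fit_image(self):
        with pytest.raises(ValueError, match="radius"):
            puncta.phansalkar_threshold(np.zeros((20, 20)), puncta.PhansalkarParams(radius=15))

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            puncta.PhansalkarParams(radius=0)
        with pytest.raises(ValueError):
            puncta.PhansalkarParams(r=0.0)


def disk_image(centers, radius, value=0.8, shape=(128, 128)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


class TestDetectNuclei:
    def test_three_disks_give_three_centered_seeds(self):
        centers = [(30, 30), (30, 90), (90, 60)]
        seeds = puncta.detect_nuclei(disk_image(centers, 8))
        assert len(seeds) == 3
        for seed, (r0, c0) in zip(seeds, sorted(centers)):
            assert abs(seed.centroid[0] - r0) <= 0.5
            assert abs(seed.centroid[1] - c0) <= 0.5

    def test_blank_channel_gives_no_seeds(self):
        assert puncta.detect_nuclei(np.zeros((64, 64))) == []

    def test_merged_disks_yield_single_seed(self):
        # Two overlapping disks form one component: a documented limitation.
        seeds = puncta.detect_nuclei(disk_image([(40, 60), (40, 70)], 8))
        assert len(seeds) == 1

    def test_min_area_filters_specks(self):
        img = disk_image([(40, 40)], 6)
        img[10, 10] = 0.8  # single bright pixel
        assert len(puncta.detect_nuclei(img, min_area=30)) == 1


class TestSegmentCytoplasm:
    def test_single_cell_covers_foreground(self):
        reporter = disk_image([(64, 64)], 40, value=0.5)
        seeds = [puncta.NucleusSeed((64.0, 64.0), 100)]
        seg = puncta.segment_cytoplasm(reporter, seeds)
        assert seg.n_cells == 1
        assert set(np.unique(seg.label_map)) == {0, 1}
        # the label covers (essentially all of) the cell disk
        cell = disk_image([(64, 64)], 38, value=1.0) > 0
        assert (seg.label_map[cell] == 1).mean() > 0.99

    def test_touching_cells_are_split_along_the_midline(self):
        rows, cols, R = 140, 220, 45
        rr, cc = np.mgrid[0:rows, 0:cols]
        d1 = (rr - 70) ** 2 + (cc - 80) ** 2
        d2 = (rr - 70) ** 2 + (cc - 140) ** 2
        reporter = np.where((d1 <= R * R) | (d2 <= R * R), 0.5, 0.0)
        seeds = [puncta.NucleusSeed((70.0, 80.0), 50), puncta.NucleusSeed((70.0, 140.0), 50)]
        seg = puncta.segment_cytoplasm(reporter, seeds)
        truth = {1: (d1 <= R * R) & (d1 <= d2), 2: (d2 <= R * R) & (d2 < d1)}
        for label, mask in truth.items():
            assert (seg.label_map[mask] == label).mean() >= 0.9
        # labels partition the foreground: no pixel in two cells by construction
        assert set(np.unique(seg.label_map)) == {0, 1, 2}

    def test_seed_outside_foreground_warns_and_yields_empty_region(self):
        reporter = disk_image([(40, 40)], 20, value=0.5)
        seeds = [
            puncta.NucleusSeed((40.0, 40.0), 50),
            puncta.NucleusSeed((100.0, 100.0), 50),
        ]
        with pytest.warns(UserWarning, match="outside the foreground"):
            seg = puncta.segment_cytoplasm(reporter, seeds)
        assert (seg.label_map == 2).sum() == 0

    def test_no_seeds_raises(self):
        with pytest.raises(ValueError):
            puncta.segment_cytoplasm(np.zeros((32, 32)), [])


class TestDetectAndAssign:
    def make_segmentation(self, shape=(64, 64)):
        label_map = np.zeros(shape, dtype=int)
        label_map[:, : shape[1] // 2] = 1
        label_map[:, shape[1] // 2 :] = 2
        return puncta.SegmentationResult(label_map, 2, {1: (0, 0), 2: (0, 0)})

    def test_area_filter_boundary(self):
        seg = self.make_segmentation()
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 10] = True  # area 1 particle
        out = puncta.detect_and_assign_puncta(mask, seg, min_area=2, split_touching=False)
        assert out.n_detected == 0 and out.n_rejected_area == 1

    def test_bookkeeping_identity(self):
        seg = self.make_segmentation()
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:12, 10:12] = True  # in cell 1
        mask[20:22, 40:42] = True  # in cell 2
        out = puncta.detect_and_assign_puncta(mask, seg, split_touching=False)
        assert sum(out.per_cell_counts.values()) + out.discarded_background == out.n_detected
        assert out.per_cell_counts == {1: 1, 2: 1}

    def test_background_particle_is_discarded_and_tallied(self):
        seg = self.make_segmentation()
        seg.label_map[:, :] = 0
        seg.label_map[0, 0] = 1  # almost everything is background
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:32, 30:32] = True
        out = puncta.detect_and_assign_puncta(mask, seg, split_touching=False)
        assert out.discarded_background == 1
        assert sum(out.per_cell_counts.values()) == 0

    def test_shape_mismatch_raises(self):
        seg = self.make_segmentation((32, 32))
        with pytest.raises(ValueError):
            puncta.detect_and_assign_puncta(np.zeros((64, 64), dtype=bool), seg)


class TestFullPipeline:
    def test_planted_counts_recovered(self):
        image, truth = synthetic.gen_cell_image(5, 8, snr=10, seed=2)
        result, seg = puncta.quantify_image(image.data)
        assert seg.n_cells == 5
        assert sorted(result.per_cell_counts.values()) == [8] * 5

    def test_zero_planted_puncta_give_zero_counts(self):
        image, _ = synthetic.gen_cell_image(5, 0, snr=10, seed=3)
        result, _ = puncta.quantify_image(image.data)
        assert sum(result.per_cell_counts.values()) <= 2  # noise floor, near zero

    def test_pipeline_deterministic(self):
        image, _ = synthetic.gen_cell_image(4, 6, snr=8, seed=5)
        r1, s1 = puncta.quantify_image(image.data)
        r2, s2 = puncta.quantify_image(image.data)
        assert r1.per_cell_counts == r2.per_cell_counts
        assert np.array_equal(s1.label_map, s2.label_map)

    def test_rejects_2d_input(self):
        with pytest.raises(ValueError):
            puncta.quantify_image(np.zeros((32, 32)))


class TestCompareConditions:
    def test_identical_groups(self):
        out = puncta.compare_conditions({"A": [5.0, 5.0, 5.0], "B": [5.0, 5.0, 5.0]})
        assert out.difference == 0.0
        assert out.p_value == pytest.approx(1.0)

    def test_identical_groups_with_variation(self):
        out = puncta.compare_conditions({"A": [5.0, 6.0, 7.0], "B": [5.0, 6.0, 7.0]})
        assert out.difference == 0.0
        assert out.p_value == pytest.approx(1.0)

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError):
            puncta.compare_conditions({"A": [5.0], "B": [4.0, 5.0]})

    def test_requires_exactly_two_conditions(self):
        with pytest.raises(ValueError):
            puncta.compare_conditions({"A": [1.0, 2.0]})

    def test_clear_effect_detected(self):
        out = puncta.compare_conditions({"BSA": [8.0, 7.9, 8.2, 8.1], "PA": [4.0, 4.2, 3.9, 4.1]})
        assert out.difference > 0
        assert out.p_value < 0.001
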