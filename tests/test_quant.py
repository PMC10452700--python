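"""SUV computation, ROI statistics, and proliferative classification."""

import numpy as np
import pytest

from fltquant import (
    EmptyROIError,
    PETStudy,
    PhantomSpec,
    ValidationError,
    classify_voxels,
    compute_suv,
    generate_phantom,
    proliferative_threshold,
    quantify_study,
    roi_summary,
)
from fltquant.quant import SUVSummary, summarize_values


def make_study(tumor_values, muscle_values):
    """Tiny 1-D-style study: tumor voxels then muscle voxels along one row."""
    nt, nm = len(tumor_values), len(muscle_values)
    vol = np.zeros((1, 1, nt + nm))
    vol[0, 0, :nt] = tumor_values
    vol[0, 0, nt:] = muscle_values
    tumor = np.zeros_like(vol, dtype=bool)
    tumor[0, 0, :nt] = True
    muscle = np.zeros_like(vol, dtype=bool)
    muscle[0, 0, nt:] = True
    return PETStudy(suv_volume=vol, tumor_mask=tumor, muscle_mask=muscle)


class TestComputeSUV:
    def test_direct_substitution(self):
        vol = np.full((2, 2, 2), 1000.0)  # Bq/mL
        suv = compute_suv(vol, injected_activity=100_000.0, body_weight=20.0)
        assert np.allclose(suv, 0.2)

    def test_zero_activity_gives_zero_suv(self):
        assert (compute_suv(np.zeros((3, 3, 3)), 1e5, 20.0) == 0).all()

    def test_typical_mouse_dose_unit_suv(self):
        # 3.68 MBq injected in a 20 g mouse, 184 kBq/mL concentration -> SUV 1
        suv = compute_suv(np.array([184_000.0]), 3.68e6, 20.0)
        assert np.allclose(suv, 1.0)

    @pytest.mark.parametrize("dose,weight", [(0.0, 20.0), (-1.0, 20.0), (1e5, 0.0)])
    def test_nonpositive_dose_or_weight_rejected(self, dose, weight):
        with pytest.raises(ValidationError):
            compute_suv(np.ones((2, 2, 2)), dose, weight)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValidationError):
            compute_suv(np.array([-1.0]), 1e5, 20.0)


class TestROISummary:
    def test_three_voxel_example(self):
        study = make_study([0.4, 0.6, 0.8], [0.5, 0.5])
        s = roi_summary(study, "tumor")
        assert s.mean == pytest.approx(0.6)
        assert s.max == 0.8
        assert s.n_voxels == 3

    def test_single_voxel_reports_sd_zero_with_warning(self):
        study = make_study([0.7], [0.5, 0.6])
        with pytest.warns(UserWarning, match="degenerate"):
            s = roi_summary(study, "tumor")
        assert s.sd == 0.0

    def test_matches_brute_force_loop(self, rng):
        values = rng.uniform(0.1, 2.0, 100)
        study = make_study(values, [0.5, 0.5])
        s = roi_summary(study, "tumor")
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(var**0.5, abs=1e-12)
        assert s.max == max(values)

    def test_empty_selection_errors(self):
        with pytest.raises(EmptyROIError):
            summarize_values(np.array([]))

    def test_sample_sd_uses_n_minus_one(self):
        study = make_study([1.0, 2.0], [0.5, 0.5])
        assert roi_summary(study, "tumor").sd == pytest.approx(np.sqrt(0.5))


class TestThreshold:
    @pytest.mark.parametrize(
        "mean,sd,expected", [(0.5, 0.1, 0.7), (0.5, 0.0, 0.5), (0.45, 0.075, 0.6)]
    )
    def test_mean_plus_two_sd(self, mean, sd, expected):
        muscle = SUVSummary(mean=mean, sd=sd, max=mean + 3 * sd, n_voxels=10)
        assert proliferative_threshold(muscle) == pytest.approx(expected)

    def test_single_voxel_reference_rejected(self):
        muscle = SUVSummary(mean=0.5, sd=0.0, max=0.5, n_voxels=1)
        with pytest.raises(ValidationError):
            proliferative_threshold(muscle)

    def test_custom_multiplier(self):
        muscle = SUVSummary(mean=0.5, sd=0.1, max=0.8, n_voxels=10)
        assert proliferative_threshold(muscle, sd_multiplier=0.0) == 0.5


class TestClassify:
    def test_inclusive_boundary(self):
        study = make_study([0.4, 0.7, 1.2], [0.5, 0.5])
        c = classify_voxels(study, 0.7)
        assert c.proliferative_mask.sum() == 2  # 0.7 itself is proliferative
        assert c.proliferative_fraction == pytest.approx(2 / 3)

    def test_threshold_above_max_flags_empty(self):
        study = make_study([0.4, 0.7], [0.5, 0.5])
        c = classify_voxels(study, 5.0)
        assert c.is_empty
        assert c.proliferative_fraction == 0.0
        assert c.proliferative_summary is None

    def test_partition_invariant(self, small_phantom):
        _, study, _ = small_phantom
        c = classify_voxels(study, 0.6)
        assert not (c.proliferative_mask & c.necrotic_mask).any()
        assert ((c.proliferative_mask | c.necrotic_mask) == study.tumor_mask).all()

    def test_matches_per_voxel_brute_force(self):
        spec = PhantomSpec(seed=31, grid_shape=(20, 20, 20))
        study, _ = generate_phantom(spec)
        thr = 0.6
        # force exact ties at the threshold to exercise inclusivity
        idx = np.argwhere(study.tumor_mask)[:5]
        for i, j, k in idx:
            study.suv_volume[i, j, k] = thr
        c = classify_voxels(study, thr)
        for i, j, k in np.argwhere(study.tumor_mask):
            expected = study.suv_volume[i, j, k] >= thr
            assert c.proliferative_mask[i, j, k] == expected

    def test_negative_threshold_rejected(self):
        study = make_study([0.4], [0.5, 0.5])
        with pytest.raises(ValidationError):
            classify_voxels(study, -0.1)


class TestQuantifyStudy:
    def test_threshold_near_nominal(self, small_phantom):
        spec, study, _ = small_phantom
        q = quantify_study(study)
        nominal = spec.muscle_suv_mean + 2 * spec.muscle_suv_sd
        assert q.classification.threshold == pytest.approx(nominal, abs=0.05)

    def test_uniform_tumor_above_threshold_keeps_mean(self):
        study = make_study([1.5] * 10, [0.5, 0.5, 0.5])
        q = quantify_study(study)
        assert q.classification.proliferative_summary.mean == pytest.approx(q.tumor.mean)
        assert q.classification.proliferative_fraction == 1.0

    def test_thresholded_mean_decreases_under_suppression(self):
        base = dict(grid_shape=(32, 32, 32))
        q_full = quantify_study(generate_phantom(PhantomSpec(seed=5, suppression=1.0, **base))[0])
        q_sup = quantify_study(generate_phantom(PhantomSpec(seed=5, suppression=0.5, **base))[0])
        assert (
            q_sup.classification.proliferative_summary.mean
            < q_full.classification.proliferative_summary.mean
        )

    def test_truncation_monotone(self, small_phantom):
        _, study, _ = small_phantom
        q = quantify_study(study)
        if 0 < q.classification.proliferative_fraction < 1:
            assert q.classification.proliferative_summary.mean >= q.tumor.mean


class TestPETStudyValidation:
    def test_overlapping_masks_rejected(self):
        vol = np.ones((1, 1, 3))
        mask = np.ones_like(vol, dtype=bool)
        with pytest.raises(ValidationError):
            PETStudy(suv_volume=vol, tumor_mask=mask, muscle_mask=mask)

    def test_negative_suv_rejected(self):
        vol = np.array([[[-0.1, 1.0]]])
        t = np.array([[[True, False]]])
        m = np.array([[[False, True]]])
        with pytest.raises(ValidationError):
            PETStudy(suv_volume=vol, tumor_mask=t, muscle_mask=m)

    def test_nonzero_mask_values_coerced(self):
        vol = np.array([[[0.5, 1.0]]])
        t = np.array([[[0, 255]]])
        m = np.array([[[2, 0]]])
        study = PETStudy(suv_volume=vol, tumor_mask=t, muscle_mask=m)
        assert study.tumor_mask.dtype == bool
        assert study.tumor_values().tolist() == [1.0]
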