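"""Lung segmentation, PSNR/SSIM metric oracles, and the NLM baseline."""

import math

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from conftest import naive_nlm
from uldct.evaluation import (NlmParams, apply_lung_zeroing, default_field_bounds,
                              dice, evaluate_study, nlm_denoise, psnr,
                              segment_lungs, ssim)
from uldct.exceptions import SegmentationError, ValidationError
from uldct.preprocess import denormalize, normalize_hu
from uldct.volume import CTVolume, LungMask


class TestPsnr:
    def test_identical_grids_flagged_infinite(self):
        x = np.random.default_rng(0).uniform(0, 1, (16, 16))
        assert math.isinf(psnr(x, x))

    def test_twenty_db_case(self):
        ref = np.zeros((10, 10))
        test = np.full((10, 10), 0.1)  # mean squared difference 0.01, peak 1
        assert psnr(ref, test, peak=1.0) == pytest.approx(20.0)

    def test_sixty_db_case(self):
        ref = np.zeros((10, 10))
        test = np.full((10, 10), 3.0)  # msd 9, peak 3000
        assert psnr(ref, test, peak=3000.0) == pytest.approx(60.0)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValidationError):
            psnr(np.zeros((4, 4)), np.zeros((4, 4)), peak=0.0)

    def test_strictly_decreasing_under_growing_noise(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0.2, 0.8, (64, 64))
        noise = rng.standard_normal(ref.shape)
        values = [psnr(ref, ref + amp * noise) for amp in (0.01, 0.03, 0.1, 0.3)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSsim:
    def test_identical_grids_score_one(self):
        x = np.random.default_rng(2).uniform(0, 1, (32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (32, 32))
        b = np.clip(a + 0.1 * rng.standard_normal(a.shape), 0, 1)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    @pytest.mark.parametrize("case", ["noise", "negation"])
    def test_cross_implementation_agreement(self, case):
        """Independent reference implementation agrees within 1e-6."""
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (48, 48))
        if case == "noise":
            b = np.clip(a + 0.15 * rng.standard_normal(a.shape), 0, 1)
        else:
            b = 2 * a.mean() - a  # negation about the mean
        mine = ssim(a, b)
        reference = structural_similarity(
            a, b, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0, K1=0.01, K2=0.03)
        assert mine == pytest.approx(reference, abs=1e-6)

    def test_invariant_to_common_constant_shift(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.2, 0.5, (32, 32))
        b = np.clip(a + 0.05 * rng.standard_normal(a.shape), 0, 1)
        shifted = ssim(a + 0.3, b + 0.3, dynamic_range=1.0)
        # luminance term changes slightly with the means; contrast/structure do
        # not -- the score must be stable to ~1e-2 and move toward 1
        assert shifted == pytest.approx(ssim(a, b), abs=2e-2)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)), window=11)


class TestNlm:
    def test_vanishing_h_returns_input(self):
        hu = np.random.default_rng(6).uniform(-1000, 200, (32, 32))
        out = nlm_denoise(hu, NlmParams(patch_side=5, search_side=11, h=1e-4))
        assert np.max(np.abs(out - np.asarray(denormalize(normalize_hu(hu))))) < 1e-6

    def test_constant_slice_unchanged(self):
        hu = np.full((32, 32), -300.0)
        out = nlm_denoise(hu, NlmParams(patch_side=5, search_side=11, h=0.02))
        assert np.allclose(out, -300.0, atol=1e-9)

    def test_matches_brute_force_triple_loop(self):
        """Vectorized NLM == per-pixel/per-neighbor/per-patch loops, to 1e-9."""
        rng = np.random.default_rng(7)
        hu = rng.uniform(-1000, 200, (32, 32))
        p = NlmParams(patch_side=5, search_side=11, h=0.05)
        fast = nlm_denoise(hu, p)
        naive = naive_nlm(hu, 5, 11, 0.05)
        assert np.max(np.abs(fast - naive)) < 1e-9

    def test_reduces_noise_on_noisy_flat_region(self):
        rng = np.random.default_rng(8)
        hu = -850.0 + 60.0 * rng.standard_normal((48, 48))
        out = nlm_denoise(hu, NlmParams(patch_side=5, search_side=21, h=0.03))
        assert np.std(out[10:-10, 10:-10]) < np.std(hu[10:-10, 10:-10])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            NlmParams(h=0.0)
        with pytest.raises(ValidationError):
            NlmParams(patch_side=4)
        with pytest.raises(ValidationError):
            nlm_denoise(np.zeros((16, 16)), NlmParams(patch_side=5, search_side=41))


class TestSegmentation:
    def test_recovers_phantom_mask(self, study128):
        sdct, _, _, truth_mask, _ = study128
        seg = segment_lungs(sdct)
        assert dice(seg.mask, truth_mask.mask) >= 0.90

    def test_vessels_absorbed_by_closing(self, study128):
        """Bright vessel disks (HU ~ 30) end up inside the closed mask."""
        sdct, _, _, truth_mask, truth = study128
        seg = segment_lungs(sdct)
        vessel_px = (truth.voxels == 30.0) & truth_mask.mask
        assert vessel_px.any()
        assert np.mean(seg.mask[vessel_px]) > 0.95

    def test_uniform_volume_raises(self):
        with pytest.raises(SegmentationError):
            segment_lungs(CTVolume(np.zeros((2, 32, 32)), kind="sdct"))

    def test_seed_point_mode(self, study128):
        sdct, _, _, truth_mask, _ = study128
        seed = tuple(np.argwhere(truth_mask.mask)[0])
        seg = segment_lungs(sdct, seed_point=seed, keep_components=1)
        assert seg.mask.any()
        assert seg.mask[seed]


class TestLungZeroing:
    def test_all_true_mask_is_noop(self):
        vol = CTVolume(np.random.default_rng(9).uniform(-500, 500, (2, 8, 8)))
        mask = LungMask(np.ones(vol.shape, dtype=bool))
        assert np.array_equal(apply_lung_zeroing(vol, mask).voxels, vol.voxels)

    def test_all_false_mask_zeroes_everything(self):
        vol = CTVolume(np.random.default_rng(10).uniform(-500, 500, (2, 8, 8)))
        mask = LungMask(np.zeros(vol.shape, dtype=bool))
        assert np.all(apply_lung_zeroing(vol, mask).voxels == 0.0)

    def test_lung_voxels_conserved(self):
        vol = CTVolume(np.random.default_rng(11).uniform(-500, 500, (2, 8, 8)))
        mask = LungMask(np.random.default_rng(12).uniform(size=vol.shape) > 0.5)
        zeroed = apply_lung_zeroing(vol, mask)
        assert np.array_equal(zeroed.voxels[mask.mask], vol.voxels[mask.mask])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            apply_lung_zeroing(CTVolume(np.zeros((1, 8, 8))),
                               LungMask(np.zeros((1, 4, 4), dtype=bool)))


class TestEvaluateStudy:
    def test_reference_against_itself(self, study128):
        sdct, _, _, mask, _ = study128
        report = evaluate_study(sdct, {"self": sdct}, mask)
        for _, row in report.table.iterrows():
            assert math.isinf(row.psnr_db)
            assert row.ssim == pytest.approx(1.0)

    def test_metadata_records_conventions(self, study128):
        sdct, _, uldct_test, mask, _ = study128
        report = evaluate_study(sdct, {"undenoised": uldct_test}, mask)
        assert report.metadata["peak"] == 1.0
        assert report.metadata["ssim_k1"] == 0.01
        assert report.metadata["ssim_window"] == 11

    def test_metrics_ignore_changes_outside_mask(self, study128):
        sdct, _, uldct_test, mask, _ = study128
        report_a = evaluate_study(sdct, {"c": uldct_test}, mask)
        tampered = uldct_test.with_voxels(
            np.where(mask.mask, uldct_test.voxels, 999.0))
        report_b = evaluate_study(sdct, {"c": tampered}, mask)
        assert np.allclose(report_a.table.psnr_db, report_b.table.psnr_db)
        assert np.allclose(report_a.table.ssim, report_b.table.ssim)

    def test_empty_field_range_rejected(self, study128):
        sdct, _, uldct_test, mask, _ = study128
        with pytest.raises(ValidationError):
            evaluate_study(sdct, {"c": uldct_test}, mask,
                           field_bounds={"upper": (1, 1)})

    def test_default_field_bounds_partition(self):
        bounds = default_field_bounds(9)
        assert bounds == {"upper": (0, 3), "middle": (3, 6), "lower": (6, 9)}
        bounds3 = default_field_bounds(3)
        assert [b[1] - b[0] for b in bounds3.values()] == [1, 1, 1]
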