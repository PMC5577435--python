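"""Intensity normalization and paired patch extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uldct.exceptions import CapacityError, ValidationError
from uldct.preprocess import (PatchDataset, denormalize, eligible_centers,
                              extract_paired_patches, normalize_hu, register_hook)
from uldct.volume import CTVolume, LungMask


class TestNormalization:
    @pytest.mark.parametrize("hu,expected", [
        (-2000.0, 0.0),   # below the clamp
        (2000.0, 1.0),    # above the clamp
        (0.0, 0.5),
        (-1500.0, 0.0),   # boundary: linear branch, continuous
        (1500.0, 1.0),
        (750.0, 0.75),
    ])
    def test_branch_values(self, hu, expected):
        assert normalize_hu(hu) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            normalize_hu(np.array([0.0, np.nan]))

    @pytest.mark.parametrize("y,expected", [(0.5, 0.0), (0.0, -1500.0), (1.0, 1500.0)])
    def test_denormalize_values(self, y, expected):
        assert denormalize(y) == pytest.approx(expected)

    def test_denormalize_clips_strays(self):
        assert denormalize(1.2) == 1500.0
        assert denormalize(-0.3) == -1500.0

    @given(st.floats(min_value=-1500.0, max_value=1500.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_on_linear_branch(self, hu):
        assert denormalize(normalize_hu(hu)) == pytest.approx(hu, abs=1e-9)

    @given(st.floats(min_value=-3000.0, max_value=3000.0, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_is_projection(self, hu):
        projected = denormalize(normalize_hu(hu))
        assert projected == pytest.approx(min(max(hu, -1500.0), 1500.0), abs=1e-9)

    def test_monotone_on_grid(self):
        grid = np.linspace(-2500, 2500, 1001)
        out = np.asarray(normalize_hu(grid))
        assert np.all(np.diff(out) >= 0)


def _toy_volumes(side=64, n_slices=2, seed=0):
    rng = np.random.default_rng(seed)
    sdct = CTVolume(rng.uniform(-1000, 500, (n_slices, side, side)), kind="sdct")
    uldct = CTVolume(rng.uniform(-1000, 500, (n_slices, side, side)),
                     kind="uldct_train")
    mask = np.zeros((n_slices, side, side), dtype=bool)
    mask[:, 20:44, 20:44] = True
    return sdct, uldct, LungMask(mask)


class TestPatchExtraction:
    def test_counts_and_shapes(self):
        sdct, uldct, mask = _toy_volumes()
        ds = extract_paired_patches(sdct, uldct, mask, n_train=300, n_val=50, seed=1)
        assert ds.x_train.shape == (300, 28, 28)
        assert ds.y_val.shape == (50, 28, 28)
        assert ds.x_train.min() >= 0.0 and ds.x_train.max() <= 1.0

    def test_centers_lung_masked_interior_and_disjoint(self):
        sdct, uldct, mask = _toy_volumes()
        ds = extract_paired_patches(sdct, uldct, mask, n_train=300, n_val=50, seed=1)
        all_centers = np.vstack([ds.centers_train, ds.centers_val])
        for s, r, c in all_centers:
            assert mask.mask[s, r, c]
            assert 13 <= r <= 64 - 15 and 13 <= c <= 64 - 15
        as_tuples = {tuple(c) for c in all_centers}
        assert len(as_tuples) == len(all_centers)  # no replacement, no leakage

    def test_pairs_cut_at_identical_centers(self):
        sdct, uldct, mask = _toy_volumes()
        ds = extract_paired_patches(sdct, uldct, mask, n_train=10, n_val=5, seed=2)
        s, r, c = ds.centers_train[0]
        r0, c0 = r - 13, c - 13
        expected = np.asarray(normalize_hu(sdct.voxels[s, r0:r0 + 28, c0:c0 + 28]))
        assert np.allclose(ds.x_train[0], expected)
        expected_y = np.asarray(normalize_hu(uldct.voxels[s, r0:r0 + 28, c0:c0 + 28]))
        assert np.allclose(ds.y_train[0], expected_y)

    def test_seeded_determinism(self):
        sdct, uldct, mask = _toy_volumes()
        a = extract_paired_patches(sdct, uldct, mask, n_train=50, n_val=10, seed=3)
        b = extract_paired_patches(sdct, uldct, mask, n_train=50, n_val=10, seed=3)
        assert np.array_equal(a.centers_train, b.centers_train)
        assert np.array_equal(a.centers_val, b.centers_val)

    def test_all_false_mask_raises_capacity_error(self):
        sdct, uldct, mask = _toy_volumes()
        empty = LungMask(np.zeros_like(mask.mask))
        with pytest.raises(CapacityError):
            extract_paired_patches(sdct, uldct, empty, n_train=1, n_val=1)

    def test_too_many_requested_raises_capacity_error(self):
        sdct, uldct, mask = _toy_volumes()
        with pytest.raises(CapacityError):
            extract_paired_patches(sdct, uldct, mask, n_train=10 ** 6, n_val=1)

    def test_shape_mismatch_rejected(self):
        sdct, uldct, mask = _toy_volumes()
        small = CTVolume(np.zeros((1, 32, 32)), kind="uldct_train")
        with pytest.raises(ValidationError):
            extract_paired_patches(sdct, small, mask, n_train=1, n_val=1)

    def test_window_containment_rule(self):
        """Centers sit where the full 28-window fits, even for an all-true mask."""
        mask = LungMask(np.ones((1, 40, 40), dtype=bool))
        centers = eligible_centers(mask, 28)
        rows = centers[:, 1]
        assert rows.min() == 13 and rows.max() == 40 - 15

    def test_hdf5_round_trip(self, tmp_path):
        sdct, uldct, mask = _toy_volumes()
        ds = extract_paired_patches(sdct, uldct, mask, n_train=20, n_val=5, seed=4)
        path = str(tmp_path / "patches.h5")
        ds.to_hdf5(path)
        back = PatchDataset.from_hdf5(path)
        assert np.array_equal(ds.x_train, back.x_train)
        assert np.array_equal(ds.centers_val, back.centers_val)
        assert back.seed == 4 and back.patch_size == 28


class TestRegisterHook:
    def test_identity_pass_through(self):
        sdct, uldct, _ = _toy_volumes()
        assert register_hook(sdct, uldct) is uldct

    def test_shape_mismatch_rejected(self):
        sdct, _, _ = _toy_volumes()
        other = CTVolume(np.zeros((1, 8, 8)))
        with pytest.raises(ValidationError):
            register_hook(sdct, other)
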