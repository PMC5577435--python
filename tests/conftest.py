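"""Shared fixtures: one synthetic paired study and one trained denoiser.

The heavy fixtures are session-scoped so the training run and the simulated
study are paid for once and shared between the module tests and the
acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from uldct.dose import DoseSimSpec, make_paired_study
from uldct.inference import denoise_volume
from uldct.model import TrainConfig
from uldct.networks import build_cae
from uldct.phantom import PhantomSpec
from uldct.preprocess import PatchDataset, extract_paired_patches
from uldct.training import train

# Study conditions: 300 mA standard dose vs 10 mA ultra-low dose on one
# phantom anatomy, three slices, desk-scale 128^2 grid.
STUDY_SEEDS = (1, 2, 3)
PHANTOM_SEED = 0
EXTRACT_SEED = 7
TRAIN_SEED = 11


@pytest.fixture(scope="session")
def study128():
    """(sdct, uldct_train, uldct_test, mask, ground_truth) at 128^2 x 3 slices."""
    spec = PhantomSpec(image_side=128, n_slices=3, rng_seed=PHANTOM_SEED)
    return make_paired_study(spec,
                             DoseSimSpec(tube_current_mA=300.0),
                             DoseSimSpec(tube_current_mA=10.0),
                             STUDY_SEEDS)


@pytest.fixture(scope="session")
def dataset5k(study128) -> PatchDataset:
    """5,000 training / 1,000 validation paired lung patches."""
    sdct, uldct_train, _, mask, _ = study128
    return extract_paired_patches(sdct, uldct_train, mask,
                                  n_train=5000, n_val=1000, seed=EXTRACT_SEED)


@pytest.fixture(scope="session")
def trained_cae(dataset5k):
    """3-hidden-layer, 8-map CAE trained 20 epochs (the scaled study model)."""
    return train(build_cae(3, 8), dataset5k,
                 TrainConfig(epochs=20, rng_seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def denoised_test(trained_cae, study128):
    """The held-out ultra-low-dose series denoised by the trained CAE."""
    _, _, uldct_test, _, _ = study128
    return denoise_volume(trained_cae, uldct_test)


def naive_overlap_denoise(model, hu_slice, patch: int = 28, stride: int = 1):
    """Brute-force reference for overlap averaging: one patch at a time."""
    from uldct import _engine
    from uldct.preprocess import denormalize, normalize_hu

    norm = np.asarray(normalize_hu(hu_slice))
    acc = np.zeros_like(norm)
    count = np.zeros(norm.shape, dtype=np.int64)
    n_rows, n_cols = norm.shape
    for r in range(0, n_rows - patch + 1, stride):
        for c in range(0, n_cols - patch + 1, stride):
            window = norm[r:r + patch, c:c + patch][None]
            out = _engine.forward(model.spec, model.params, window,
                                  deterministic=True, clip=True)[0]
            acc[r:r + patch, c:c + patch] += out
            count[r:r + patch, c:c + patch] += 1
    covered = count > 0
    acc[covered] /= count[covered]
    acc[~covered] = norm[~covered]
    return np.asarray(denormalize(acc))


def naive_nlm(hu, patch_side: int, search_side: int, h: float):
    """Brute-force non-local means: explicit pixel/neighbor/patch loops."""
    import math

    from uldct.preprocess import denormalize, normalize_hu

    img = np.asarray(normalize_hu(hu))
    pr, sr = (patch_side - 1) // 2, (search_side - 1) // 2
    pad = pr + sr
    padded = np.pad(img, pad, mode="reflect")
    n_rows, n_cols = img.shape
    out = np.empty_like(img)
    h2 = h * h
    for i in range(n_rows):
        for j in range(n_cols):
            num = den = 0.0
            patch_i = padded[pad + i - pr:pad + i + pr + 1,
                             pad + j - pr:pad + j + pr + 1]
            for di in range(-sr, sr + 1):
                for dj in range(-sr, sr + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < n_rows and 0 <= jj < n_cols):
                        continue
                    patch_j = padded[pad + ii - pr:pad + ii + pr + 1,
                                     pad + jj - pr:pad + jj + pr + 1]
                    w = math.exp(-float(np.mean((patch_i - patch_j) ** 2)) / h2)
                    num += w * img[ii, jj]
                    den += w
            out[i, j] = num / den
    return np.asarray(denormalize(out))


def make_synthetic_patchset(n_train: int = 200, n_val: int = 60,
                            noise: float = 0.05, shift: float | None = None,
                            seed: int = 0, patch_size: int = 28) -> PatchDataset:
    """Small self-contained patch dataset for fast training-contract tests.

    Targets are smooth random fields in [0.2, 0.8]; inputs add i.i.d. noise
    (or a constant shift, or nothing when ``noise=0`` and ``shift=None``).
    """
    rng = np.random.default_rng(seed)
    n = n_train + n_val
    base = gaussian_filter(rng.uniform(0, 1, (n, patch_size, patch_size)),
                           sigma=(0, 3, 3))
    lo, hi = base.min(), base.max()
    x = 0.2 + 0.6 * (base - lo) / (hi - lo)
    if shift is not None:
        y = np.clip(x + shift, 0.0, 1.0)
    elif noise > 0:
        y = np.clip(x + noise * rng.standard_normal(x.shape), 0.0, 1.0)
    else:
        y = x.copy()
    centers = np.zeros((n, 3), dtype=np.int64)
    return PatchDataset(
        x_train=x[:n_train], y_train=y[:n_train],
        x_val=x[n_train:], y_val=y[n_train:],
        centers_train=centers[:n_train], centers_val=centers[n_train:],
        patch_size=patch_size, seed=seed,
    )
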