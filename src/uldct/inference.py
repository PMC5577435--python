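"""Whole-image denoising by overlapping patches with overlap averaging.

The slice is normalized to [0, 1], decomposed into every patch window that
fits fully inside it (stepping by ``stride``; the default stride 1 is the
pixel-by-pixel decomposition), each patch is reconstructed by the trained
network, and the outputs are summed into an accumulator and divided by the
per-pixel coverage count before the inverse intensity transform.

Patch windows are never padded past the slice border: border pixels are
simply covered by fewer windows.  At stride 1 every pixel of a slice at
least one patch wide is covered by at least one window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .exceptions import ValidationError
from .preprocess import denormalize, normalize_hu
from .volume import CTVolume


@dataclass(frozen=True)
class DenoiseConfig:
    patch_size: int = 28
    stride: int = 1
    batch_size: int = 1024

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.patch_size):
            raise ValidationError("stride must satisfy 1 <= stride <= patch_size")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


def patch_positions(image_shape: tuple[int, int], patch: int, stride: int
                    ) -> list[tuple[int, int]]:
    """Top-left corners of all fully interior patch windows, row-major."""
    n_rows, n_cols = image_shape
    return [(r, c)
            for r in range(0, n_rows - patch + 1, stride)
            for c in range(0, n_cols - patch + 1, stride)]


def coverage_count(image_side: int, patch: int, stride: int = 1) -> np.ndarray:
    """How many patch windows cover each pixel of a square image."""
    if image_side < patch:
        raise ValidationError("image_side must be >= patch")
    count = np.zeros((image_side, image_side), dtype=np.int64)
    for r, c in patch_positions((image_side, image_side), patch, stride):
        count[r:r + patch, c:c + patch] += 1
    return count


def denoise_slice(model, hu_slice: np.ndarray,
                  config: DenoiseConfig | None = None) -> np.ndarray:
    """Denoise one HU slice with a trained model (overlap averaging).

    ``model`` is any object with ``spec`` and ``params`` attributes (a
    :class:`~uldct.model.DenoisingResults`).  Returns the denoised slice in HU.
    """
    cfg = config or DenoiseConfig(patch_size=model.spec.input_side)
    patch = cfg.patch_size
    if patch != model.spec.input_side:
        raise ValidationError(
            f"config patch_size {patch} != model input side {model.spec.input_side}")
    hu_slice = np.asarray(hu_slice, dtype=np.float64)
    if hu_slice.ndim != 2:
        raise ValidationError("hu_slice must be 2-D")
    if hu_slice.shape[0] < patch or hu_slice.shape[1] < patch:
        raise ValidationError(
            f"slice {hu_slice.shape} smaller than patch size {patch}")

    norm = normalize_hu(hu_slice)
    positions = patch_positions(hu_slice.shape, patch, cfg.stride)
    patches = np.stack([norm[r:r + patch, c:c + patch] for r, c in positions])

    outputs = np.empty_like(patches)
    for start in range(0, patches.shape[0], cfg.batch_size):
        stop = start + cfg.batch_size
        outputs[start:stop] = _engine.forward(
            model.spec, model.params, patches[start:stop],
            deterministic=True, clip=True)

    acc = np.zeros_like(norm)
    count = np.zeros(hu_slice.shape, dtype=np.int64)
    for out, (r, c) in zip(outputs, positions):
        acc[r:r + patch, c:c + patch] += out
        count[r:r + patch, c:c + patch] += 1
    covered = count > 0
    acc[covered] /= count[covered]
    # Pixels a coarse stride leaves uncovered keep their input value.
    acc[~covered] = norm[~covered]
    return denormalize(acc)


def denoise_volume(model, volume: CTVolume,
                   config: DenoiseConfig | None = None) -> CTVolume:
    """Denoise every slice independently; provenance records the model hash."""
    cfg = config or DenoiseConfig(patch_size=model.spec.input_side)
    out = np.empty_like(volume.voxels)
    for s in range(volume.n_slices):
        try:
            out[s] = denoise_slice(model, volume.voxels[s], cfg)
        except ValidationError as exc:
            raise ValidationError(f"slice {s}: {exc}") from exc
    meta = dict(volume.meta)
    meta.update({"denoised_from": volume.kind, "stride": cfg.stride,
                 "model_sha256": model.checksum() if hasattr(model, "checksum") else ""})
    result = CTVolume(out, spacing=volume.spacing, kind="denoised", meta=meta)
    return result
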