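"""Lung segmentation, lung-masked image-quality metrics, and the NLM baseline.

Metric conventions (recorded in every report): PSNR and SSIM are computed in
the normalized [0, 1] intensity space after non-lung voxels are zeroed in HU,
with peak / dynamic range 1, an 11x11 Gaussian SSIM window (sigma 1.5) and the
standard stabilizer constants k1 = 0.01, k2 = 0.03.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import SegmentationError, ValidationError
from .preprocess import denormalize, normalize_hu
from .volume import CTVolume, LungMask

LUNG_THRESHOLD_HU = -500.0


# --------------------------------------------------------------------------
# lung segmentation
# --------------------------------------------------------------------------

def segment_lungs(sdct: CTVolume, threshold: float = LUNG_THRESHOLD_HU,
                  closing_radius: int = 3, keep_components: int = 2,
                  seed_point: tuple[int, int, int] | None = None) -> LungMask:
    """Threshold-and-grow lung segmentation with vessel-filling closing.

    Voxels below ``threshold`` HU are grouped into connected components.  The
    surrounding air is identified as any component touching the in-plane
    volume boundary and removed; of the interior components, the largest
    ``keep_components`` are kept (the two lungs).  A per-slice binary closing
    with a disk of ``closing_radius`` pixels absorbs bright intralung vessels
    into the mask.

    Alternatively a ``seed_point`` (slice, row, col) selects the component
    containing that voxel — an explicit region-growing seed.

    Raises
    ------
    SegmentationError
        If no interior sub-threshold component exists.
    """
    low = sdct.voxels < threshold
    labels, n_labels = ndimage.label(low)
    if n_labels == 0:
        raise SegmentationError("no voxels below threshold: volume has no lung-like region")

    if seed_point is not None:
        seed_label = labels[tuple(seed_point)]
        if seed_label == 0:
            raise SegmentationError(f"seed point {seed_point} is not below threshold")
        kept = labels == seed_label
    else:
        # Background air touches the in-plane border on every slice; lungs do
        # not.  (Slice-direction faces are excluded: lungs legitimately reach
        # the first and last slice of a cropped volume.)
        border_labels = np.unique(np.concatenate([
            labels[:, 0, :].ravel(), labels[:, -1, :].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
        interior = np.setdiff1d(np.arange(1, n_labels + 1), border_labels)
        if interior.size == 0:
            raise SegmentationError("every sub-threshold component touches the boundary")
        sizes = ndimage.sum_labels(low, labels, interior)
        order = interior[np.argsort(sizes)[::-1]]
        chosen = order[:keep_components]
        kept = np.isin(labels, chosen)

    if closing_radius > 0:
        disk = _disk(closing_radius)
        closed = np.empty_like(kept)
        for s in range(kept.shape[0]):
            closed[s] = ndimage.binary_closing(kept[s], structure=disk)
        kept = kept | closed
    if not kept.any():
        raise SegmentationError("segmentation produced an empty mask")
    return LungMask(kept, spacing=sdct.spacing)


def _disk(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius ** 2


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom


def apply_lung_zeroing(volume: CTVolume, mask: LungMask) -> CTVolume:
    """Set every non-lung voxel to 0 HU, leaving lung voxels untouched."""
    mask.check_congruent(volume)
    return volume.with_voxels(np.where(mask.mask, volume.voxels, 0.0))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(peak^2 / MSE).

    Returns ``math.inf`` when the images are identical.
    """
    if peak <= 0:
        raise ValidationError("peak must be positive")
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValidationError("psnr: shape mismatch")
    msd = float(np.mean((reference - test) ** 2))
    if msd == 0.0:
        return math.inf
    return 10.0 * math.log10(peak ** 2 / msd)


def _gaussian_window(window: int, sigma: float) -> np.ndarray:
    radius = (window - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def ssim(reference: np.ndarray, test: np.ndarray, window: int = 11,
         k1: float = 0.01, k2: float = 0.03, sigma: float = 1.5,
         dynamic_range: float = 1.0) -> float:
    """Structural similarity index (Gaussian-weighted windows).

    Mean over all fully interior windows of the standard luminance-contrast-
    structure product with stabilizers (k1 L)^2 and (k2 L)^2, L the dynamic
    range.  Windowed moments use population (not sample) normalization.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if dynamic_range <= 0:
        raise ValidationError("dynamic_range must be positive")
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("ssim: shape mismatch")
    if x.ndim != 2 or min(x.shape) < window:
        raise ValidationError("ssim: images must be 2-D and at least window-sized")

    kern = _gaussian_window(window, sigma)
    radius = (window - 1) // 2

    def filt(img):
        return ndimage.convolve(img, kern, mode="constant")[radius:-radius, radius:-radius]

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    return float(np.mean(s))


# --------------------------------------------------------------------------
# non-local means baseline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NlmParams:
    """NLM settings; defaults follow the chest-CT baseline configuration."""

    patch_side: int = 11
    search_side: int = 81
    h: float = 0.02

    def __post_init__(self) -> None:
        if self.patch_side % 2 == 0 or self.search_side % 2 == 0:
            raise ValidationError("patch_side and search_side must be odd")
        if self.h <= 0:
            raise ValidationError("h must be positive")


def nlm_denoise(hu_slice: np.ndarray, params: NlmParams | None = None) -> np.ndarray:
    """Non-local-means denoising of one HU slice.

    Operates in normalized [0, 1] space.  Each pixel is replaced by a
    weighted average of the pixels in its search window, with weights
    ``w = exp(-d^2 / h^2)`` where ``d^2`` is the *mean* squared difference
    between the two pixels' patches (so ``h`` is in normalized intensity
    units).  Patches near the border are completed by reflection; candidate
    pixels outside the image are excluded.
    """
    p = params or NlmParams()
    x = np.asarray(hu_slice, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("hu_slice must be 2-D")
    if min(x.shape) < p.search_side:
        raise ValidationError("slice must be larger than the search window")

    img = np.asarray(normalize_hu(x))
    pr = (p.patch_side - 1) // 2
    sr = (p.search_side - 1) // 2
    pad = pr + sr
    xq = np.pad(img, pad, mode="reflect")
    n_rows, n_cols = img.shape
    h2 = p.h * p.h
    n_patch = p.patch_side ** 2

    num = np.zeros_like(img)
    den = np.zeros_like(img)
    core = xq[sr:sr + n_rows + 2 * pr, sr:sr + n_cols + 2 * pr]
    for di in range(-sr, sr + 1):
        for dj in range(-sr, sr + 1):
            shifted = xq[sr + di:sr + di + n_rows + 2 * pr,
                         sr + dj:sr + dj + n_cols + 2 * pr]
            sq = (core - shifted) ** 2
            d2 = ndimage.uniform_filter(sq, size=p.patch_side, mode="constant")
            d2 = d2[pr:pr + n_rows, pr:pr + n_cols]
            w = np.exp(-d2 / h2)
            # candidate pixel must lie inside the image
            valid = np.zeros_like(w, dtype=bool)
            r0, r1 = max(0, -di), min(n_rows, n_rows - di)
            c0, c1 = max(0, -dj), min(n_cols, n_cols - dj)
            valid[r0:r1, c0:c1] = True
            w = np.where(valid, w, 0.0)
            values = xq[pad + di:pad + di + n_rows, pad + dj:pad + dj + n_cols]
            num += w * values
            den += w
    return np.asarray(denormalize(num / den))


# --------------------------------------------------------------------------
# study-level evaluation
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Lung-masked PSNR/SSIM per candidate per lung field."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        import json
        with open(path, "w") as f:
            json.dump({"metadata": self.metadata,
                       "rows": self.table.to_dict(orient="records")}, f, indent=2)

    def value(self, method: str, fieldname: str, metric: str) -> float:
        row = self.table[(self.table.method == method) & (self.table.field == fieldname)]
        if row.empty:
            raise KeyError(f"no entry for {method}/{fieldname}")
        return float(row.iloc[0][metric])


def default_field_bounds(n_slices: int) -> dict[str, tuple[int, int]]:
    """Equal-thirds split of the slice range into upper/middle/lower fields.

    Fields that would be empty (volumes with fewer than three slices) are
    dropped rather than reported with a zero-length range.
    """
    edges = [round(i * n_slices / 3) for i in range(4)]
    bounds = {"upper": (edges[0], edges[1]),
              "middle": (edges[1], edges[2]),
              "lower": (edges[2], edges[3])}
    return {name: span for name, span in bounds.items() if span[1] > span[0]}


def evaluate_study(sdct: CTVolume, candidates: dict[str, CTVolume], mask: LungMask,
                   field_bounds: dict[str, tuple[int, int]] | None = None,
                   ssim_window: int = 11) -> MetricsReport:
    """Lung-masked PSNR and SSIM of each candidate against the reference.

    Non-lung voxels of the reference and every candidate are zeroed (in HU),
    intensities are normalized to [0, 1], and PSNR (peak 1, over all voxels
    of the field jointly) and SSIM (per slice, averaged over the field's
    slices) are computed per lung field.
    """
    bounds = field_bounds or default_field_bounds(sdct.n_slices)
    for name, (lo, hi) in bounds.items():
        if hi <= lo:
            raise ValidationError(f"field {name!r} has empty slice range [{lo}, {hi})")
    mask.check_congruent(sdct)
    ref = np.asarray(normalize_hu(apply_lung_zeroing(sdct, mask).voxels))

    rows = []
    for method, volume in candidates.items():
        if volume.shape != sdct.shape:
            raise ValidationError(f"candidate {method!r} not congruent with reference")
        cand = np.asarray(normalize_hu(apply_lung_zeroing(volume, mask).voxels))
        for fieldname, (lo, hi) in bounds.items():
            p = psnr(ref[lo:hi], cand[lo:hi], peak=1.0)
            s = float(np.mean([ssim(ref[i], cand[i], window=ssim_window,
                                    dynamic_range=1.0)
                               for i in range(lo, hi)]))
            rows.append({"method": method, "field": fieldname,
                         "psnr_db": p, "ssim": s})
    meta = {
        "peak": 1.0, "dynamic_range": 1.0, "ssim_window": ssim_window,
        "ssim_k1": 0.01, "ssim_k2": 0.03, "ssim_sigma": 1.5,
        "intensity_space": "normalized [0,1]",
        "mask_voxels": int(mask.mask.sum()),
        "field_bounds": {k: list(v) for k, v in bounds.items()},
    }
    return MetricsReport(table=pd.DataFrame(rows), metadata=meta)
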