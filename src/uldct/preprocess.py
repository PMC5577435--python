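"""HU normalization and paired patch-dataset construction.

CT values are mapped to [0, 1] before entering any network:

    f(x) = 0                  if x < -1500
           1                  if x >  1500
           (x + 1500) / 3000  otherwise

and denoised outputs are mapped back with the inverse of the linear branch.
Training data are pairs of 28x28 patches cut at identical lung positions from
a registered standard-dose / ultra-low-dose volume pair: the noisy patch is
the network input, the standard-dose patch the regression target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .exceptions import CapacityError, ValidationError
from .volume import CTVolume, LungMask

log = logging.getLogger(__name__)

HU_LOW = -1500.0
HU_HIGH = 1500.0
HU_RANGE = HU_HIGH - HU_LOW  # 3000

DEFAULT_PATCH_SIZE = 28
DEFAULT_N_TRAIN = 100_000
DEFAULT_N_VAL = 10_000


def normalize_hu(x):
    """Map HU to [0, 1]: clamp outside [-1500, 1500], linear in between.

    Elementwise on arrays; scalars return scalars.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(np.isnan(arr)):
        raise ValidationError("normalize_hu: NaN input")
    out = np.clip((arr + (-HU_LOW)) / HU_RANGE, 0.0, 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def denormalize(y):
    """Inverse of the linear branch of :func:`normalize_hu`.

    Inputs are clipped to [0, 1] first (denoiser outputs may stray slightly),
    then mapped by ``3000 * y - 1500``.
    """
    arr = np.clip(np.asarray(y, dtype=np.float64), 0.0, 1.0)
    out = HU_RANGE * arr + HU_LOW
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


@dataclass
class PatchDataset:
    """Paired normalized patches split into training and validation sets.

    ``x_*`` are clean standard-dose patches (targets), ``y_*`` the matching
    ultra-low-dose patches (inputs); ``centers_*`` hold the (slice, row, col)
    extraction centers.  Train and validation center sets are disjoint.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    centers_train: np.ndarray
    centers_val: np.ndarray
    patch_size: int = DEFAULT_PATCH_SIZE
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("x_train", "y_train", "x_val", "y_val"):
            arr = getattr(self, name)
            if arr.ndim != 3 or arr.shape[1:] != (self.patch_size, self.patch_size):
                raise ValidationError(f"{name}: expected (n, {self.patch_size}, {self.patch_size})")
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValidationError(f"{name}: values outside [0, 1]")
        if self.x_train.shape != self.y_train.shape or self.x_val.shape != self.y_val.shape:
            raise ValidationError("paired arrays must have identical shapes")

    @property
    def n_train(self) -> int:
        return self.x_train.shape[0]

    @property
    def n_val(self) -> int:
        return self.x_val.shape[0]

    def split(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which == "train":
            return self.x_train, self.y_train
        if which == "val":
            return self.x_val, self.y_val
        raise ValidationError(f"unknown split {which!r}")

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["patch_size"] = self.patch_size
            f.attrs["seed"] = self.seed
            for key, value in self.meta.items():
                f.attrs[f"meta_{key}"] = value
            for split, (x, y, c) in {
                "train": (self.x_train, self.y_train, self.centers_train),
                "val": (self.x_val, self.y_val, self.centers_val),
            }.items():
                g = f.create_group(split)
                g.create_dataset("x", data=x)
                g.create_dataset("y", data=y)
                g.create_dataset("centers", data=c)

    @classmethod
    def from_hdf5(cls, path: str) -> "PatchDataset":
        with h5py.File(path, "r") as f:
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(
                x_train=f["train/x"][...], y_train=f["train/y"][...],
                x_val=f["val/x"][...], y_val=f["val/y"][...],
                centers_train=f["train/centers"][...],
                centers_val=f["val/centers"][...],
                patch_size=int(f.attrs["patch_size"]), seed=int(f.attrs["seed"]),
                meta=meta,
            )


def eligible_centers(mask: LungMask, patch_size: int) -> np.ndarray:
    """(n, 3) array of lung-masked centers whose full patch window fits in-slice.

    A patch is "from lungs" when its *center* pixel is lung-masked; the window
    itself may extend past the lung boundary but never past the slice edge.
    """
    _, n_rows, n_cols = mask.shape
    half_lo = (patch_size - 1) // 2
    half_hi = patch_size - half_lo  # center + half_hi is the exclusive window end
    ok = np.zeros_like(mask.mask)
    ok[:, half_lo:n_rows - half_hi + 1, half_lo:n_cols - half_hi + 1] = True
    return np.argwhere(mask.mask & ok)


def extract_paired_patches(sdct: CTVolume, uldct: CTVolume, mask: LungMask,
                           n_train: int = DEFAULT_N_TRAIN, n_val: int = DEFAULT_N_VAL,
                           patch_size: int = DEFAULT_PATCH_SIZE,
                           seed: int = 0) -> PatchDataset:
    """Randomly extract paired lung patches and normalize them.

    Centers are drawn uniformly without replacement across train and
    validation jointly, so the two splits can never share a center.

    Raises
    ------
    CapacityError
        If fewer than ``n_train + n_val`` eligible centers exist.
    ValidationError
        If the two volumes are not congruent.
    """
    if sdct.shape != uldct.shape:
        raise ValidationError(f"volume shapes differ: {sdct.shape} vs {uldct.shape}")
    mask.check_congruent(sdct)
    centers = eligible_centers(mask, patch_size)
    needed = n_train + n_val
    if centers.shape[0] < needed:
        raise CapacityError(
            f"need {needed} centers but only {centers.shape[0]} eligible lung positions")
    rng = np.random.default_rng(seed)
    chosen = centers[rng.choice(centers.shape[0], size=needed, replace=False)]
    centers_train, centers_val = chosen[:n_train], chosen[n_train:]

    x_norm = normalize_hu(sdct.voxels)
    y_norm = normalize_hu(uldct.voxels)

    def cut(volume: np.ndarray, cs: np.ndarray) -> np.ndarray:
        half_lo = (patch_size - 1) // 2
        out = np.empty((cs.shape[0], patch_size, patch_size), dtype=np.float64)
        for i, (s, r, c) in enumerate(cs):
            r0, c0 = r - half_lo, c - half_lo
            out[i] = volume[s, r0:r0 + patch_size, c0:c0 + patch_size]
        return out

    return PatchDataset(
        x_train=cut(x_norm, centers_train), y_train=cut(y_norm, centers_train),
        x_val=cut(x_norm, centers_val), y_val=cut(y_norm, centers_val),
        centers_train=centers_train, centers_val=centers_val,
        patch_size=patch_size, seed=seed,
        meta={"n_eligible": centers.shape[0]},
    )


def register_hook(fixed: CTVolume, moving: CTVolume) -> CTVolume:
    """Identity pass-through registration point.

    Synthetic pairs are intrinsically registered; real data registered
    externally (e.g. with ANTs) enter the pipeline here.  Only congruence is
    checked; a notice is logged so provenance shows the no-op.
    """
    if fixed.shape != moving.shape:
        raise ValidationError(
            f"register_hook: shape mismatch {fixed.shape} vs {moving.shape}")
    log.info("register_hook: identity pass-through (volumes assumed registered)")
    return moving
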