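"""In-memory CT volume and lung-mask containers plus NIfTI round-trip.

Axis convention throughout the package: ``(slice, row, column)``, 0-based.
Voxel values are Hounsfield units (HU): air ~ -1000, water 0, bone >> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .exceptions import ValidationError

#: HU range representable on CT scanners with a 12-bit detector pipeline.
HU_MIN = -1024.0
HU_MAX = 3071.0

VOLUME_KINDS = ("ground_truth", "sdct", "uldct_train", "uldct_test", "denoised")


@dataclass
class CTVolume:
    """A voxel grid in Hounsfield units with spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values; must be finite.
    spacing : tuple of float
        Millimetres per voxel along (slice, row, column).
    kind : str
        Provenance tag, one of :data:`VOLUME_KINDS`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)
    kind: str = "ground_truth"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxels must be 3-D (slice, row, col); got ndim={self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxels contain non-finite values")
        if self.kind not in VOLUME_KINDS:
            raise ValidationError(f"unknown volume kind {self.kind!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be 3 positive floats (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray, kind: str | None = None) -> "CTVolume":
        """Copy of this volume with replaced voxel data (spacing preserved)."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64),
                       kind=self.kind if kind is None else kind)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str) -> None:
        """Write as NIfTI, HU rounded and stored as signed 16-bit.

        Data axes are stored as (col, row, slice) so that standard viewers
        show axial slices; the affine carries the spacing in mm.
        """
        data = np.clip(np.rint(self.voxels), HU_MIN, HU_MAX).astype(np.int16)
        data = np.transpose(data, (2, 1, 0))
        affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, kind: str = "ground_truth") -> "CTVolume":
        img = nib.load(path)
        data = np.transpose(np.asanyarray(img.dataobj).astype(np.float64), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return cls(voxels=data, spacing=spacing, kind=kind)


@dataclass
class LungMask:
    """Boolean grid congruent with its :class:`CTVolume`, True on lung voxels."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be 3-D (slice, row, col)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def check_congruent(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != volume shape {volume.shape}"
            )

    def to_nifti(self, path: str) -> None:
        data = np.transpose(self.mask.astype(np.uint8), (2, 1, 0))
        affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
        nib.save(nib.Nifti1Image(data, affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "LungMask":
        img = nib.load(path)
        data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)) > 0
        zooms = img.header.get_zooms()[:3]
        return cls(mask=data, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])))
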