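"""Synthetic chest-phantom generator.

Builds noise-free axial CT slices of an anthropomorphic-style chest phantom:
an elliptical soft-tissue body, two lung ellipses whose cross-section waxes
and wanes along the craniocaudal axis, bright vessel disks scattered inside
the lungs, and a vertebral bone ellipse.  The generator also returns the
ground-truth lung mask, which downstream modules use for patch sampling and
for validating lung segmentation.

All geometry defaults are expressed as fractions of the slice side so the
same anatomy is produced at any resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .volume import CTVolume, LungMask, HU_MIN, HU_MAX

# Tissue palette (HU).  These are artifact choices recorded in provenance:
# typical textbook values for air, aerated parenchyma, soft tissue, blood
# and trabecular bone.
DEFAULT_TISSUES = {
    "air": -1000.0,
    "lung": -850.0,
    "soft_tissue": 40.0,
    "bone": 700.0,
    "vessel": 30.0,
}


@dataclass
class PhantomSpec:
    """Geometry and tissue description of the synthetic chest phantom.

    Geometry fields are fractions of ``image_side`` (center_row, center_col,
    semi_axis_row, semi_axis_col).  ``lung_axes`` gives the mid-volume lung
    semi-axes; the per-slice axes are scaled by a smooth craniocaudal profile
    so apical/basal slices carry small lungs.
    """

    image_side: int = 256
    n_slices: int = 3
    body: tuple[float, float, float, float] = (0.50, 0.50, 0.32, 0.44)
    lung_left: tuple[float, float, float, float] = (0.51, 0.305, 0.215, 0.150)
    lung_right: tuple[float, float, float, float] = (0.51, 0.695, 0.215, 0.150)
    bone: tuple[float, float, float, float] = (0.745, 0.50, 0.062, 0.050)
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    vessels_per_lung: int = 6
    vessel_radius_range: tuple[float, float] = (0.008, 0.016)
    rng_seed: int = 0
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.spacing is None:
            # Constant physical field of view (256 mm in-plane) at any grid
            # size, so dose/noise physics do not depend on resolution.
            px = 256.0 / self.image_side
            self.spacing = (1.25, px, px)
        if self.image_side < 32:
            raise ValidationError("image_side must be >= 32 pixels")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        for name, value in self.tissues.items():
            if not (HU_MIN <= value <= HU_MAX):
                raise ValidationError(f"tissue {name!r} HU {value} outside [{HU_MIN}, {HU_MAX}]")
        for lung in (self.lung_left, self.lung_right):
            if not _ellipse_inside(lung, self.body):
                raise ValidationError("lung ellipse not strictly inside the body ellipse")

    def slice_profile(self, slice_index: int) -> float:
        """Smooth scale factor for lung axes: small at the ends, 1 mid-volume."""
        t = (slice_index + 0.5) / self.n_slices
        return 0.55 + 0.45 * float(np.sin(np.pi * t))


def _ellipse_inside(inner, outer) -> bool:
    """Conservative containment check for axis-aligned ellipses."""
    ir, ic, iar, iac = inner
    orow, ocol, oar, oac = outer
    # Sample the inner boundary and test against the outer implicit equation.
    t = np.linspace(0.0, 2 * np.pi, 128)
    r = ir + iar * np.cos(t)
    c = ic + iac * np.sin(t)
    return bool(np.all(((r - orow) / oar) ** 2 + ((c - ocol) / oac) ** 2 < 1.0))


def _ellipse_mask(side: int, center_row: float, center_col: float,
                  ax_row: float, ax_col: float) -> np.ndarray:
    rows = np.arange(side)[:, None]
    cols = np.arange(side)[None, :]
    return ((rows - center_row) / ax_row) ** 2 + ((cols - center_col) / ax_col) ** 2 <= 1.0


def generate_phantom_slice(spec: PhantomSpec, slice_index: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free phantom slice and its lung mask.

    Returns
    -------
    hu_slice : ndarray (side, side) of float64
        Ground-truth HU values.
    lung_mask_slice : ndarray (side, side) of bool
        True exactly on lung-interior pixels (vessels included).

    Raises
    ------
    IndexError
        If ``slice_index`` is outside ``[0, n_slices)``.
    """
    if not (0 <= slice_index < spec.n_slices):
        raise IndexError(f"slice_index {slice_index} outside [0, {spec.n_slices})")
    side = spec.image_side
    hu = np.full((side, side), spec.tissues["air"], dtype=np.float64)

    def px(fraction: float) -> float:
        return fraction * side

    br, bc, bar, bac = spec.body
    body = _ellipse_mask(side, px(br), px(bc), px(bar), px(bac))
    hu[body] = spec.tissues["soft_tissue"]

    scale = spec.slice_profile(slice_index)
    lung_mask = np.zeros((side, side), dtype=bool)
    # Per-slice child RNG: vessel layout is deterministic per (seed, slice).
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(slice_index,)))
    for lr, lc, lar, lac in (spec.lung_left, spec.lung_right):
        ar, ac = px(lar) * scale, px(lac) * scale
        lung = _ellipse_mask(side, px(lr), px(lc), ar, ac)
        lung_mask |= lung
        hu[lung] = spec.tissues["lung"]
        # Vessels: disks fully inside the lung ellipse, position drawn in
        # normalized ellipse coordinates with a margin for the disk radius.
        for _ in range(spec.vessels_per_lung):
            radius = rng.uniform(*spec.vessel_radius_range) * side
            radius = max(radius, 1.0)
            margin = 1.0 - (radius + 1.0) / min(ar, ac)
            if margin <= 0:
                continue
            while True:
                u, v = rng.uniform(-1, 1, size=2)
                if u * u + v * v <= margin * margin:
                    break
            vrow, vcol = px(lr) + u * ar, px(lc) + v * ac
            vessel = _ellipse_mask(side, vrow, vcol, radius, radius)
            hu[vessel & lung] = spec.tissues["vessel"]

    bor, boc, boar, boac = spec.bone
    bone = _ellipse_mask(side, px(bor), px(boc), px(boar), px(boac))
    hu[bone & body & ~lung_mask] = spec.tissues["bone"]
    return hu, lung_mask


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LungMask]:
    """Full noise-free phantom volume plus its ground-truth lung mask."""
    slices, masks = zip(*(generate_phantom_slice(spec, s) for s in range(spec.n_slices)))
    volume = CTVolume(np.stack(slices), spacing=spec.spacing, kind="ground_truth",
                      meta={"rng_seed": spec.rng_seed})
    mask = LungMask(np.stack(masks), spacing=spec.spacing)
    return volume, mask
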