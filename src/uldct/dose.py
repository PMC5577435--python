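"""Dose-dependent CT noise simulation in the sinogram domain.

The pipeline per slice is the classic transmission model:

1. HU -> linear attenuation ``mu = mu_water * (1 + HU/1000)``, clamped at 0;
2. parallel-beam forward projection (Radon transform) over ``n_projection_angles``
   spanning 180 degrees, with line integrals in millimetres;
3. expected transmitted counts ``I = i0 * exp(-p)`` per detector bin, replaced
   by a Poisson draw (counts floored at one photon before the log, the
   photon-starvation guard);
4. noisy projection ``p' = -ln(max(I, 1)/i0)``;
5. ramp-filtered back-projection;
6. attenuation back to HU.

The photon budget ``i0`` scales linearly with tube current, so a 300 mA
standard-dose scan sees 30x the photons of a 10 mA ultra-low-dose scan.
Because the noise is injected in the projection domain, low-dose slices show
the directional streaks characteristic of photon-starved rays through the
mediastinum rather than white image-domain noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon, iradon

from .exceptions import ValidationError
from .phantom import PhantomSpec, generate_phantom
from .volume import CTVolume, LungMask

#: Linear attenuation of water (per mm) at the simulated effective energy.
MU_WATER = 0.019

#: Reference photon count per detector bin at the reference tube current.
I0_REFERENCE = 1.0e5
REFERENCE_CURRENT_MA = 300.0


@dataclass
class DoseSimSpec:
    """Acquisition parameters of one simulated scan series."""

    tube_current_mA: float = 300.0
    i0_reference: float = I0_REFERENCE
    n_projection_angles: int = 360
    reconstruction_filter: str = "ramp"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_current_mA <= 0:
            raise ValidationError("tube_current_mA must be positive")
        if self.i0_reference <= 0:
            raise ValidationError("i0_reference must be positive")
        if self.n_projection_angles < 1:
            raise ValidationError("n_projection_angles must be >= 1")

    @property
    def i0(self) -> float:
        """Photon count at this tube current (linear in mA)."""
        return self.i0_reference * self.tube_current_mA / REFERENCE_CURRENT_MA


def hu_to_mu(hu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """HU to linear attenuation (per mm), clamped at zero."""
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0)


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / mu_water - 1.0)


def _project(hu_slice: np.ndarray, dose: DoseSimSpec, pixel_mm: float) -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, 180.0, dose.n_projection_angles, endpoint=False)
    mu = hu_to_mu(hu_slice)
    sinogram = radon(mu, theta=theta, circle=False) * pixel_mm
    return sinogram, theta


def _reconstruct(sinogram: np.ndarray, theta: np.ndarray, dose: DoseSimSpec,
                 side: int, pixel_mm: float) -> np.ndarray:
    mu = iradon(sinogram / pixel_mm, theta=theta, circle=False,
                filter_name=dose.reconstruction_filter, output_size=side)
    return mu_to_hu(mu)


def simulate_dose(hu_slice: np.ndarray, dose: DoseSimSpec,
                  pixel_mm: float = 1.0, rng_seed: int | None = None) -> np.ndarray:
    """Simulate one noisy acquisition of a noise-free slice.

    Parameters
    ----------
    hu_slice : (side, side) array
        Noise-free slice in HU.
    dose : DoseSimSpec
        Tube current / photon budget; ``dose.rng_seed`` seeds the Poisson
        draw unless ``rng_seed`` overrides it.
    pixel_mm : float
        In-plane pixel size in millimetres (sets ray path lengths).

    Returns
    -------
    (side, side) array of HU with dose-dependent, streak-like noise.
    """
    hu_slice = np.asarray(hu_slice, dtype=np.float64)
    if hu_slice.ndim != 2 or hu_slice.shape[0] != hu_slice.shape[1]:
        raise ValidationError("hu_slice must be a square 2-D array")
    if not np.all(np.isfinite(hu_slice)):
        raise ValidationError("hu_slice contains non-finite values")
    seed = dose.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    sinogram, theta = _project(hu_slice, dose, pixel_mm)
    expected = dose.i0 * np.exp(-sinogram)
    counts = rng.poisson(expected).astype(np.float64)
    noisy_sino = -np.log(np.maximum(counts, 1.0) / dose.i0)
    return _reconstruct(noisy_sino, theta, dose, hu_slice.shape[0], pixel_mm)


def reconstruct_noise_free(hu_slice: np.ndarray, dose: DoseSimSpec,
                           pixel_mm: float = 1.0) -> np.ndarray:
    """FBP of the exact sinogram: the zero-noise limit of :func:`simulate_dose`."""
    sinogram, theta = _project(np.asarray(hu_slice, dtype=np.float64), dose, pixel_mm)
    return _reconstruct(sinogram, theta, dose, hu_slice.shape[0], pixel_mm)


def simulate_volume(phantom: CTVolume, dose: DoseSimSpec, base_seed: int,
                    kind: str) -> CTVolume:
    """Independent noisy acquisition of every slice of a noise-free volume."""
    pixel_mm = phantom.spacing[2]
    out = np.empty_like(phantom.voxels)
    for s in range(phantom.n_slices):
        slice_seed = int(np.random.SeedSequence(
            entropy=int(base_seed), spawn_key=(s,)).generate_state(1)[0] % (2 ** 31))
        out[s] = simulate_dose(phantom.voxels[s], dose, pixel_mm=pixel_mm,
                               rng_seed=slice_seed)
    return CTVolume(out, spacing=phantom.spacing, kind=kind,
                    meta={"tube_current_mA": dose.tube_current_mA,
                          "i0": dose.i0, "rng_seed": int(base_seed)})


def make_paired_study(spec: PhantomSpec, dose_sd: DoseSimSpec, dose_uld: DoseSimSpec,
                      seeds: tuple[int, int, int]
                      ) -> tuple[CTVolume, CTVolume, CTVolume, LungMask, CTVolume]:
    """One standard-dose and two independent ultra-low-dose series of one phantom.

    Mirrors a paired phantom session: a single anatomy scanned at 300 mA
    (standard dose) and twice at 10 mA (one ultra-low-dose series for
    training, one held out for testing), all intrinsically registered.

    Returns
    -------
    (sdct, uldct_train, uldct_test, lung_mask, ground_truth)
    """
    if len(set(int(s) for s in seeds)) != len(seeds):
        raise ValidationError("seeds must be distinct: noise realizations must be independent")
    truth, mask = generate_phantom(spec)
    sdct = simulate_volume(truth, dose_sd, seeds[0], "sdct")
    uldct_train = simulate_volume(truth, dose_uld, seeds[1], "uldct_train")
    uldct_test = simulate_volume(truth, dose_uld, seeds[2], "uldct_test")
    return sdct, uldct_train, uldct_test, mask, truth


def lung_noise_sd(spec: PhantomSpec, dose: DoseSimSpec, seeds, slice_index: int = 0,
                  erode_iterations: int = 3) -> float:
    """Monte-Carlo noise level: SD of (noisy - noise-free FBP) inside the lungs.

    Averaged over the given seeds; the lung mask is eroded to avoid edge
    gradients contaminating the noise estimate.
    """
    from scipy.ndimage import binary_erosion

    hu, lung = generate_phantom_slice_cached(spec, slice_index)
    roi = binary_erosion(lung, iterations=erode_iterations)
    clean = reconstruct_noise_free(hu, dose, pixel_mm=spec.spacing[2])
    sds = []
    for seed in seeds:
        noisy = simulate_dose(hu, dose, pixel_mm=spec.spacing[2], rng_seed=int(seed))
        sds.append(float(np.std((noisy - clean)[roi])))
    return float(np.mean(sds))


def generate_phantom_slice_cached(spec: PhantomSpec, slice_index: int):
    # Thin indirection point (kept separate so callers can memoize externally).
    from .phantom import generate_phantom_slice
    return generate_phantom_slice(spec, slice_index)
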