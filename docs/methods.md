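# Methods

This note documents the models, the synthetic data, and the numerical
choices behind `uldct`, in the spirit of a package methods appendix.  It
states no empirical result that the test suite and `scripts/acceptance.py`
do not themselves compute.

## The denoising model

The core method is supervised patch-to-patch regression.  Let `x` be a
28×28 patch from a standard-dose CT (SDCT, 300 mA) series and `y` the patch
at the same location in a registered ultra-low-dose CT (ULDCT, 10 mA)
series of the same anatomy.  Intensities are mapped from Hounsfield units
to [0, 1] by

    f(x) = 0                    x < −1500 HU
           1                    x >  1500 HU
           (x + 1500) / 3000    otherwise

and a network `g` is fitted to minimise the mean squared error
`MSE = (1/n) Σ_i (x_i − g(y_i))²` over a training set of paired patches.
Two families are implemented:

* **DAE** — a dense auto-encoder on the 784-vectorised patch with sigmoid
  activations and decoder weights tied as the transposes of the mirrored
  encoder weights (`W' = Wᵀ`; pairwise for deeper symmetric stacks).  Tying
  is structural: one array serves both layers and receives gradient from
  both uses, so it cannot drift apart during optimisation.
* **CAE** — a plain stack of stride-1, zero-padded 2-D convolutions with no
  pooling.  With symmetric padding `⌊kernel/2⌋` every layer preserves the
  28×28 patch shape (`conv_output_size(28, k, ⌊k/2⌋) = 28`), so input,
  latent representations and output share the grid.  The sigmoid family
  applies sigmoid after every layer including the output; ReLU-family
  networks (the Chen-style reference and the random-search space) use a
  linear output convolution whose result is clipped to [0, 1] at inference.
  Sigmoid-after-ReLU would be non-standard, and the clip only affects the
  inference path — the training loss uses the raw output so gradients never
  vanish at the clip boundary.

Model selection is by validation MSE: `fit()` records the validation score
after every epoch and returns the weight snapshot of the best epoch, not
the last.  The grid search trains every (hidden layers × feature maps)
combination under one shared seeded configuration; the random search draws
architectures (layers from {1,3,5,7,9,11}, per-layer feature maps from
{16,32,48,80}, per-weight-layer kernels from {3,5,7,9,11}, paddings by the
truncation rule) with per-trial seeds spawned from a master seed, so a
rerun with the same master seed reproduces the identical ranked list.
Search ties are broken by fewer free parameters, then enumeration order.

## Whole-image denoising

A slice is normalised, decomposed into every 28×28 window that fits fully
inside it (stride 1 by default — the pixel-by-pixel decomposition), each
window reconstructed by the network, and the outputs accumulated into a sum
grid divided by a per-pixel coverage count before the inverse intensity
map.  Windows are never padded past the slice border; border pixels are
simply covered by fewer windows, and at stride 1 every pixel of a slice at
least 28 px wide is covered.  Whole-image convolution is *not* substituted
for the patch procedure even though the CAE is fully convolutional: the
per-patch zero padding makes the two genuinely different operations.

The implementation is verified bit-for-bit against a naive one-patch-at-a-
time reference.  To make that equality exact rather than approximate, the
inference convolution uses a compiled direct kernel whose accumulation
order is fixed per sample and therefore independent of batch grouping.

## The synthetic phantom study

No public paired SDCT/ULDCT phantom data exist, so the package generates
its own study conditions: a chest-phantom anatomy scanned once at 300 mA
and twice independently at 10 mA (one ULDCT series to train on, one held
out), plus the ground-truth lung mask.

**Geometry.**  Each axial slice holds an elliptical soft-tissue body
(40 HU), two lung ellipses (−850 HU) whose semi-axes follow a smooth
craniocaudal profile (55–100 % of the mid-volume size, so apical and basal
slices carry small lungs), seeded bright vessel disks (30 HU) strictly
inside the lungs, a vertebral bone ellipse (700 HU), and −1000 HU air
outside.  Geometry is specified in fractions of the slice side; the default
in-plane spacing is `256/image_side` mm so the physical field of view —
and hence the attenuation and noise physics — is resolution-independent.

**Noise.**  Noise is injected in the sinogram domain, not as image-domain
Gaussian noise: HU → linear attenuation (`μ_water = 0.019 /mm`, clamped at
0), parallel-beam Radon transform over 360 angles spanning 180°, expected
transmission counts `I = i0·exp(−p)` Poisson-sampled per detector bin
(floored at one photon before the log — the photon-starvation guard), and
ramp-filtered back-projection.  The photon budget `i0` is `1×10⁵` at
300 mA and scales linearly with tube current, giving a 30× photon ratio
between the standard and ultra-low dose.  Because photon starvation is
worst along long high-attenuation ray paths, low-dose reconstructions show
the directional streak artifacts that motivate the method; image-domain
white noise could not exercise that behaviour.

**What the phantom does not emulate:** beam hardening, scatter, bowtie
filtration, helical geometry, detector electronics, anatomical texture
inside the lung parenchyma, or breathing misregistration (synthetic pairs
are intrinsically registered; `register_hook` is the entry point for
externally registered real data).  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the expected
qualitative orderings (dose–noise law, denoising gains), not clinical
performance on scanner data.

## Patch sampling

Patch centers are drawn uniformly at random, without replacement across the
union of the training and validation sets, from lung-mask positions whose
full 28×28 window lies inside the slice.  A patch is "from lungs" when its
center pixel is masked; whole-window containment is not required, so lung
boundaries are represented.  Sampling without replacement across both
splits guarantees the two never share a center.

## Evaluation

Lung segmentation follows a threshold-and-grow scheme on the SDCT series:
voxels below −500 HU are grouped into connected components; components
touching the in-plane volume border (the surrounding air) are removed; the
largest two interior components are kept; and a per-slice binary closing
with a radius-3 disk absorbs the bright intralung vessels.  A manual
seed-point mode selects the component containing a given voxel instead.

PSNR and SSIM are computed after zeroing every non-lung voxel (in HU) in
both the reference and the candidate, in normalised [0, 1] space with
peak/dynamic range 1 — this makes PSNR independent of the HU clamp width;
the convention is recorded in every report's metadata.  SSIM uses the
standard constants k₁ = 0.01, k₂ = 0.03 and an 11×11 Gaussian window with
σ = 1.5 and population moments; the implementation is cross-checked in the
tests against an independent reference implementation to 1×10⁻⁶.  Lung
fields (upper/middle/lower) on synthetic volumes are equal thirds of the
slice range; fields that would be empty on volumes with fewer than three
slices are dropped.

The non-local-means baseline operates in normalised space: each pixel is
replaced by the weighted mean of the pixels in its search window (default
81×81), with weights `exp(−d²/h²)` where `d²` is the *mean* squared
difference of the two 11×11 patches.  Normalising the patch distance per
pixel puts `h` in intensity units, consistent with the tested range
0.0001–0.05.  Patches near the border are completed by reflection;
candidate pixels outside the image are excluded.  The multi-scale
machinery of "large-scale" NLM variants is out of scope; what is
implemented is the plain patch-similarity weighted average.

## Optimisation defaults and numerical choices

* **Optimizer.** Adam, learning rate 1×10⁻², batch size 64, default 30
  epochs.  The learning rate matters: Adam's per-step displacement is
  bounded by roughly the learning rate, and a sigmoid output must move its
  bias by ≈1.4 logits to reach mean lung intensity (normalised ≈0.22) from
  the σ(0)=0.5 start; at 1×10⁻³ a few hundred steps cannot traverse that
  distance, so small-budget fits stall far above the no-op baseline.  At
  1×10⁻² training is smooth for every architecture in the search spaces.
* **Initialisation.** Uniform weights scaled by 1/√fan-in, zero biases,
  seeded; every random choice in the package (phantom, noise, sampling,
  initialisation, batching) flows from named integer seeds through
  independent `SeedSequence` streams.
* **Precision and determinism.** All computation is float64.  Training uses
  the fastest convolution kernel per layer (a compiled direct kernel for
  small channel counts, im2col + BLAS GEMM for large ones); with a fixed
  batching scheme runs are bit-reproducible, and the reported best
  validation MSE is recomputable from the serialised weights.
* **Validation scoring** uses the inference output convention (clipped to
  [0, 1]); since targets lie in [0, 1], clipping never increases the
  squared error.
* **Degenerate inputs** raise typed errors: non-finite volumes, duplicate
  noise seeds in a paired study, empty masks, patch requests beyond
  capacity, slices smaller than the patch, kernels larger than the padded
  input, even kernels (no symmetric shape-preserving padding exists).

## Problem sizes used by the tests

The acceptance-style checks run the full workflow at desk scale: a 3-slice
128² study; 5,000 training / 1,000 validation patches; a 3-hidden-layer,
8-feature-map CAE trained 20 epochs; a 5-trial random search on a small
synthetic patch set (1 epoch per trial); and 20-seed Monte-Carlo noise
estimates for the dose law at 256².  These sizes are the package's chosen
demonstration conditions; the library itself is routinely run at the full
100,000/10,000-patch, 512² scale by passing the corresponding parameters.

## Known limitations

* The simulator's HU palette, photon budget and reconstruction settings are
  package choices recorded in provenance metadata, not measurements of any
  physical scanner; absolute MSE/PSNR/SSIM values are therefore not
  comparable to values reported for physical phantom studies.
* The DAE tying scheme for deep stacks (pairwise mirrored transposes) is
  one natural generalisation of the classic single-hidden-layer tie; other
  schemes exist.
* FBP at desk-scale grids (128²–256², 360 angles) carries discretisation
  error that is common to all series of a study; it cancels in comparisons
  between candidates but adds a floor to fidelity against the noise-free
  phantom.
* BM3D is not implemented; the evaluation harness accepts externally
  produced volumes wherever a candidate is expected.
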