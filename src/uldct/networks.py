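"""Declarative network architectures for patch denoising.

Two families are supported:

* ``dae`` — a fully connected denoising auto-encoder on vectorized 28x28
  patches (784 inputs), sigmoid activations, with decoder weights tied as the
  transposes of the mirrored encoder weights (W' = W^T, pairwise for deeper
  stacks).
* ``cae`` — a convolutional auto-encoder: a plain stack of stride-1 zero-padded
  2-D convolutions (no pooling).  With symmetric padding ``floor(kernel/2)``
  every layer preserves the 28x28 patch shape.

A :class:`NetworkSpec` is purely declarative; weights live in the training
engine.  Builders cover the grid-search family (uniform 3x3 kernels), the
three-convolution ReLU reference architecture of Chen et al., and the random
architecture-search space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import ValidationError

PATCH_SIDE = 28

RANDOM_HIDDEN_CHOICES = (1, 3, 5, 7, 9, 11)
RANDOM_MAP_CHOICES = (16, 32, 48, 80)
RANDOM_KERNEL_CHOICES = (3, 5, 7, 9, 11)


def conv_output_size(input_side: int, kernel: int, padding: int, stride: int = 1) -> int:
    """Spatial side after a 2-D convolution: floor((n + 2p - k)/s) + 1."""
    if input_side < 1 or kernel < 1 or stride < 1 or padding < 0:
        raise ValidationError("conv_output_size: arguments must be positive (padding >= 0)")
    if kernel > input_side + 2 * padding:
        raise ValidationError(
            f"kernel {kernel} exceeds padded input {input_side + 2 * padding}")
    return (input_side + 2 * padding - kernel) // stride + 1


def padding_from_kernel(kernel: int) -> int:
    """Symmetric padding that preserves shape at stride 1: floor(kernel/2).

    Only odd kernels admit shape preservation with symmetric padding.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"kernel must be odd and >= 1, got {kernel}")
    return kernel // 2


@dataclass
class NetworkSpec:
    """Architecture descriptor for either network family.

    For ``family='cae'``: ``feature_maps`` has one entry per hidden layer and
    ``kernel_sizes``/``paddings`` one entry per weight layer (hidden layers
    plus the single-channel output convolution).  For ``family='dae'``:
    ``units_per_layer`` hidden units in each of ``n_hidden_layers`` layers,
    decoder weights tied to the encoder.
    """

    family: str
    n_hidden_layers: int
    feature_maps: tuple[int, ...] = ()
    kernel_sizes: tuple[int, ...] = ()
    paddings: tuple[int, ...] = ()
    activation: str = "sigmoid"
    output_activation: str = "sigmoid"
    units_per_layer: int = 0
    tied: bool = True
    input_side: int = PATCH_SIDE

    def __post_init__(self) -> None:
        if self.family not in ("dae", "cae"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.n_hidden_layers < 1:
            raise ValidationError("n_hidden_layers must be >= 1")
        if self.activation not in ("sigmoid", "relu"):
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.output_activation not in ("sigmoid", "identity"):
            raise ValidationError(f"unknown output_activation {self.output_activation!r}")
        if self.family == "cae":
            self.feature_maps = tuple(int(m) for m in self.feature_maps)
            self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
            self.paddings = tuple(int(p) for p in self.paddings)
            n_weight = self.n_hidden_layers + 1
            if len(self.feature_maps) != self.n_hidden_layers:
                raise ValidationError("feature_maps must have one entry per hidden layer")
            if len(self.kernel_sizes) != n_weight or len(self.paddings) != n_weight:
                raise ValidationError(
                    "kernel_sizes and paddings must have n_hidden_layers + 1 entries")
            if any(m < 1 for m in self.feature_maps):
                raise ValidationError("feature_maps must be >= 1")
            side = self.input_side
            for k, p in zip(self.kernel_sizes, self.paddings):
                side = conv_output_size(side, k, p, stride=1)
                if side != self.input_side:
                    raise ValidationError(
                        f"layer with kernel {k}, padding {p} breaks shape preservation")
        else:
            if self.n_hidden_layers % 2 == 0:
                raise ValidationError(
                    "dae requires an odd hidden-layer count for symmetric weight tying")
            if self.units_per_layer < 1:
                raise ValidationError("units_per_layer must be >= 1")

    # ------------------------------------------------------------- structure
    @property
    def n_weight_layers(self) -> int:
        return self.n_hidden_layers + 1

    @property
    def input_dim(self) -> int:
        """Vectorized input length for the dense family."""
        return self.input_side * self.input_side

    def channel_sequence(self) -> tuple[int, ...]:
        """CAE channel counts including the 1-channel input and output."""
        if self.family != "cae":
            raise ValidationError("channel_sequence applies to the cae family")
        return (1, *self.feature_maps, 1)

    def layer_sides(self) -> list[int]:
        """Spatial side after each weight layer (shape-preservation audit)."""
        if self.family != "cae":
            return [self.input_side] * self.n_weight_layers
        sides, side = [], self.input_side
        for k, p in zip(self.kernel_sizes, self.paddings):
            side = conv_output_size(side, k, p, stride=1)
            sides.append(side)
        return sides

    def n_parameters(self) -> int:
        """Count of free parameters (tied DAE matrices counted once)."""
        if self.family == "cae":
            chans = self.channel_sequence()
            total = 0
            for c_in, c_out, k in zip(chans[:-1], chans[1:], self.kernel_sizes):
                total += c_out * c_in * k * k + c_out
            return total
        dims = [self.input_dim] + [self.units_per_layer] * self.n_hidden_layers + [self.input_dim]
        n_free_mats = (self.n_hidden_layers + 1) // 2 if self.tied else self.n_hidden_layers + 1
        total = sum(dims[j] * dims[j + 1] for j in range(n_free_mats))
        total += sum(dims[j + 1] for j in range(self.n_hidden_layers + 1))  # biases, all layers
        return total

    # ----------------------------------------------------------------- (de)serialization
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        payload = json.loads(text)
        for key in ("feature_maps", "kernel_sizes", "paddings"):
            payload[key] = tuple(payload.get(key, ()))
        return cls(**payload)


def build_cae(n_hidden: int, n_maps: int, kernel: int = 3,
              activation: str = "sigmoid") -> NetworkSpec:
    """CAE of the main grid: uniform feature maps and kernels, shape-preserving.

    Sigmoid networks apply sigmoid after every layer including the output;
    ReLU networks use an identity output (clipped to [0, 1] at inference).
    """
    if n_hidden < 1 or n_maps < 1:
        raise ValidationError("n_hidden and n_maps must be >= 1")
    n_weight = n_hidden + 1
    pad = padding_from_kernel(kernel)
    return NetworkSpec(
        family="cae", n_hidden_layers=n_hidden,
        feature_maps=(n_maps,) * n_hidden,
        kernel_sizes=(kernel,) * n_weight,
        paddings=(pad,) * n_weight,
        activation=activation,
        output_activation="sigmoid" if activation == "sigmoid" else "identity",
    )


def build_chen() -> NetworkSpec:
    """Three-convolution ReLU reference architecture (Chen et al. settings).

    Two hidden layers with 64 and 32 feature maps; kernels 9, 3, 5 with
    paddings 4, 1, 2 (the floor(kernel/2) rule); ReLU activations and a
    linear output convolution.
    """
    kernels = (9, 3, 5)
    return NetworkSpec(
        family="cae", n_hidden_layers=2, feature_maps=(64, 32),
        kernel_sizes=kernels,
        paddings=tuple(padding_from_kernel(k) for k in kernels),
        activation="relu", output_activation="identity",
    )


def sample_random_spec(rng_seed: int) -> NetworkSpec:
    """Draw one architecture from the random-search space.

    Hidden-layer count uniform over {1,3,5,7,9,11}; each hidden layer's
    feature count independently uniform over {16,32,48,80}; each weight
    layer's kernel independently uniform over {3,5,7,9,11}; paddings derived
    by the truncation rule; ReLU activations, linear output.
    """
    rng = np.random.default_rng(rng_seed)
    n_hidden = int(rng.choice(RANDOM_HIDDEN_CHOICES))
    maps = tuple(int(m) for m in rng.choice(RANDOM_MAP_CHOICES, size=n_hidden))
    kernels = tuple(int(k) for k in rng.choice(RANDOM_KERNEL_CHOICES, size=n_hidden + 1))
    return NetworkSpec(
        family="cae", n_hidden_layers=n_hidden, feature_maps=maps,
        kernel_sizes=kernels,
        paddings=tuple(padding_from_kernel(k) for k in kernels),
        activation="relu", output_activation="identity",
    )


def build_dae(n_hidden: int, units: int) -> NetworkSpec:
    """Tied-weight dense auto-encoder on vectorized patches.

    The decoder mirrors the encoder: weight layer j >= ceil(L/2) reuses the
    transpose of weight layer L-1-j (L = n_hidden + 1 weight layers), so the
    classic one-hidden-layer case has exactly W and W^T.  Sigmoid throughout.
    """
    if n_hidden % 2 == 0:
        raise ValidationError("dae hidden-layer count must be odd for symmetric tying")
    return NetworkSpec(
        family="dae", n_hidden_layers=n_hidden, units_per_layer=units,
        activation="sigmoid", output_activation="sigmoid", tied=True,
    )
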