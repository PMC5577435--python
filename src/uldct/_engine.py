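"""Minimal numpy forward/backward engine for the DAE and CAE families.

Two execution paths exist for the convolutions:

* ``deterministic=True`` (inference default) runs a compiled direct
  convolution whose per-sample accumulation order is fixed, so results are
  independent of how patches are batched: denoising a slice patch-by-patch
  and in large batches gives bit-identical results.
* ``deterministic=False`` (training default) picks the faster of the direct
  kernel and an im2col GEMM per layer; within a fixed batching scheme it is
  still run-to-run deterministic.

Parameters are plain dicts of float64 arrays.  DAE decoder weights are tied
structurally: one stored matrix serves both its encoder layer and the
mirrored decoder layer, and gradients from both uses accumulate into it.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .exceptions import TrainingError, ValidationError
from .networks import NetworkSpec


# --------------------------------------------------------------------------
# parameter initialization
# --------------------------------------------------------------------------

def init_params(spec: NetworkSpec, seed: int) -> dict[str, np.ndarray]:
    """Fan-in-scaled uniform init; biases start at zero."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    if spec.family == "cae":
        chans = spec.channel_sequence()
        for j, (c_in, c_out, k) in enumerate(zip(chans[:-1], chans[1:], spec.kernel_sizes)):
            bound = 1.0 / np.sqrt(c_in * k * k)
            params[f"W{j}"] = rng.uniform(-bound, bound, size=(c_out, c_in, k, k))
            params[f"b{j}"] = np.zeros(c_out)
    else:
        dims = _dae_dims(spec)
        n_free = (spec.n_hidden_layers + 1) // 2
        for j in range(n_free):
            bound = 1.0 / np.sqrt(dims[j])
            params[f"W{j}"] = rng.uniform(-bound, bound, size=(dims[j + 1], dims[j]))
        for j in range(spec.n_hidden_layers + 1):
            params[f"b{j}"] = np.zeros(dims[j + 1])
    return params


def _dae_dims(spec: NetworkSpec) -> list[int]:
    return [spec.input_dim] + [spec.units_per_layer] * spec.n_hidden_layers + [spec.input_dim]


def _dae_matrix(spec: NetworkSpec, params: dict, j: int) -> np.ndarray:
    """Weight matrix of dense layer j, honouring the mirrored transpose tie."""
    n_weight = spec.n_hidden_layers + 1
    n_free = n_weight // 2
    if j < n_free:
        return params[f"W{j}"]
    return params[f"W{n_weight - 1 - j}"].T


# --------------------------------------------------------------------------
# convolution primitives (channels-last)
#
# Two kernels: a numba direct convolution (wins at small channel counts,
# where im2col is memory-bound) and an im2col GEMM (wins at large ones).

_COL_BUDGET = 16_000_000  # float64 entries per im2col buffer (~128 MB)
_NUMBA_MAX_WORK = 80_000  # use the direct kernel while k*k*c_in*c_out is below this

from numba import njit  # noqa: E402


@njit(cache=True)
def _nb_conv_fwd(xp, W, b, out):  # pragma: no cover - exercised via forward()
    n, _, _, cin = xp.shape
    k = W.shape[0]
    ho, wo, cout = out.shape[1], out.shape[2], out.shape[3]
    for i in range(n):
        for y in range(ho):
            for x in range(wo):
                for co in range(cout):
                    out[i, y, x, co] = b[co]
            for ki in range(k):
                for kj in range(k):
                    for x in range(wo):
                        for ci in range(cin):
                            a = xp[i, y + ki, x + kj, ci]
                            for co in range(cout):
                                out[i, y, x, co] += a * W[ki, kj, ci, co]


@njit(cache=True)
def _nb_conv_bwd(xp, W, dz, dxp, dW, db):  # pragma: no cover
    n, _, _, cin = xp.shape
    k = W.shape[0]
    ho, wo, cout = dz.shape[1], dz.shape[2], dz.shape[3]
    for i in range(n):
        for y in range(ho):
            for x in range(wo):
                for co in range(cout):
                    db[co] += dz[i, y, x, co]
            for ki in range(k):
                for kj in range(k):
                    for x in range(wo):
                        for ci in range(cin):
                            a = xp[i, y + ki, x + kj, ci]
                            acc = 0.0
                            for co in range(cout):
                                d = dz[i, y, x, co]
                                dW[ki, kj, ci, co] += a * d
                                acc += d * W[ki, kj, ci, co]
                            dxp[i, y + ki, x + kj, ci] += acc


def _im2col(xp: np.ndarray, k: int, h_out: int, w_out: int) -> np.ndarray:
    """xp (n, Hp, Wp, C) -> columns (n, h_out, w_out, k*k*C)."""
    n, _, _, c = xp.shape
    cols = np.empty((n, h_out, w_out, k * k * c), dtype=xp.dtype)
    slot = 0
    for ki in range(k):
        for kj in range(k):
            cols[..., slot:slot + c] = xp[:, ki:ki + h_out, kj:kj + w_out, :]
            slot += c
    return cols


def _weight_matrix(W: np.ndarray) -> np.ndarray:
    """(C_out, C_in, k, k) -> (k*k*C_in, C_out) matching _im2col slot order."""
    return W.transpose(2, 3, 1, 0).reshape(-1, W.shape[0])


def _conv2d_fast(x: np.ndarray, W: np.ndarray, b: np.ndarray, padding: int) -> np.ndarray:
    """Channels-last convolution; x (n, H, W, C_in) -> (n, H', W', C_out)."""
    n, h, w, c_in = x.shape
    c_out, _, k, _ = W.shape
    h_out = h + 2 * padding - k + 1
    w_out = w + 2 * padding - k + 1
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    out = np.empty((n, h_out, w_out, c_out), dtype=x.dtype)
    if k * k * c_in * c_out <= _NUMBA_MAX_WORK:
        _nb_conv_fwd(xp, np.ascontiguousarray(W.transpose(2, 3, 1, 0)), b, out)
        return out
    wm = _weight_matrix(W)
    chunk = max(1, _COL_BUDGET // (h_out * w_out * k * k * c_in))
    for s in range(0, n, chunk):
        cols = _im2col(xp[s:s + chunk], k, h_out, w_out)
        out[s:s + chunk] = (cols.reshape(-1, wm.shape[0]) @ wm + b).reshape(
            -1, h_out, w_out, c_out)
    return out


def _conv2d_fast_backward(x: np.ndarray, W: np.ndarray, padding: int,
                          dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, h, w, c_in = x.shape
    c_out, _, k, _ = W.shape
    h_out, w_out = dout.shape[1], dout.shape[2]
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    dxp = np.zeros_like(xp)
    if k * k * c_in * c_out <= _NUMBA_MAX_WORK:
        w_kkio = np.ascontiguousarray(W.transpose(2, 3, 1, 0))
        dw_kkio = np.zeros_like(w_kkio)
        db = np.zeros(c_out)
        _nb_conv_bwd(xp, w_kkio, np.ascontiguousarray(dout), dxp, dw_kkio, db)
        dW = dw_kkio.transpose(3, 2, 0, 1)
    else:
        wm = _weight_matrix(W)
        dwm = np.zeros_like(wm)
        db = dout.sum(axis=(0, 1, 2))
        chunk = max(1, _COL_BUDGET // (h_out * w_out * k * k * c_in))
        for s in range(0, n, chunk):
            cols = _im2col(xp[s:s + chunk], k, h_out, w_out)
            dflat = dout[s:s + chunk].reshape(-1, c_out)
            dwm += cols.reshape(-1, wm.shape[0]).T @ dflat
            dcols = (dflat @ wm.T).reshape(-1, h_out, w_out, k * k, c_in)
            slot = 0
            for ki in range(k):
                for kj in range(k):
                    dxp[s:s + chunk, ki:ki + h_out, kj:kj + w_out, :] += dcols[:, :, :, slot, :]
                    slot += 1
        dW = dwm.reshape(k, k, c_in, c_out).transpose(3, 2, 0, 1)
    if padding:
        dx = dxp[:, padding:padding + h, padding:padding + w, :]
    else:
        dx = dxp
    return dx, dW, db


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return expit(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    return z  # identity


def _activation_grad(a: np.ndarray, kind: str) -> np.ndarray:
    """d(activation)/dz expressed through the activated output a."""
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "relu":
        return (a > 0.0).astype(a.dtype)
    return np.ones_like(a)


# --------------------------------------------------------------------------
# forward / backward per family
# --------------------------------------------------------------------------

def _conv2d_batch_invariant(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                            padding: int) -> np.ndarray:
    """Direct compiled convolution: per-sample fixed accumulation order.

    Results are bitwise independent of how samples are grouped into batches,
    which the overlap-averaging oracle equivalence relies on.
    """
    n, h, w, c_in = x.shape
    c_out, _, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    out = np.empty((n, h + 2 * padding - k + 1, w + 2 * padding - k + 1, c_out),
                   dtype=x.dtype)
    _nb_conv_fwd(xp, np.ascontiguousarray(W.transpose(2, 3, 1, 0)), b, out)
    return out


def _forward_cae(spec: NetworkSpec, params: dict, batch: np.ndarray,
                 deterministic: bool, want_cache: bool):
    # Channels-last throughout; the deterministic flag selects the
    # batch-invariant direct kernel over the per-layer fastest kernel.
    a = batch[:, :, :, None]
    inputs = []
    acts = []
    conv = _conv2d_batch_invariant if deterministic else _conv2d_fast
    n_weight = spec.n_weight_layers
    for j in range(n_weight):
        inputs.append(a)
        z = conv(a, params[f"W{j}"], params[f"b{j}"], spec.paddings[j])
        kind = spec.activation if j < n_weight - 1 else spec.output_activation
        a = _activate(z, kind)
        acts.append(a)
    out = a[:, :, :, 0]
    if want_cache:
        return out, {"inputs": inputs, "acts": acts}
    return out, None


def _backward_cae(spec: NetworkSpec, params: dict, cache: dict, dout: np.ndarray) -> dict:
    grads: dict[str, np.ndarray] = {}
    d = dout[:, :, :, None]
    n_weight = spec.n_weight_layers
    for j in reversed(range(n_weight)):
        kind = spec.activation if j < n_weight - 1 else spec.output_activation
        dz = d * _activation_grad(cache["acts"][j], kind)
        d, dW, db = _conv2d_fast_backward(cache["inputs"][j], params[f"W{j}"],
                                          spec.paddings[j], dz)
        grads[f"W{j}"] = dW
        grads[f"b{j}"] = db
    return grads


def _forward_dae(spec: NetworkSpec, params: dict, batch: np.ndarray,
                 want_cache: bool):
    n = batch.shape[0]
    a = batch.reshape(n, -1)
    inputs, acts = [], []
    n_weight = spec.n_hidden_layers + 1
    for j in range(n_weight):
        inputs.append(a)
        z = a @ _dae_matrix(spec, params, j).T + params[f"b{j}"]
        kind = spec.activation if j < n_weight - 1 else spec.output_activation
        a = _activate(z, kind)
        acts.append(a)
    out = a.reshape(n, spec.input_side, spec.input_side)
    if want_cache:
        return out, {"inputs": inputs, "acts": acts}
    return out, None


def _backward_dae(spec: NetworkSpec, params: dict, cache: dict, dout: np.ndarray) -> dict:
    n = dout.shape[0]
    d = dout.reshape(n, -1)
    n_weight = spec.n_hidden_layers + 1
    n_free = n_weight // 2
    grads = {key: np.zeros_like(val) for key, val in params.items()}
    for j in reversed(range(n_weight)):
        kind = spec.activation if j < n_weight - 1 else spec.output_activation
        dz = d * _activation_grad(cache["acts"][j], kind)
        a_in = cache["inputs"][j]
        dM = dz.T @ a_in  # gradient wrt the layer matrix (d_out, d_in)
        if j < n_free:
            grads[f"W{j}"] += dM
        else:
            grads[f"W{n_weight - 1 - j}"] += dM.T
        grads[f"b{j}"] += dz.sum(axis=0)
        d = dz @ _dae_matrix(spec, params, j)
    return grads


# --------------------------------------------------------------------------
# public forward
# --------------------------------------------------------------------------

def forward(spec: NetworkSpec, params: dict, batch: np.ndarray,
            deterministic: bool = True, clip: bool = True,
            want_cache: bool = False):
    """Reconstruct a batch of normalized patches.

    ``batch`` has shape (n, side, side) with values in [0, 1].  Networks with
    an identity output have their result clipped back to [0, 1] when
    ``clip=True`` (sigmoid outputs already lie in (0, 1)).
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 3 or batch.shape[1] != spec.input_side or batch.shape[2] != spec.input_side:
        raise ValidationError(
            f"batch must be (n, {spec.input_side}, {spec.input_side}); got {batch.shape}")
    if spec.family == "cae":
        out, cache = _forward_cae(spec, params, batch, deterministic, want_cache)
    else:
        out, cache = _forward_dae(spec, params, batch, want_cache)
    if clip and spec.output_activation == "identity":
        out = np.clip(out, 0.0, 1.0)
    if want_cache:
        return out, cache
    return out


def backward(spec: NetworkSpec, params: dict, cache: dict, dout: np.ndarray) -> dict:
    if spec.family == "cae":
        return _backward_cae(spec, params, cache, dout)
    return _backward_dae(spec, params, cache, dout)


def loss_and_grads(spec: NetworkSpec, params: dict, x: np.ndarray, y: np.ndarray,
                   deterministic: bool = False) -> tuple[float, dict]:
    """MSE between targets ``x`` and reconstruction of ``y``, with gradients.

    The training loss uses the raw (unclipped) network output so gradients
    are never zeroed by the inference clip.
    """
    out, cache = forward(spec, params, y, deterministic=deterministic,
                         clip=False, want_cache=True)
    diff = out - x
    loss = float(np.mean(diff ** 2))
    if not np.isfinite(loss):
        raise TrainingError("loss diverged to a non-finite value")
    dout = (2.0 / diff.size) * diff
    return loss, backward(spec, params, cache, dout)


class Adam:
    """Adaptive-moment optimizer with standard bias correction."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.beta2 ** self.t) / (1.0 - self.beta1 ** self.t)
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            params[key] -= lr_t * self.m[key] / (np.sqrt(self.v[key]) + self.eps)


class SGD:
    """Plain mini-batch gradient descent (kept for ablations)."""

    def __init__(self, params: dict, lr: float = 1e-2) -> None:
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for key, g in grads.items():
            params[key] -= self.lr * g


OPTIMIZERS = {"adam": Adam, "sgd": SGD}
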