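"""Model/Results interface for patch denoisers.

:class:`PatchDenoiser` binds an architecture to a paired patch dataset, in the
spirit of statsmodels model classes; calling :meth:`PatchDenoiser.fit` runs
seeded mini-batch optimization of the reconstruction MSE and returns a
:class:`DenoisingResults` carrying the selected weights (the epoch with the
lowest validation MSE), the full per-epoch validation history, and enough
provenance (seed, config) to reproduce the fit bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import _engine
from .exceptions import ValidationError
from .networks import NetworkSpec
from .preprocess import PatchDataset


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (these are artifact choices, surfaced in provenance)."""

    batch_size: int = 64
    epochs: int = 30
    optimizer: str = "adam"
    learning_rate: float = 1e-2
    rng_seed: int = 0
    patience: int | None = None  # early stop after this many non-improving epochs
    val_batch_size: int = 1024

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if self.optimizer not in _engine.OPTIMIZERS:
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


class PatchDenoiser:
    """A denoising network family bound to a paired patch dataset."""

    def __init__(self, dataset: PatchDataset, spec: NetworkSpec) -> None:
        if dataset.patch_size != spec.input_side:
            raise ValidationError(
                f"dataset patch size {dataset.patch_size} != spec input side {spec.input_side}")
        if dataset.n_train == 0 or dataset.n_val == 0:
            raise ValidationError("dataset must have non-empty train and validation splits")
        self.dataset = dataset
        self.spec = spec

    def fit(self, config: TrainConfig | None = None) -> "DenoisingResults":
        """Seeded mini-batch training; returns the best-validation-epoch model."""
        cfg = config or TrainConfig()
        ds, spec = self.dataset, self.spec
        seed_seq = np.random.SeedSequence(entropy=cfg.rng_seed)
        init_seed = int(seed_seq.generate_state(2)[0] % (2 ** 31))
        params = _engine.init_params(spec, init_seed)
        opt = _engine.OPTIMIZERS[cfg.optimizer](params, lr=cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.rng_seed, spawn_key=(1,)))

        history: list[float] = []
        train_losses: list[float] = []
        best = {"mse": np.inf, "epoch": -1, "params": None}
        stale = 0
        n = ds.n_train
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = _engine.loss_and_grads(
                    spec, params, ds.x_train[idx], ds.y_train[idx])
                opt.step(params, grads)
                epoch_loss += loss * idx.size
            train_losses.append(epoch_loss / n)
            val_mse = _validation_mse(spec, params, ds, cfg.val_batch_size)
            history.append(val_mse)
            if val_mse < best["mse"]:
                best = {"mse": val_mse, "epoch": epoch,
                        "params": {k: v.copy() for k, v in params.items()}}
                stale = 0
            else:
                stale += 1
                if cfg.patience is not None and stale > cfg.patience:
                    break
        return DenoisingResults(
            spec=spec, params=best["params"], history=np.asarray(history),
            train_history=np.asarray(train_losses), best_epoch=int(best["epoch"]),
            best_val_mse=float(best["mse"]), config=cfg, seed=cfg.rng_seed,
        )


def _validation_mse(spec: NetworkSpec, params: dict, ds: PatchDataset,
                    batch: int) -> float:
    """Validation MSE with the inference-time output convention (clipped)."""
    total, n = 0.0, ds.n_val
    for start in range(0, n, batch):
        out = _engine.forward(spec, params, ds.y_val[start:start + batch],
                              deterministic=False, clip=True)
        total += float(np.sum((out - ds.x_val[start:start + batch]) ** 2))
    return total / (n * spec.input_side ** 2)


@dataclass
class DenoisingResults:
    """Fitted denoiser: selected weights, validation history, provenance."""

    spec: NetworkSpec
    params: dict[str, np.ndarray]
    history: np.ndarray
    train_history: np.ndarray
    best_epoch: int
    best_val_mse: float
    config: TrainConfig
    seed: int
    meta: dict = field(default_factory=dict)

    # -------------------------------------------------------------- predict
    def predict(self, batch: np.ndarray, deterministic: bool = True) -> np.ndarray:
        """Reconstruct normalized patches (clipped to [0, 1])."""
        return _engine.forward(self.spec, self.params, batch,
                               deterministic=deterministic, clip=True)

    def validation_mse(self, dataset: PatchDataset) -> float:
        """Recompute validation MSE from stored weights (round-trip audit)."""
        return _validation_mse(self.spec, self.params, dataset,
                               self.config.val_batch_size)

    def denoise_slice(self, hu_slice, config=None):
        from .inference import denoise_slice
        return denoise_slice(self, hu_slice, config)

    def denoise_volume(self, volume, config=None):
        from .inference import denoise_volume
        return denoise_volume(self, volume, config)

    # ------------------------------------------------------------- reporting
    def checksum(self) -> str:
        digest = hashlib.sha256()
        for key in sorted(self.params):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.params[key]).tobytes())
        return digest.hexdigest()

    def summary(self) -> str:
        s = self.spec
        arch = (f"hidden={s.n_hidden_layers}, maps={list(s.feature_maps)}, "
                f"kernels={list(s.kernel_sizes)}, paddings={list(s.paddings)}"
                if s.family == "cae" else
                f"hidden={s.n_hidden_layers}, units={s.units_per_layer}, tied={s.tied}")
        lines = [
            "Patch denoiser results",
            "=" * 58,
            f"family:             {s.family}",
            f"architecture:       {arch}",
            f"activation:         {s.activation} / output {s.output_activation}",
            f"free parameters:    {s.n_parameters()}",
            f"epochs run:         {len(self.history)}",
            f"best epoch:         {self.best_epoch}",
            f"best val MSE:       {self.best_val_mse:.6g}",
            f"final train MSE:    {self.train_history[-1]:.6g}",
            f"seed:               {self.seed}",
            f"weights sha256:     {self.checksum()[:16]}…",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Per-epoch train/validation MSE curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(len(self.history))
        ax.plot(epochs, self.train_history, label="train MSE")
        ax.plot(epochs, self.history, label="validation MSE")
        ax.axvline(self.best_epoch, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (normalized units)")
        ax.legend()
        return ax

    # ----------------------------------------------------------------- I/O
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["spec"] = self.spec.to_json()
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["best_epoch"] = self.best_epoch
            f.attrs["best_val_mse"] = self.best_val_mse
            f.attrs["seed"] = self.seed
            f.create_dataset("history", data=self.history)
            f.create_dataset("train_history", data=self.train_history)
            g = f.create_group("params")
            for key, val in self.params.items():
                g.create_dataset(key, data=val)

    @classmethod
    def load(cls, path: str) -> "DenoisingResults":
        with h5py.File(path, "r") as f:
            cfg_payload = json.loads(f.attrs["config"])
            if cfg_payload.get("patience") is not None:
                cfg_payload["patience"] = int(cfg_payload["patience"])
            return cls(
                spec=NetworkSpec.from_json(f.attrs["spec"]),
                params={k: f["params"][k][...] for k in f["params"]},
                history=f["history"][...],
                train_history=f["train_history"][...],
                best_epoch=int(f.attrs["best_epoch"]),
                best_val_mse=float(f.attrs["best_val_mse"]),
                config=TrainConfig(**cfg_payload),
                seed=int(f.attrs["seed"]),
            )


def make_identity_model(kernel: int = 3) -> DenoisingResults:
    """A CAE whose convolutions are centred delta kernels: a perfect identity.

    Useful for exercising the patch-reassembly plumbing independently of any
    training: with ReLU hidden activation and a linear output, non-negative
    normalized inputs pass through unchanged.
    """
    from .networks import padding_from_kernel

    pad = padding_from_kernel(kernel)
    spec = NetworkSpec(
        family="cae", n_hidden_layers=1, feature_maps=(1,),
        kernel_sizes=(kernel, kernel), paddings=(pad, pad),
        activation="relu", output_activation="identity",
    )
    params = {}
    for j in range(2):
        w = np.zeros((1, 1, kernel, kernel))
        w[0, 0, pad, pad] = 1.0
        params[f"W{j}"] = w
        params[f"b{j}"] = np.zeros(1)
    return DenoisingResults(
        spec=spec, params=params, history=np.array([0.0]),
        train_history=np.array([0.0]), best_epoch=0, best_val_mse=0.0,
        config=TrainConfig(epochs=1), seed=0, meta={"identity": True},
    )


def make_constant_model(value: float = 0.5) -> DenoisingResults:
    """A CAE that outputs a constant patch regardless of input (test fixture)."""
    spec = NetworkSpec(
        family="cae", n_hidden_layers=1, feature_maps=(1,),
        kernel_sizes=(3, 3), paddings=(1, 1),
        activation="relu", output_activation="identity",
    )
    params = {
        "W0": np.zeros((1, 1, 3, 3)), "b0": np.zeros(1),
        "W1": np.zeros((1, 1, 3, 3)), "b1": np.full(1, float(value)),
    }
    return DenoisingResults(
        spec=spec, params=params, history=np.array([0.0]),
        train_history=np.array([0.0]), best_epoch=0, best_val_mse=0.0,
        config=TrainConfig(epochs=1), seed=0, meta={"constant": value},
    )
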