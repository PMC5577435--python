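"""Training entry points and architecture searches.

The contract of every search is the one the validation set defines: train
each candidate with a shared, seeded policy, score it by its best validation
MSE, and return the candidates ranked (ties broken by fewer free parameters,
then enumeration order).  The absolute MSE values depend entirely on the data
the searches are run on; only the ordering and the beats-the-no-op-baseline
property are portable claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .exceptions import TrainingError, ValidationError
from .model import DenoisingResults, PatchDenoiser, TrainConfig
from .networks import NetworkSpec, build_cae, sample_random_spec
from .preprocess import PatchDataset

log = logging.getLogger(__name__)

GRID_LAYER_CHOICES = (1, 3, 5, 7, 9, 11)
GRID_MAP_CHOICES = (20, 30, 40)


def mse(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean squared error over all patches and pixels."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValidationError(f"mse: shape mismatch {x.shape} vs {x_prime.shape}")
    return float(np.mean((x - x_prime) ** 2))


def baseline_mse(dataset: PatchDataset, split: str = "val") -> float:
    """MSE between the clean and noisy patches themselves.

    This is the score of the no-op denoiser — the bar any trained model must
    beat for the training to have been worthwhile.
    """
    x, y = dataset.split(split)
    if x.shape[0] == 0:
        raise ValidationError(f"baseline_mse: empty split {split!r}")
    return mse(x, y)


def train(spec: NetworkSpec, dataset: PatchDataset,
          config: TrainConfig | None = None) -> DenoisingResults:
    """Fit one architecture on the dataset (see :class:`PatchDenoiser`)."""
    return PatchDenoiser(dataset, spec).fit(config)


@dataclass
class SearchResult:
    """Ranked outcome of an architecture search."""

    entries: list[dict] = field(default_factory=list)  # spec, result, order index

    def add(self, spec: NetworkSpec, result: DenoisingResults | None,
            index: int, error: str | None = None) -> None:
        self.entries.append({"spec": spec, "result": result, "index": index,
                             "error": error})

    @property
    def ranked(self) -> list[dict]:
        ok = [e for e in self.entries if e["result"] is not None]
        return sorted(ok, key=lambda e: (e["result"].best_val_mse,
                                         e["spec"].n_parameters(), e["index"]))

    @property
    def winner(self) -> DenoisingResults:
        ranked = self.ranked
        if not ranked:
            raise TrainingError("search produced no successful trials")
        return ranked[0]["result"]

    @property
    def winner_spec(self) -> NetworkSpec:
        return self.ranked[0]["spec"]

    def summary(self) -> str:
        lines = ["rank  val_mse      params    architecture"]
        for rank, e in enumerate(self.ranked, 1):
            s = e["spec"]
            arch = (f"{s.family} h={s.n_hidden_layers} maps={list(s.feature_maps)} "
                    f"k={list(s.kernel_sizes)}")
            lines.append(f"{rank:>4}  {e['result'].best_val_mse:<11.6g} "
                         f"{s.n_parameters():<9} {arch}")
        failed = [e for e in self.entries if e["result"] is None]
        if failed:
            lines.append(f"({len(failed)} failed trials omitted)")
        return "\n".join(lines)


def grid_search(dataset: PatchDataset,
                layer_grid=GRID_LAYER_CHOICES, map_grid=GRID_MAP_CHOICES,
                config: TrainConfig | None = None) -> SearchResult:
    """Exhaustive search over (hidden layers) x (feature maps) CAE cells.

    Every cell trains with the same seeded config, so cells differ only in
    architecture.  Training errors are re-raised annotated with the cell.
    """
    if not layer_grid or not map_grid:
        raise ValidationError("grid_search: grids must be nonempty")
    cfg = config or TrainConfig()
    out = SearchResult()
    for index, (n_hidden, n_maps) in enumerate(product(layer_grid, map_grid)):
        spec = build_cae(n_hidden, n_maps)
        try:
            result = train(spec, dataset, cfg)
        except TrainingError as exc:
            raise TrainingError(
                f"grid cell (layers={n_hidden}, maps={n_maps}) failed: {exc}") from exc
        log.info("grid cell layers=%d maps=%d: best val MSE %.6g",
                 n_hidden, n_maps, result.best_val_mse)
        out.add(spec, result, index)
    return out


def trial_seed(master_seed: int, trial: int) -> int:
    """Per-trial seed derived from the master seed (independent, reproducible)."""
    return int(np.random.SeedSequence(entropy=int(master_seed),
                                      spawn_key=(int(trial),)).generate_state(1)[0]
               % (2 ** 31))


def random_search(dataset: PatchDataset, n_trials: int = 100,
                  config: TrainConfig | None = None,
                  master_seed: int = 0) -> SearchResult:
    """Random architecture search over the CAE space.

    Each trial draws an architecture (hidden layers, per-layer feature maps,
    per-layer kernels) with a seed derived from ``master_seed`` and trains it;
    individual failures are logged and skipped so the search always finishes.
    """
    if n_trials < 1:
        raise ValidationError("random_search: n_trials must be >= 1")
    cfg = config or TrainConfig()
    out = SearchResult()
    for trial in range(n_trials):
        seed = trial_seed(master_seed, trial)
        spec = sample_random_spec(seed)
        try:
            result = train(spec, dataset, replace(cfg, rng_seed=seed))
        except TrainingError as exc:
            log.warning("random-search trial %d failed: %s", trial, exc)
            out.add(spec, None, trial, error=str(exc))
            continue
        log.info("trial %d: h=%d maps=%s k=%s -> best val MSE %.6g",
                 trial, spec.n_hidden_layers, spec.feature_maps,
                 spec.kernel_sizes, result.best_val_mse)
        out.add(spec, result, trial)
    return out
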