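"""Training loop, model selection, and the architecture searches."""

import numpy as np
import pytest

from conftest import make_synthetic_patchset
from uldct.exceptions import ValidationError
from uldct.model import PatchDenoiser, TrainConfig
from uldct.networks import (RANDOM_HIDDEN_CHOICES, RANDOM_KERNEL_CHOICES,
                            RANDOM_MAP_CHOICES, build_cae, build_dae)
from uldct.training import (baseline_mse, grid_search, mse, random_search,
                            train, trial_seed)

FAST = TrainConfig(epochs=2, batch_size=50, rng_seed=0)


class TestMse:
    def test_identical_is_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (5, 28, 28))
        assert mse(x, x) == 0.0

    def test_unit_offset(self):
        assert mse(np.zeros((2, 4, 4)), np.ones((2, 4, 4))) == 1.0

    def test_half_offset(self):
        x = np.random.default_rng(1).uniform(0, 0.5, (3, 4, 4))
        assert mse(x, x + 0.5) == pytest.approx(0.25)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, (2, 6, 6)), rng.uniform(0, 1, (2, 6, 6))
        assert mse(a, b) == mse(b, a) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mse(np.zeros((1, 4, 4)), np.zeros((2, 4, 4)))


class TestBaseline:
    def test_clean_pairs_score_zero(self):
        ds = make_synthetic_patchset(noise=0.0)
        assert baseline_mse(ds, "val") == 0.0

    def test_constant_shift_scores_shift_squared(self):
        ds = make_synthetic_patchset(shift=0.1)
        assert baseline_mse(ds, "train") == pytest.approx(0.01, rel=1e-9)

    def test_noisy_pairs_score_positive(self):
        ds = make_synthetic_patchset(noise=0.05)
        assert baseline_mse(ds, "val") > 0.0

    def test_unknown_split_rejected(self):
        with pytest.raises(ValidationError):
            baseline_mse(make_synthetic_patchset(), "test")


class TestTrain:
    def test_full_determinism_contract(self):
        ds = make_synthetic_patchset(seed=3)
        spec = build_cae(1, 3)
        a = train(spec, ds, FAST)
        b = train(spec, ds, FAST)
        assert a.best_val_mse == b.best_val_mse
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)
        assert np.array_equal(a.history, b.history)

    def test_identity_task_is_learnable(self):
        """With y = x the reconstruction error falls toward zero."""
        ds = make_synthetic_patchset(noise=0.0, n_train=300, seed=4)
        short = train(build_cae(1, 4), ds, TrainConfig(epochs=10, rng_seed=1))
        longer = train(build_cae(1, 4), ds, TrainConfig(epochs=30, rng_seed=1))
        assert longer.best_val_mse < short.best_val_mse
        assert longer.best_val_mse < 1e-3

    def test_best_epoch_snapshot_selected(self):
        ds = make_synthetic_patchset(seed=5)
        res = train(build_cae(1, 3), ds, TrainConfig(epochs=4, rng_seed=2))
        assert res.best_val_mse == res.history.min()
        assert res.history[res.best_epoch] == res.best_val_mse

    def test_round_trip_validation_mse(self, tmp_path):
        """Stored weights reproduce the reported score after serialization."""
        from uldct.model import DenoisingResults

        ds = make_synthetic_patchset(seed=6)
        res = train(build_cae(1, 3), ds, FAST)
        path = str(tmp_path / "model.h5")
        res.save(path)
        back = DenoisingResults.load(path)
        assert back.validation_mse(ds) == pytest.approx(res.best_val_mse, rel=1e-12)
        assert back.spec == res.spec
        assert back.checksum() == res.checksum()

    def test_dae_trains_too(self):
        ds = make_synthetic_patchset(noise=0.0, seed=7)
        res = train(build_dae(1, 32), ds, TrainConfig(epochs=5, rng_seed=3))
        assert res.history[-1] < res.history[0]
        # tying survives training: the engine stores only the free matrix
        assert set(k for k in res.params if k.startswith("W")) == {"W0"}

    def test_patch_size_mismatch_rejected(self):
        ds = make_synthetic_patchset(patch_size=16)
        with pytest.raises(ValidationError):
            PatchDenoiser(ds, build_cae(1, 3))

    def test_summary_mentions_key_facts(self):
        ds = make_synthetic_patchset(seed=8)
        res = train(build_cae(1, 3), ds, FAST)
        text = res.summary()
        assert "best val MSE" in text and "cae" in text


class TestGridSearch:
    def test_scaled_down_grid_contract(self):
        ds = make_synthetic_patchset(noise=0.05, n_train=300, seed=9)
        cfg = TrainConfig(epochs=3, rng_seed=4)
        result = grid_search(ds, layer_grid=(1, 3), map_grid=(2, 4), config=cfg)
        assert len(result.entries) == 4
        scores = [e["result"].best_val_mse for e in result.entries]
        assert all(s >= 0.0 for s in scores)
        assert result.winner.best_val_mse == min(scores)
        # the winner is an element of the Cartesian grid
        assert result.winner_spec.n_hidden_layers in (1, 3)
        assert result.winner_spec.feature_maps[0] in (2, 4)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            grid_search(make_synthetic_patchset(), layer_grid=(), map_grid=(8,))


class TestRandomSearch:
    def test_reruns_are_bit_identical(self):
        ds = make_synthetic_patchset(n_train=100, n_val=30, seed=10)
        cfg = TrainConfig(epochs=1, batch_size=50, rng_seed=0)
        a = random_search(ds, n_trials=2, config=cfg, master_seed=1)
        b = random_search(ds, n_trials=2, config=cfg, master_seed=1)
        assert [e["spec"] for e in a.entries] == [e["spec"] for e in b.entries]
        assert a.winner.best_val_mse == b.winner.best_val_mse
        assert all(np.array_equal(a.winner.params[k], b.winner.params[k])
                   for k in a.winner.params)

    def test_sampled_specs_in_support_and_winner_is_argmin(self):
        ds = make_synthetic_patchset(n_train=100, n_val=30, seed=11)
        cfg = TrainConfig(epochs=1, batch_size=50, rng_seed=0)
        result = random_search(ds, n_trials=3, config=cfg, master_seed=1)
        for e in result.entries:
            spec = e["spec"]
            assert spec.n_hidden_layers in RANDOM_HIDDEN_CHOICES
            assert all(m in RANDOM_MAP_CHOICES for m in spec.feature_maps)
            assert all(k in RANDOM_KERNEL_CHOICES for k in spec.kernel_sizes)
        scores = [e["result"].best_val_mse for e in result.entries]
        assert result.winner.best_val_mse == min(scores)

    def test_trial_seeds_are_distinct_and_reproducible(self):
        seeds = [trial_seed(42, t) for t in range(10)]
        assert len(set(seeds)) == 10
        assert seeds == [trial_seed(42, t) for t in range(10)]
        assert all(0 <= s < 2 ** 31 for s in seeds)
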