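"""End-to-end orchestration: simulate -> extract -> train/search -> denoise -> evaluate.

A single JSON config drives the whole workflow.  Every stage writes its
artifacts plus a :class:`RunManifest` next to them; a stage whose artifacts
already exist with a matching config hash is skipped, so interrupted runs
resume from cache.  Unknown config keys are rejected before any compute.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dose import DoseSimSpec, make_paired_study
from .evaluation import MetricsReport, NlmParams, evaluate_study, nlm_denoise, segment_lungs
from .exceptions import ValidationError
from .inference import DenoiseConfig, denoise_volume
from .model import DenoisingResults, TrainConfig
from .networks import build_cae
from .phantom import PhantomSpec
from .preprocess import PatchDataset, extract_paired_patches
from .training import baseline_mse, grid_search, random_search, train
from .volume import CTVolume, LungMask

log = logging.getLogger(__name__)

PACKAGE_VERSION = "0.1.0"

_SCHEMA: dict[str, dict] = {
    "schema_version": None,
    "out_dir": None,
    "simulate": {"image_side", "n_slices", "phantom_seed", "sdct_mA", "uldct_mA",
                 "seed_sdct", "seed_train", "seed_test", "n_projection_angles",
                 "i0_reference"},
    "patches": {"n_train", "n_val", "patch_size", "seed"},
    "train": {"mode", "n_hidden", "n_maps", "epochs", "batch_size",
              "learning_rate", "seed", "trials", "layer_grid", "map_grid"},
    "denoise": {"stride", "batch_size"},
    "evaluate": {"include_nlm", "nlm_h", "nlm_search", "nlm_patch"},
}


def validate_config(config: dict) -> dict:
    """Schema check: reject unknown keys, require the simulate stage, fail fast."""
    for key in config:
        if key not in _SCHEMA:
            raise ValidationError(f"unknown config key {key!r}")
        allowed = _SCHEMA[key]
        if allowed is not None:
            if not isinstance(config[key], dict):
                raise ValidationError(f"config section {key!r} must be an object")
            for sub in config[key]:
                raise_unknown = sub not in allowed
                if raise_unknown:
                    raise ValidationError(f"unknown config key {key}.{sub}")
    if "out_dir" not in config:
        raise ValidationError("config must define out_dir")
    sim = config.get("simulate", {})
    seeds = [sim.get("seed_sdct", 1), sim.get("seed_train", 2), sim.get("seed_test", 3)]
    if len(set(seeds)) != 3:
        raise ValidationError("simulation seeds must be distinct")
    return config


def _sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every stage's artifacts."""

    command: str
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""
    package_version: str = PACKAGE_VERSION

    def write(self, path: Path) -> None:
        self.timestamp = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=str)


def _stage_fresh(out_dir: Path, stage: str, payload: dict, artifacts: list[Path]) -> bool:
    """True when cached artifacts for this stage match the current config."""
    manifest = out_dir / f"{stage}.manifest.json"
    if not manifest.exists() or not all(a.exists() for a in artifacts):
        return False
    try:
        recorded = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return recorded.get("config", {}).get("hash") == _config_hash(payload)


def _write_stage_manifest(out_dir: Path, stage: str, payload: dict,
                          artifacts: list[Path], seeds: dict) -> None:
    manifest = RunManifest(
        command=stage,
        config={"hash": _config_hash(payload), "payload": payload},
        seeds=seeds,
        outputs={a.name: _sha256_file(a) for a in artifacts},
    )
    manifest.write(out_dir / f"{stage}.manifest.json")


def run_pipeline(config_path: str) -> MetricsReport:
    """Execute the full study described by a JSON config file."""
    config = validate_config(json.loads(Path(config_path).read_text()))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------------- simulate
    sim = dict(config.get("simulate", {}))
    sim_payload = {"stage": "simulate", **sim}
    vol_paths = {name: out_dir / f"{name}.nii.gz"
                 for name in ("sdct", "uldct_train", "uldct_test", "lung_mask", "ground_truth")}
    if not _stage_fresh(out_dir, "simulate", sim_payload, list(vol_paths.values())):
        log.info("stage simulate: running")
        spec = PhantomSpec(image_side=sim.get("image_side", 256),
                           n_slices=sim.get("n_slices", 3),
                           rng_seed=sim.get("phantom_seed", 0))
        dose_kwargs = {}
        if "n_projection_angles" in sim:
            dose_kwargs["n_projection_angles"] = sim["n_projection_angles"]
        if "i0_reference" in sim:
            dose_kwargs["i0_reference"] = sim["i0_reference"]
        dose_sd = DoseSimSpec(tube_current_mA=sim.get("sdct_mA", 300.0), **dose_kwargs)
        dose_uld = DoseSimSpec(tube_current_mA=sim.get("uldct_mA", 10.0), **dose_kwargs)
        seeds = (sim.get("seed_sdct", 1), sim.get("seed_train", 2), sim.get("seed_test", 3))
        sdct, uldct_train, uldct_test, mask, truth = make_paired_study(
            spec, dose_sd, dose_uld, seeds)
        sdct.to_nifti(str(vol_paths["sdct"]))
        uldct_train.to_nifti(str(vol_paths["uldct_train"]))
        uldct_test.to_nifti(str(vol_paths["uldct_test"]))
        truth.to_nifti(str(vol_paths["ground_truth"]))
        mask.to_nifti(str(vol_paths["lung_mask"]))
        _write_stage_manifest(out_dir, "simulate", sim_payload, list(vol_paths.values()),
                              {"phantom": spec.rng_seed, "volumes": list(seeds)})
    sdct = CTVolume.from_nifti(str(vol_paths["sdct"]), kind="sdct")
    uldct_train = CTVolume.from_nifti(str(vol_paths["uldct_train"]), kind="uldct_train")
    uldct_test = CTVolume.from_nifti(str(vol_paths["uldct_test"]), kind="uldct_test")
    mask = LungMask.from_nifti(str(vol_paths["lung_mask"]))

    # ---------------------------------------------------------------- patches
    pat = dict(config.get("patches", {}))
    pat_payload = {"stage": "patches", **pat, "sim_hash": _config_hash(sim_payload)}
    patches_path = out_dir / "patches.h5"
    if not _stage_fresh(out_dir, "patches", pat_payload, [patches_path]):
        log.info("stage patches: running")
        dataset = extract_paired_patches(
            sdct, uldct_train, mask,
            n_train=pat.get("n_train", 5000), n_val=pat.get("n_val", 1000),
            patch_size=pat.get("patch_size", 28), seed=pat.get("seed", 0))
        dataset.to_hdf5(str(patches_path))
        _write_stage_manifest(out_dir, "patches", pat_payload, [patches_path],
                              {"extraction": pat.get("seed", 0)})
    dataset = PatchDataset.from_hdf5(str(patches_path))
    log.info("baseline (no-op) validation MSE: %.6g", baseline_mse(dataset, "val"))

    # ---------------------------------------------------------------- train
    tr = dict(config.get("train", {}))
    tr_payload = {"stage": "train", **tr, "patches_hash": _config_hash(pat_payload)}
    model_path = out_dir / "model.h5"
    if not _stage_fresh(out_dir, "train", tr_payload, [model_path]):
        log.info("stage train: running (mode=%s)", tr.get("mode", "single"))
        cfg = TrainConfig(batch_size=tr.get("batch_size", 128),
                          epochs=tr.get("epochs", 30),
                          learning_rate=tr.get("learning_rate", 1e-3),
                          rng_seed=tr.get("seed", 0))
        mode = tr.get("mode", "single")
        if mode == "single":
            result = train(build_cae(tr.get("n_hidden", 3), tr.get("n_maps", 8)),
                           dataset, cfg)
        elif mode == "grid":
            result = grid_search(dataset, tuple(tr.get("layer_grid", (1, 3))),
                                 tuple(tr.get("map_grid", (8, 16))), cfg).winner
        elif mode == "random":
            result = random_search(dataset, n_trials=tr.get("trials", 5),
                                   config=cfg, master_seed=tr.get("seed", 0)).winner
        else:
            raise ValidationError(f"unknown train mode {mode!r}")
        result.save(str(model_path))
        _write_stage_manifest(out_dir, "train", tr_payload, [model_path],
                              {"training": tr.get("seed", 0)})
    result = DenoisingResults.load(str(model_path))
    log.info("trained model: best val MSE %.6g (epoch %d)",
             result.best_val_mse, result.best_epoch)

    # ---------------------------------------------------------------- denoise
    dn = dict(config.get("denoise", {}))
    dn_payload = {"stage": "denoise", **dn, "train_hash": _config_hash(tr_payload)}
    denoised_path = out_dir / "denoised.nii.gz"
    if not _stage_fresh(out_dir, "denoise", dn_payload, [denoised_path]):
        log.info("stage denoise: running")
        cfg = DenoiseConfig(patch_size=result.spec.input_side,
                            stride=dn.get("stride", 1),
                            batch_size=dn.get("batch_size", 1024))
        denoised = denoise_volume(result, uldct_test, cfg)
        denoised.to_nifti(str(denoised_path))
        _write_stage_manifest(out_dir, "denoise", dn_payload, [denoised_path], {})
    denoised = CTVolume.from_nifti(str(denoised_path), kind="denoised")

    # ---------------------------------------------------------------- evaluate
    ev = dict(config.get("evaluate", {}))
    seg_mask = segment_lungs(sdct)
    candidates = {"undenoised": uldct_test, "cae": denoised}
    if ev.get("include_nlm", False):
        params = NlmParams(patch_side=ev.get("nlm_patch", 11),
                           search_side=ev.get("nlm_search", 41),
                           h=ev.get("nlm_h", 0.02))
        nlm_voxels = np.stack([nlm_denoise(uldct_test.voxels[s], params)
                               for s in range(uldct_test.n_slices)])
        candidates[f"nlm_h{params.h}"] = uldct_test.with_voxels(nlm_voxels, kind="denoised")
    report = evaluate_study(sdct, candidates, seg_mask)
    report.metadata["segmentation"] = {"threshold_hu": LUNG_SEG_THRESHOLD,
                                       "closing_radius": 3}
    report.to_csv(str(out_dir / "metrics.csv"))
    report.to_json(str(out_dir / "metrics.json"))
    ev_payload = {"stage": "evaluate", **ev, "denoise_hash": _config_hash(dn_payload)}
    _write_stage_manifest(out_dir, "evaluate", ev_payload,
                          [out_dir / "metrics.csv", out_dir / "metrics.json"], {})
    return report


LUNG_SEG_THRESHOLD = -500.0
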