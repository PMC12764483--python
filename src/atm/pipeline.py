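"""End-to-end orchestration: phantom -> train -> generate -> postprocess -> evaluate.

A single YAML-able config dict drives all stages; every stage's randomness
is derived from one master seed through named substreams, so a run is fully
replayable.  Artifacts (NIfTI volumes, TRK bundles, checkpoints, JSON
reports) are written under the output directory and inventoried in a run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from atm.generation import embed_training_streamlines, fit_latent_kde, sample_bundle
from atm.io import write_tractogram, write_volume
from atm.losses import LossWeights
from atm.metrics import BundleDefinition, evaluate_bundle
from atm.model import ModelConfig
from atm.phantom import BundleSpec, default_specs, make_population
from atm.postprocess import postprocess_bundle
from atm.training import TrainConfig, train


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


# substream indices for deriving per-stage seeds from the master seed
_STAGES = {"phantom": 0, "train": 1, "generate": 2}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid_shape": [32, 32, 32],
    "n_points": 32,
    "n_train_subjects": 8,
    "n_val_subjects": 2,
    "n_test_subjects": 1,
    "variability_sd": 0.75,
    "bundles": "default",  # or list of BundleSpec field dicts
    "model": {
        "latent_dim": 8,
        "cond_dim": 16,
        "anat_channels": [8, 16, 24, 32],
        "line_channels": 24,
    },
    "train": {
        "learning_rate": 1e-3,
        "epochs": 150,
        "streamlines_per_step": 100,
    },
    "generate": {"n_streamlines": 300},
    "postprocess": {"min_length_mm": 20.0},
    "evaluate": {"ba_threshold_mm": 5.0, "lmax": 8, "validity_fraction": 0.9},
}


def _merged(base: dict, override: dict | None) -> dict:
    out = json.loads(json.dumps(base))
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Replay information for one pipeline run."""

    config: dict
    config_hash: str
    seeds: dict[str, int]
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2, sort_keys=True)


def _bundle_specs(config: dict) -> list[BundleSpec]:
    if config["bundles"] == "default":
        return default_specs(n_points=config["n_points"])
    specs = []
    for d in config["bundles"]:
        d = dict(d)
        d.setdefault("n_points", config["n_points"])
        for key in ("center", "orientation"):
            if key in d:
                d[key] = tuple(d[key])
        specs.append(BundleSpec(**d))
    return specs


def run_pipeline(config: dict | None, out_dir: str | Path) -> RunManifest:
    """Execute the staged workflow on phantom data; returns the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    saving a partial manifest.
    """
    cfg = _merged(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(cfg["seed"], s) for s in _STAGES}
    manifest = RunManifest(config=cfg, config_hash=_config_hash(cfg), seeds=seeds)

    def fail(stage: str, exc: Exception):
        manifest.save(out / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    def record(stage: str, t0: float):
        manifest.timings_s[stage] = round(time.time() - t0, 3)
        manifest.completed_stages.append(stage)

    # --- phantom -----------------------------------------------------------
    t0 = time.time()
    try:
        specs = _bundle_specs(cfg)
        n_total = (
            cfg["n_train_subjects"] + cfg["n_val_subjects"] + cfg["n_test_subjects"]
        )
        pop = make_population(
            n_total, specs, cfg["variability_sd"], rng_seed=seeds["phantom"]
        )
        n_tr, n_va = cfg["n_train_subjects"], cfg["n_val_subjects"]
        train_subjects = pop[:n_tr]
        val_subjects = pop[n_tr : n_tr + n_va]
        test_subjects = pop[n_tr + n_va :]
        phantom_dir = out / "phantoms"
        phantom_dir.mkdir(exist_ok=True)
        for subj in test_subjects:
            write_volume(subj.t1_like, phantom_dir / f"{subj.name}_t1.nii.gz")
            manifest.outputs.append(f"phantoms/{subj.name}_t1.nii.gz")
            for bname, sset in subj.bundles.items():
                p = phantom_dir / f"{subj.name}_{bname}_gt.trk"
                write_tractogram(sset, p)
                manifest.outputs.append(f"phantoms/{subj.name}_{bname}_gt.trk")
    except PipelineError:
        raise
    except Exception as exc:
        fail("phantom", exc)
    record("phantom", t0)

    # --- per-bundle: train, generate, postprocess, evaluate ----------------
    model_cfg_dict = cfg["model"]
    reports: dict[str, dict] = {}
    for spec in specs:
        bname = spec.name
        t0 = time.time()
        try:
            model_config = ModelConfig(
                grid_shape=tuple(cfg["grid_shape"]),
                latent_dim=model_cfg_dict["latent_dim"],
                cond_dim=model_cfg_dict["cond_dim"],
                n_points=cfg["n_points"],
                anat_channels=tuple(model_cfg_dict["anat_channels"]),
                line_channels=model_cfg_dict["line_channels"],
                seed=seeds["train"],
            )
            train_config = TrainConfig(
                learning_rate=cfg["train"]["learning_rate"],
                epochs=cfg["train"]["epochs"],
                streamlines_per_step=cfg["train"]["streamlines_per_step"],
                seed=seeds["train"],
                weights=LossWeights(),
                bundle_name=bname,
            )
            checkpoint, history = train(
                train_subjects, val_subjects, model_config, train_config
            )
            ckpt_path = out / f"checkpoint_{bname}.npz"
            checkpoint.save(ckpt_path)
            history.to_csv(out / f"history_{bname}.csv")
            manifest.outputs += [f"checkpoint_{bname}.npz", f"history_{bname}.csv"]
        except Exception as exc:
            fail(f"train[{bname}]", exc)
        record(f"train[{bname}]", t0)

        t0 = time.time()
        try:
            model = checkpoint.build_model()
            emb = embed_training_streamlines(
                model, train_subjects, bname,
                max_per_subject=cfg["train"]["streamlines_per_step"],
            )
            density = fit_latent_kde(emb)
            n_gen = int(cfg["generate"]["n_streamlines"])
            if n_gen < 1:
                raise ValueError("generate.n_streamlines must be >= 1")
            generated = {
                subj.name: sample_bundle(
                    model, density, subj.t1_like, n_gen, seed=seeds["generate"]
                )
                for subj in test_subjects
            }
            for sname, sset in generated.items():
                p = out / f"generated_{sname}_{bname}.trk"
                write_tractogram(sset, p)
                manifest.outputs.append(p.name)
        except Exception as exc:
            fail(f"generate[{bname}]", exc)
        record(f"generate[{bname}]", t0)

        t0 = time.time()
        try:
            processed = {}
            for subj in test_subjects:
                clean, report = postprocess_bundle(
                    generated[subj.name],
                    subj.brain_mask,
                    subj.wm_mask,
                    subj.parcellation,
                    subj.exception_labels,
                    min_length_mm=cfg["postprocess"]["min_length_mm"],
                    hemisphere_plane_x=None,
                )
                processed[subj.name] = clean
                p = out / f"clean_{subj.name}_{bname}.trk"
                write_tractogram(clean, p)
                with open(out / f"filter_{subj.name}_{bname}.json", "w") as fh:
                    json.dump(report, fh, indent=2)
                manifest.outputs += [p.name, f"filter_{subj.name}_{bname}.json"]
        except Exception as exc:
            fail(f"postprocess[{bname}]", exc)
        record(f"postprocess[{bname}]", t0)

        t0 = time.time()
        try:
            for subj in test_subjects:
                gt_defs = {
                    nm: BundleDefinition(
                        mask=subj.gt_occupancy[nm],
                        roi_a=subj.endpoint_rois[nm][0],
                        roi_b=subj.endpoint_rois[nm][1],
                    )
                    for nm in subj.bundles
                }
                report = evaluate_bundle(
                    processed[subj.name],
                    subj.bundles[bname],
                    subj.gt_occupancy[bname],
                    subj.t1_like,
                    gt_defs=gt_defs,
                    parcellation=subj.parcellation,
                    ba_threshold_mm=cfg["evaluate"]["ba_threshold_mm"],
                    lmax=cfg["evaluate"]["lmax"],
                    validity_fraction=cfg["evaluate"]["validity_fraction"],
                )
                key = f"{subj.name}/{bname}"
                reports[key] = report.to_dict()
        except Exception as exc:
            fail(f"evaluate[{bname}]", exc)
        record(f"evaluate[{bname}]", t0)

    with open(out / "metrics.json", "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
    manifest.outputs.append("metrics.json")
    manifest.save(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
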