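"""End-to-end pipeline: simulate → filter → cluster → featurize → train →
evaluate → explain, with every artifact stamped by config hash and seeds."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .cohort import filter_eligible
from .evaluation import EvalConfig, cross_validate, run_fold
from .interpret import decompose_tensor_sample, global_pattern
from .model import ModelConfig
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("retainwl")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    out_dir: str = "retainwl_out"
    seed: int = 0
    # simulate (set n_users=0 to read existing files instead)
    n_users: int = 200
    profiles_path: str | None = None
    logs_path: str | None = None
    # cluster / model / evaluation
    k_clusters: int = 5
    n_replicates: int = 5
    train_fraction: float = 0.7
    hidden_size: int = 24
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 5e-3

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            n_replicates=self.n_replicates,
            train_fraction=self.train_fraction,
            seed=self.seed,
            k_clusters=self.k_clusters,
            model=ModelConfig(
                hidden_size=self.hidden_size,
                seed=self.seed,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                batch_size=self.batch_size,
            ),
        )

    def config_hash(self) -> str:
        # hash the scientific configuration only, not filesystem locations
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "profiles_path", "logs_path")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
                raise StageError(name, exc) from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; returns a map from artifact name to path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    @_stage("simulate")
    def simulate():
        if config.n_users > 0:
            cohort = generate_cohort(GeneratorConfig(n_users=config.n_users, seed=config.seed))
            rio.write_profiles(cohort.profiles, out / "profiles.csv")
            rio.write_logs(cohort.logs, out / "logs.csv")
            rio.write_truth(cohort.truth, out / "truth.txt")
            artifacts["profiles"] = str(out / "profiles.csv")
            artifacts["logs"] = str(out / "logs.csv")
            artifacts["truth"] = str(out / "truth.txt")
            return cohort.profiles, cohort.logs
        if not (config.profiles_path and config.logs_path):
            raise ValueError("n_users=0 requires profiles_path and logs_path")
        return rio.read_profiles(config.profiles_path), rio.read_logs(config.logs_path)

    @_stage("filter")
    def filt(profiles, logs):
        eligible, report = filter_eligible(profiles, logs)
        (out / "exclusion_report.txt").write_text(report.summary() + "\n")
        artifacts["exclusion_report"] = str(out / "exclusion_report.txt")
        if not eligible:
            raise ValueError("no eligible users after filtering")
        return eligible

    @_stage("fit")
    def fit(eligible, logs):
        # cluster + featurize + train happen inside the leakage-free fold
        result = run_fold(eligible, logs, config.eval_config(), split_seed=config.seed)
        if result.trajectory_model is not None:
            rio.save_trajectory_model(result.trajectory_model, out / "trajectory_model.json")
            artifacts["trajectory_model"] = str(out / "trajectory_model.json")
        rio.save_model_params(result.params, out / "model_params.json")
        artifacts["model_params"] = str(out / "model_params.json")
        return result

    @_stage("evaluate")
    def evaluate(eligible, logs):
        report = cross_validate(eligible, logs, config.eval_config())
        payload = {
            "config_hash": config.config_hash(),
            "split_seeds": report.split_seeds,
            "overall_mape": report.overall_mape,
            "per_week_mape": report.per_week_mape.tolist(),
            "per_fold": [
                {
                    "fold": f.fold,
                    "split_seed": f.split_seed,
                    "overall_mape": f.overall_mape,
                    "per_week_mape": f.per_week_mape.tolist(),
                    "n_train_users": f.n_train_users,
                    "n_test_users": f.n_test_users,
                }
                for f in report.per_fold
            ],
        }
        (out / "eval_report.json").write_text(json.dumps(payload, indent=1))
        (out / "eval_report.txt").write_text(report.summary() + "\n")
        artifacts["eval_report"] = str(out / "eval_report.json")
        artifacts["eval_summary"] = str(out / "eval_report.txt")
        return report

    @_stage("explain")
    def explain(result):
        pattern = global_pattern(result.test_tensor, result.params)
        pattern.to_frame().to_csv(out / "global_pattern.csv", index=False)
        artifacts["global_pattern"] = str(out / "global_pattern.csv")
        full = result.test_tensor.full_length_only()
        table = decompose_tensor_sample(full, 0, result.params)
        table.to_frame().to_csv(out / "sample_contributions.csv", index=False)
        artifacts["sample_contributions"] = str(out / "sample_contributions.csv")

    profiles, logs = simulate()
    eligible = filt(profiles, logs)
    result = fit(eligible, logs)
    evaluate(eligible, logs)
    explain(result)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out / "run_manifest.json")
    return artifacts
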