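"""End-to-end orchestration: simulate -> preprocess -> extract -> split ->
calibrate (BPNN, SVR, PLSR) -> evaluate -> compare.

A single :class:`RunConfig` drives the whole run; the master seed
propagates deterministic sub-seeds to every stochastic stage, so a rerun
with the same configuration reproduces every intermediate artifact
byte for byte.  Models are ranked by validation RPD, then R^2, then
(ascending) RMSE.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import (BPNNConfig, BPNNModel, Dataset, PLSRConfig,
                        PLSRModel, SVRConfig, SVRModel)
from .evaluation import EvaluationReport, evaluate
from .exceptions import AossomError
from .features import extract_features, features_to_frame
from .signal_io import PreprocessConfig, preprocess, write_recording
from .split import kennard_stone, train_count
from .synthetic import SimulatorConfig, default_sensor_params, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("aossom.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The master ``seed`` overrides the sub-config seeds (simulator, BPNN,
    SVR fold assignment) with deterministically derived values.
    """

    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    normalizer: str = "variance"
    split_ratio: float = 0.7
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)
    plsr: PLSRConfig = field(default_factory=PLSRConfig)
    models: tuple = ("bpnn", "svr", "plsr")
    seed: int = 0
    t_target: float = 20.0

    def __post_init__(self):
        subseeds = np.random.SeedSequence(self.seed).generate_state(4)
        self.simulator.seed = int(subseeds[0] % (2**31))
        self.bpnn.seed = int(subseeds[1] % (2**31))
        self.svr.seed = int(subseeds[2] % (2**31))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build from a hierarchical YAML document of keyword arguments."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sim = dict(raw.pop("simulator", {}))
        noise_sd = sim.pop("noise_sd", None)
        if noise_sd is not None:
            sim["sensors"] = default_sensor_params(noise_sd=float(noise_sd))
        kwargs["simulator"] = SimulatorConfig(**sim)
        kwargs["preprocessing"] = PreprocessConfig(**raw.pop("preprocessing", {}))
        kwargs["bpnn"] = BPNNConfig(**{
            k: tuple(v) if k == "hidden_range" else v
            for k, v in raw.pop("bpnn", {}).items()})
        kwargs["svr"] = SVRConfig(**{
            k: tuple(v) if k == "coarse_range" else v
            for k, v in raw.pop("svr", {}).items()})
        kwargs["plsr"] = PLSRConfig(**raw.pop("plsr", {}))
        if "models" in raw:
            kwargs["models"] = tuple(raw.pop("models"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """All artifacts of one run."""

    features: pd.DataFrame
    partition: object
    models: dict
    reports: dict          # kind -> {"calibration": ..., "prediction": ...}
    comparison: pd.DataFrame

    def summary(self) -> str:
        lines = ["Model comparison (ranked by validation RPD, R^2, RMSE):",
                 self.comparison.to_string(index=False)]
        return "\n".join(lines)


def _rank_models(reports: dict) -> pd.DataFrame:
    rows = []
    for kind, phases in reports.items():
        pred: EvaluationReport = phases["prediction"]
        rows.append({"model": kind, "r2": pred.r2, "rmse": pred.rmse,
                     "rpd": pred.rpd, "category": pred.category})
    frame = pd.DataFrame(rows)
    return frame.sort_values(by=["rpd", "r2", "rmse"],
                             ascending=[False, False, True],
                             kind="mergesort").reset_index(drop=True)


def run_pipeline(config: RunConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Execute every stage and assemble a ranked comparison report.

    Parameters
    ----------
    config : RunConfig
    outdir : optional path
        When given, intermediate artifacts (recordings, feature table,
        partition, per-model reports, comparison) are persisted under
        ``recordings/``, ``features/``, ``partition/``, ``reports/``.
    """
    config = config or RunConfig()
    outdir = Path(outdir) if outdir is not None else None
    stage = "simulate"
    try:
        t0 = time.time()
        log.info("[simulate] %d samples, seed %d",
                 config.simulator.n_samples, config.simulator.seed)
        recordings, som = simulate_dataset(config.simulator)

        stage = "preprocess"
        processed = [preprocess(r, config.preprocessing) for r in recordings]
        if outdir is not None:
            rec_dir = outdir / "recordings"
            rec_dir.mkdir(parents=True, exist_ok=True)
            for rec in processed:
                write_recording(rec, rec_dir / f"{rec.sample_id}.csv")

        stage = "extract"
        tables = [extract_features(r, config.t_target) for r in processed]
        frame = features_to_frame(tables, normalizer=config.normalizer,
                                  som=som)
        log.info("[extract] %d x %d feature matrix (normalizer=%s)",
                 frame.shape[0], frame.shape[1] - 1, config.normalizer)
        if outdir is not None:
            feat_dir = outdir / "features"
            feat_dir.mkdir(parents=True, exist_ok=True)
            frame.to_csv(feat_dir / "features.csv")

        stage = "split"
        n_train = train_count(len(frame), config.split_ratio)
        partition = kennard_stone(frame.drop(columns=["som_g_per_kg"]),
                                  n_train)
        log.info("[split] Kennard-Stone %d train / %d validation",
                 len(partition.train_ids), len(partition.valid_ids))
        if outdir is not None:
            part_dir = outdir / "partition"
            part_dir.mkdir(parents=True, exist_ok=True)
            with open(part_dir / "partition.json", "w") as fh:
                json.dump(partition.to_dict(), fh, indent=1)

        data = Dataset.from_dataframe(frame)
        train = data.subset(partition.train_ids)
        valid = data.subset(partition.valid_ids)

        builders = {
            "bpnn": lambda: BPNNModel(train, config.bpnn).fit(),
            "svr": lambda: SVRModel(train, config.svr).fit(),
            "plsr": lambda: PLSRModel(train, config.plsr).fit(),
        }
        models, reports = {}, {}
        for kind in config.models:
            stage = f"calibrate:{kind}"
            if kind not in builders:
                raise AossomError(f"unknown model kind {kind!r}")
            log.info("[%s] fitting", stage)
            result = builders[kind]()
            models[kind] = result
            stage = f"evaluate:{kind}"
            reports[kind] = {
                "calibration": evaluate(result, train, "calibration"),
                "prediction": evaluate(result, valid, "prediction"),
            }
            log.info("[%s] prediction R^2=%.3f RPD=%.3f (%s)", stage,
                     reports[kind]["prediction"].r2,
                     reports[kind]["prediction"].rpd,
                     reports[kind]["prediction"].category)

        stage = "compare"
        comparison = _rank_models(reports)
        if outdir is not None:
            rep_dir = outdir / "reports"
            rep_dir.mkdir(parents=True, exist_ok=True)
            for kind, phases in reports.items():
                payload = {ph: rep.to_dict() for ph, rep in phases.items()}
                with open(rep_dir / f"{kind}.json", "w") as fh:
                    json.dump(payload, fh, indent=1)
            comparison.to_csv(rep_dir / "comparison.csv", index=False)
        log.info("[done] %.1f s", time.time() - t0)
        return PipelineResult(features=frame, partition=partition,
                              models=models, reports=reports,
                              comparison=comparison)
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise
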