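"""End-to-end orchestration: load/simulate -> normalize -> select -> model -> report.

A pipeline run takes either a pair of CSV paths (descriptor table + PK
table) or a synthetic-benchmark spec, runs the GA descriptor selection and
the repeated sub-sampling network validation, and writes every artifact
(selection report, per-repeat trained models, evaluation report, log) into
a run directory named by a hash of the resolved configuration — distinct
configurations can never collide on disk, and re-running an identical
configuration reproduces identical artifacts byte for byte.

Per-stage seeds are derived from the single global seed with a counter
scheme (stage 0 = simulation, 1 = GA, 2 = validation), so any stage can be
re-run in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ann import ANNConfig, init_network, save_model, train_levenberg_marquardt
from .evaluate import repeated_subsampling_validation
from .ga import GAConfig, run_ga
from .io_normalize import (
    QSPkRDataset,
    handle_missing,
    minmax_normalize,
    read_descriptor_table,
    read_pk_table,
)
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline"]

_STAGES = {"simulate": 0, "ga": 1, "evaluate": 2}


def stage_seed(global_seed: int | None, stage: str) -> int | None:
    """Derive a 31-bit stage seed from the global seed (documented counter
    scheme: SeedSequence([global_seed, stage_index]))."""
    if global_seed is None:
        return None
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one data source must be set."""

    descriptor_csv: str | None = None
    pk_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    n_train: int | None = None
    n_repeats: int = 10
    missing_policy: str = "drop_columns"
    out_dir: str = "qspkr_runs"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.descriptor_csv is not None or self.pk_csv is not None
        if has_files and (self.descriptor_csv is None or self.pk_csv is None):
            raise ValueError("descriptor_csv and pk_csv must be given together")
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "exactly one data source (CSV paths or synthetic spec) required"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "ga" in d:
            d["ga"] = GAConfig(**d["ga"])
        if "ann" in d:
            d["ann"] = ANNConfig(**d["ann"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = {
            "descriptor_csv": self.descriptor_csv,
            "pk_csv": self.pk_csv,
            "synthetic": (None if self.synthetic is None
                          else {k: v for k, v in self.synthetic.__dict__.items()}),
            "ga": dict(self.ga.__dict__),
            "ann": dict(self.ann.__dict__),
            "n_train": self.n_train,
            "n_repeats": self.n_repeats,
            "missing_policy": self.missing_policy,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d

    def config_hash(self) -> str:
        """Hash of the resolved configuration minus the output location."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    run_dir: Path
    config_hash: str
    selection: dict
    evaluation: dict
    dataset: QSPkRDataset


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def _load_dataset(config: PipelineConfig) -> QSPkRDataset:
    if config.synthetic is not None:
        spec = config.synthetic
        if spec.seed is None and config.seed is not None:
            spec = SyntheticSpec(**{**spec.__dict__,
                                    "seed": stage_seed(config.seed, "simulate")})
        data, _truth = generate_dataset(spec)
        return data
    raw = read_descriptor_table(config.descriptor_csv)
    raw, report = handle_missing(raw, policy=config.missing_policy)
    if report["n_missing"]:
        logger.info("missing-value handling: %s", report)
    pk = read_pk_table(config.pk_csv)
    return minmax_normalize(raw, pk)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute normalize -> GA selection -> ANN validation and write artifacts."""
    chash = config.config_hash()
    run_dir = Path(config.out_dir) / f"run-{chash[:12]}"
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("qspkr")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    stamp = {"config_hash": chash, "seed": config.seed}
    stage = "load_data"
    try:
        _write_json(run_dir / "config.json", {**config.to_dict(), **stamp})

        data = _load_dataset(config)
        logger.info("dataset: %d compounds x %d descriptors (%s)",
                    data.n_compounds, data.n_descriptors, data.pk_name)

        stage = "ga_select"
        ga_cfg = config.ga
        if ga_cfg.seed is None and config.seed is not None:
            ga_cfg = GAConfig(**{**ga_cfg.__dict__,
                                 "seed": stage_seed(config.seed, "ga")})
        ga_result = run_ga(data, ga_cfg)
        selection = {**ga_result.to_dict(), **stamp}
        _write_json(run_dir / "selection.json", selection)
        logger.info("GA selected %d descriptors after %d generations (%s)",
                    len(ga_result.selected_indices), ga_result.generations,
                    ga_result.termination_reason)
        if not ga_result.selected_indices:
            raise RuntimeError("GA returned an empty descriptor selection")

        stage = "evaluate"
        eval_seed = (stage_seed(config.seed, "evaluate")
                     if config.seed is not None else None)
        report = repeated_subsampling_validation(
            data, ga_result.selected_indices, ann_config=config.ann,
            n_repeats=config.n_repeats, n_train=config.n_train, seed=eval_seed)
        evaluation = {**report.to_dict(), **stamp}
        _write_json(run_dir / "evaluation.json", evaluation)

        stage = "final_model"
        # one model per validation repeat is implicit in the report; also fit
        # a final model on all compounds for downstream prediction
        final_cfg = ANNConfig(**{**config.ann.__dict__,
                                 "seed": eval_seed})
        model = init_network(len(ga_result.selected_indices), final_cfg)
        model = train_levenberg_marquardt(
            model, data.X[:, ga_result.selected_indices], data.dp, final_cfg)
        save_model(model, run_dir / "model_final.json")

        logger.info("run complete: %s", run_dir)
        return PipelineResult(run_dir=run_dir, config_hash=chash,
                              selection=selection, evaluation=evaluation,
                              dataset=data)
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n",
                                        encoding="utf-8")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
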