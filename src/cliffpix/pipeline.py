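"""End-to-end orchestration: curate -> enumerate -> label -> split ->
render -> train -> predict -> evaluate -> explain.

A run is driven by one :class:`RunConfig` (serializable to YAML), writes
every stage's output into a run directory and finishes with an aggregate
report (mean +/- sd over trials) plus a per-panel attribution summary.
Stages log their counts as line-delimited JSON records so a run can be
audited after the fact; persisted intermediates (curated table, MMP
table, labeled table, split manifest, model checkpoints) let any stage
be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, dataset, imaging, metrics, mmp, synth
from .classifier import CNNClassifier, ModelConfig, reduced_config
from .dataset import Label
from .errors import CliffpixError, DataError
from .gradcam import explain_batch, gradcam, panel_heat_fractions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str = "run"
    input_table: str | None = None  # delimited compound/potency table
    synthetic_seed: int | None = None  # generate the packaged benchmark instead
    # curation
    max_spread: float = 1.0
    # enumeration
    max_sub_atoms: int = mmp.MAX_SUBSTITUENT_ATOMS
    core_factor: float = mmp.CORE_SIZE_FACTOR
    max_sub_diff: int = mmp.MAX_SUBSTITUENT_DIFF
    # labeling / filtering
    ac_threshold: float = dataset.AC_THRESHOLD
    non_ac_threshold: float = dataset.NON_AC_THRESHOLD
    # trials
    n_trials: int = 10
    base_seed: int = 7
    # imaging / model
    reduced: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)
    explain_layers: tuple[str, ...] = ("conv1", "conv2")
    save_images: bool = False
    save_models: bool = False

    def panel_size(self) -> int:
        return self.model.input_shape[0]

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        model = payload.pop("model", None)
        cfg = cls(**payload)
        if model is not None:
            for key in ("input_shape", "filter_sizes"):
                if key in model:
                    model[key] = tuple(model[key])
            cfg.model = ModelConfig(**model)
        if "explain_layers" in payload:
            cfg.explain_layers = tuple(payload["explain_layers"])
        return cfg


def reduced_run_config(**overrides) -> RunConfig:
    """Desk-scale run: reduced model profile, 2 trials."""
    cfg = RunConfig(model=reduced_config(), reduced=True, n_trials=2)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise CliffpixError(f"unknown run config field {key!r}")
        setattr(cfg, key, value)
    return cfg


class _StageLogger:
    """Line-delimited JSON stage log."""

    def __init__(self, path: Path):
        self._fh = open(path, "a")

    def log(self, stage: str, **fields) -> None:
        record = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
        self._fh.write(json.dumps(record) + "\n")
        self._fh.flush()
        logger.info("stage %s: %s", stage, fields)

    def close(self) -> None:
        self._fh.close()


@dataclass
class RunResult:
    """In-memory handles to everything a finished run produced."""

    config: RunConfig
    labeled: list
    splits: list
    tensors: np.ndarray
    mmp_ids: list[str]
    models: list[CNNClassifier]
    trial_reports: list[metrics.MetricsReport]
    predictions: list[pd.DataFrame]
    aggregate: metrics.AggregateReport
    heat_summary: pd.DataFrame | None


def _stage_inputs(config: RunConfig, log: _StageLogger):
    if config.input_table is not None:
        records = curation.load_activity_class(config.input_table, max_spread=config.max_spread)
        log.log("curate", source=str(config.input_table), compounds=len(records))
        return records
    if config.synthetic_seed is None:
        raise DataError("run_pipeline: configure either input_table or synthetic_seed")
    spec = synth.default_benchmark_spec(seed=config.synthetic_seed)
    raw = synth.generate_series(spec)
    records = curation.curate_records(raw, max_spread=config.max_spread)
    log.log("curate", source="synthetic-benchmark", compounds=len(records))
    return records


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline; raises with the stage name on failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.model.validate()
    config.to_yaml(out / "config.yaml")
    log = _StageLogger(out / "run_log.jsonl")
    stage = "curate"
    try:
        records = _stage_inputs(config, log)
        curation.write_curated(records, out / "curated.csv")

        stage = "enumerate"
        pairs = mmp.enumerate_mmps_from_records(
            records,
            max_sub_atoms=config.max_sub_atoms,
            core_factor=config.core_factor,
            max_sub_diff=config.max_sub_diff,
        )
        mmp.mmps_to_frame(pairs).to_csv(out / "mmps.csv", index=False)
        log.log(stage, mmps=len(pairs))

        stage = "label"
        labeled_all = dataset.label_mmps(
            pairs, ac_threshold=config.ac_threshold, non_ac_threshold=config.non_ac_threshold
        )
        counts = {
            lbl.value: sum(lm.label is lbl for lm in labeled_all) for lbl in Label
        }
        labeled = dataset.multiplicity_filter(dataset.drop_excluded(labeled_all))
        dataset.labeled_to_frame(labeled).to_csv(out / "labeled.csv", index=False)
        log.log(stage, **counts, retained=len(labeled))

        stage = "split"
        splits = dataset.make_splits(labeled, n_trials=config.n_trials, base_seed=config.base_seed)
        dataset.splits_to_json(splits, out / "splits.json")
        log.log(stage, n_trials=config.n_trials)

        stage = "render"
        cache = imaging.PanelCache()
        tensors, ids = imaging.render_tensors(
            labeled, panel_size=config.panel_size(), cache=cache
        )
        if config.save_images:
            imaging.render_dataset(labeled, out / "images", panel_size=config.panel_size(), cache=cache)
        log.log(stage, images=len(ids), unique_panels=cache.render_count)
        id_to_idx = {mid: i for i, mid in enumerate(ids)}
        y_all = np.array([1 if lm.label is Label.AC else 0 for lm in labeled], dtype=np.int64)

        stage = "train"
        models, trial_reports, predictions = [], [], []
        for t, split in enumerate(splits):
            mcfg = dataclasses.replace(config.model, seed=split.trial_seed)
            model = CNNClassifier(mcfg)
            tr_idx = [id_to_idx[lm.mmp_id] for lm in split.train]
            te_idx = [id_to_idx[lm.mmp_id] for lm in split.test]
            history = model.fit(tensors[tr_idx], y_all[tr_idx])
            pd.DataFrame({"epoch": range(1, len(history) + 1), "loss": history}).to_csv(
                out / f"history_trial{t}.csv", index=False
            )
            if config.save_models:
                model.save(out / f"model_trial{t}")
            preds = model.predict(tensors[te_idx], mmp_ids=[ids[i] for i in te_idx])
            frame = pd.DataFrame(
                {
                    "mmp_id": [p.mmp_id for p in preds],
                    "p_ac": [p.p_ac for p in preds],
                    "p_non_ac": [p.p_non_ac for p in preds],
                    "predicted_label": [p.predicted_label for p in preds],
                    "true_label": [lm.label.value for lm in split.test],
                }
            )
            frame.to_csv(out / f"predictions_trial{t}.csv", index=False)
            predictions.append(frame)
            rep = metrics.report(
                frame["true_label"], frame["predicted_label"], frame["p_ac"]
            )
            trial_reports.append(rep)
            models.append(model)
            log.log(
                "trial",
                trial=t,
                trial_seed=split.trial_seed,
                final_loss=history[-1] if history else None,
                **rep.as_dict(),
            )

        stage = "evaluate"
        agg = metrics.aggregate(trial_reports)
        metrics.reports_to_frame(trial_reports).to_csv(out / "metrics_trials.csv", index=False)
        with open(out / "aggregate.json", "w") as fh:
            json.dump(
                {"mean": agg.mean, "sd": agg.sd, "n_trials": agg.n_trials}, fh, indent=1
            )
        log.log(stage, **{f"mean_{k}": v for k, v in agg.mean.items()})

        stage = "explain"
        heat_summary = None
        if config.explain_layers:
            # attribute the last trial's correctly predicted test cliffs
            frame = predictions[-1]
            hits = frame[(frame.true_label == "AC") & (frame.predicted_label == "AC")]
            sel = [id_to_idx[mid] for mid in hits.mmp_id]
            heat_summary = explain_batch(
                models[-1],
                tensors[sel],
                list(hits.mmp_id),
                layer_ids=config.explain_layers,
                out_dir=(out / "overlays") if config.save_images else None,
            )
            heat_summary.to_csv(out / "heat_summary.csv", index=False)
            log.log(stage, explained=len(sel), layers=list(config.explain_layers))
    except CliffpixError as exc:
        log.log("error", failed_stage=stage, error=str(exc))
        log.close()
        raise CliffpixError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.close()
    return RunResult(
        config=config,
        labeled=labeled,
        splits=splits,
        tensors=tensors,
        mmp_ids=ids,
        models=models,
        trial_reports=trial_reports,
        predictions=predictions,
        aggregate=agg,
        heat_summary=heat_summary,
    )
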