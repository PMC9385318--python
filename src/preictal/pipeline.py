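"""Per-patient orchestration: read -> harmonize -> segment -> label ->
features -> sequences -> balance -> train -> evaluate, once per
qualifying-window length.

Training and evaluation are carried out separately for every patient.
Class imbalance is handled at the *sequence* level: the interictal
sequences are partitioned into disjoint subgroups the size of the
preictal-sequence pool; a classifier is trained per subgroup on a seeded
stratified 80/20 split and the reported segment metrics are subgroup
averages.  Event scoring applies the first subgroup's model to every
scored sequence across the whole timeline, so alarms and missed seizures
refer to the full recording set.

Outputs per run: one metrics JSON/CSV per qualifying window plus a
manifest recording the configuration hash, seed, package versions and
per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    balance_interictal,
    blocked_stratified_split,
    event_metrics,
    segment_metrics,
    stratified_split,
)
from .features import SegmentFeatureExtractor, feature_matrix, raw_segment_table
from .io import harmonize_channels, read_annotation_json, read_edf
from .lstm import LstmSequenceClassifier, ModelConfig
from .segmentation import (
    QualifyingWindow,
    label_counts,
    label_segments,
    segment_recording,
)
from .sequences import build_sequences
from .types import Recording, SeizureAnnotation


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of one per-patient run."""

    patient_id: str
    edf_paths: list[str] = field(default_factory=list)
    annotation_paths: list[str] = field(default_factory=list)
    qualifying_windows_min: list[float] = field(
        default_factory=lambda: [15.0, 30.0, 60.0, 120.0]
    )
    feature_mode: str = "features"  # or "raw"
    model: ModelConfig = field(default_factory=ModelConfig)
    split: str = "blocked"  # or "random" (leaks across overlapping sequences)
    test_fraction: float = 0.2
    refractory_s: float = 300.0
    output_dir: str = "preictal_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in ("features", "raw"):
            raise ValueError("feature_mode must be 'features' or 'raw'")
        if self.split not in ("blocked", "random"):
            raise ValueError("split must be 'blocked' or 'random'")
        if any(w <= 0 for w in self.qualifying_windows_min):
            raise ValueError("qualifying windows must be positive")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _evaluate_window(
    table: pd.DataFrame,
    annotations: list[SeizureAnnotation],
    qw: QualifyingWindow,
    cfg: RunConfig,
    segment_s: float,
) -> dict:
    """Train/evaluate for one qualifying-window length; returns metrics."""
    ds = build_sequences(table, cfg.model.sequence_length)
    if len(ds) == 0:
        raise ValueError("empty sequence dataset")
    groups = balance_interictal(ds.y, seed=cfg.seed)
    pre_idx = np.nonzero(ds.y == "preictal")[0]

    per_group = []
    models = []
    for gi, inter_idx in enumerate(groups):
        sel = np.concatenate([pre_idx, inter_idx])
        Xg, yg = ds.X[sel], ds.y[sel]
        if cfg.split == "blocked":
            meta_g = ds.meta.iloc[sel].reset_index(drop=True)
            train_i, test_i = blocked_stratified_split(
                meta_g, cfg.test_fraction, seed=cfg.seed + 1000 + gi,
                purge=cfg.model.sequence_length - 1,
            )
        else:
            train_i, test_i = stratified_split(
                yg, cfg.test_fraction, seed=cfg.seed + 1000 + gi
            )
        model = LstmSequenceClassifier(
            architecture=cfg.model.architecture,
            n_layers=cfg.model.n_layers,
            hidden=cfg.model.hidden,
            dropout_rate=cfg.model.dropout_rate,
            batch_size=cfg.model.batch_size,
            epochs=cfg.model.epochs,
            learning_rate=cfg.model.learning_rate,
            beta1=cfg.model.beta1,
            beta2=cfg.model.beta2,
            epsilon=cfg.model.epsilon,
            decay=cfg.model.decay,
            standardize=cfg.model.standardize,
            seed=cfg.seed + gi,
        )
        model.fit(Xg[train_i], yg[train_i])
        pred = model.predict(Xg[test_i])
        sm = segment_metrics(yg[test_i], pred)
        per_group.append(
            {"subgroup": gi, "n_train": len(train_i), "n_test": len(test_i),
             "tp": sm.tp, "tn": sm.tn, "fp": sm.fp, "fn": sm.fn,
             "sensitivity": sm.sensitivity, "specificity": sm.specificity,
             "accuracy": sm.accuracy,
             "final_loss": model.loss_trace_[-1]}
        )
        models.append(model)

    def _avg(key: str) -> float | None:
        vals = [g[key] for g in per_group if g[key] is not None]
        return float(np.mean(vals)) if vals else None

    # event scoring: first subgroup's model over the whole timeline
    scorer = models[0]
    pred_all = scorer.predict(ds.X)
    pred_table = ds.meta.copy()
    pred_table["pred"] = pred_all
    report = event_metrics(
        pred_table, annotations, qw,
        refractory_s=cfg.refractory_s, segment_s=segment_s,
    )
    return {
        "window_min": qw.length_min,
        "n_sequences": len(ds),
        "n_preictal_sequences": int(pre_idx.size),
        "n_subgroups": len(groups),
        "subgroups": per_group,
        "avg_sensitivity": _avg("sensitivity"),
        "avg_specificity": _avg("specificity"),
        "avg_accuracy": _avg("accuracy"),
        "event": {
            "n_seizures": report.n_seizures,
            "n_predicted": report.n_predicted,
            "event_sensitivity": report.event_sensitivity,
            "false_alarms": report.false_alarms,
            "raw_false_positive_segments": report.raw_false_positive_segments,
            "monitored_interictal_hours": report.monitored_interictal_hours,
            "fpr_per_hour": report.fpr_per_hour,
        },
    }


def run_patient(
    cfg: RunConfig,
    recordings: list[Recording] | None = None,
    annotations: list[SeizureAnnotation] | None = None,
) -> dict:
    """Execute the full per-patient pipeline; returns the run manifest.

    ``recordings``/``annotations`` may be passed directly (e.g. synthetic
    data); otherwise they are read from the configured paths.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "patient_id": cfg.patient_id,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"preictal": __version__, "numpy": np.__version__},
        "stages": {},
    }

    try:
        if recordings is None:
            recordings = [read_edf(p) for p in cfg.edf_paths]
        if annotations is None:
            annotations = [read_annotation_json(p)
                           for p in cfg.annotation_paths]
        if not recordings:
            raise ValueError("no recordings")
    except Exception as exc:
        raise StageError("read", exc) from exc
    manifest["stages"]["read"] = {"n_recordings": len(recordings)}

    try:
        channels = harmonize_channels(recordings)
        recordings = [rec.subset_channels(channels) for rec in recordings]
    except Exception as exc:
        raise StageError("harmonize", exc) from exc
    manifest["stages"]["harmonize"] = {"channels": channels}

    ann_by_id = {a.record_id: a for a in annotations}
    extractor = SegmentFeatureExtractor()
    results = []
    segment_s = 5.0

    # features do not depend on the qualifying window: extract once
    try:
        segments = {
            rec.record_id: segment_recording(rec, window_s=segment_s)
            for rec in recordings
        }
        all_segments = [s for segs in segments.values() for s in segs]
        if cfg.feature_mode == "features":
            base_table = extractor.transform(recordings, all_segments)
        else:
            base_table = raw_segment_table(recordings, all_segments)
    except Exception as exc:
        raise StageError("features", exc) from exc
    manifest["stages"]["features"] = {
        "n_segments": len(all_segments),
        "n_columns": base_table.shape[1],
    }

    for window_min in cfg.qualifying_windows_min:
        qw = QualifyingWindow(window_min)
        try:
            labeled = []
            for rec in recordings:
                ann = ann_by_id.get(
                    rec.record_id, SeizureAnnotation(rec.record_id, [])
                )
                labeled.extend(
                    label_segments(segments[rec.record_id], ann, qw)
                )
            counts = label_counts(labeled)
            table = base_table.copy()
            table["label"] = [s.label for s in labeled]
        except Exception as exc:
            raise StageError("segment", exc) from exc

        try:
            metrics = _evaluate_window(
                table, annotations, qw, cfg, segment_s
            )
        except Exception as exc:
            raise StageError("train_evaluate", exc) from exc

        metrics["segment_counts"] = counts
        results.append(metrics)
        stem = f"metrics_window_{window_min:g}min"
        with open(out_dir / f"{stem}.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        pd.DataFrame(metrics["subgroups"]).assign(
            window_min=window_min
        ).to_csv(out_dir / f"{stem}.csv", index=False)
        manifest["stages"][f"window_{window_min:g}min"] = {
            "segment_counts": counts,
            "n_sequences": metrics["n_sequences"],
            "n_subgroups": metrics["n_subgroups"],
        }

    manifest["results"] = results
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
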