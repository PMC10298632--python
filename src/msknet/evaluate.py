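"""Evaluation: confusion counts, accuracy/sensitivity/specificity at the
fixed 0.5 threshold, and the input-sequence ablation harness.

Sensitivity is the true-positive rate tp/(tp+fn); specificity the
true-negative rate tn/(tn+fp). When a denominator is zero (no positives or
no negatives in the evaluated split) the metric is reported as ``None``
rather than a misleading 0 or 100. Percentages are printed rounded half-up
to one decimal.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from msknet.dicom_io import TASKS, LabelManifest
from msknet.model import KNetParams, MSKNet
from msknet.preprocess import FusedVolume
from msknet.train import TrainConfig, train_model

#: The default ablation grid: the four single sequences and three
#: three-sequence combinations of clinical interest.
DEFAULT_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("coronal_hybrid",),
    ("axial_t2",),
    ("sagittal_t1",),
    ("sagittal_t2",),
    ("coronal_hybrid", "sagittal_t1", "sagittal_t2"),
    ("axial_t2", "coronal_hybrid", "sagittal_t1"),
    ("axial_t2", "sagittal_t1", "sagittal_t2"),
)


def _ratio_percent(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return 100.0 * num / den


def _round1(value: float | None) -> float | None:
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Accuracy/sensitivity/specificity (percent) with their counts."""

    task: str
    counts: ConfusionCounts
    input_combination: tuple[str, ...] = ()
    accuracy: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        self.accuracy = _ratio_percent(c.tp + c.tn, c.total)
        self.sensitivity = _ratio_percent(c.tp, c.tp + c.fn)
        self.specificity = _ratio_percent(c.tn, c.tn + c.fp)

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "task": self.task,
            "input_combination": list(self.input_combination),
            "tp": c.tp,
            "tn": c.tn,
            "fp": c.fp,
            "fn": c.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetricsReport":
        return cls(
            task=data["task"],
            counts=ConfusionCounts(
                tp=data["tp"], tn=data["tn"], fp=data["fp"], fn=data["fn"]
            ),
            input_combination=tuple(data["input_combination"]),
        )

    def save_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | os.PathLike) -> "MetricsReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def row(self) -> dict:
        """One-decimal display row (half-up rounding, None -> 'NA')."""
        def fmt(v: float | None):
            return "NA" if v is None else _round1(v)
        return {
            "task": self.task,
            "input_combination": "+".join(self.input_combination),
            "accuracy": fmt(self.accuracy),
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
        }


def compute_metrics(
    predictions: Sequence[float],
    labels: Sequence[int],
    task: str = "abnormality",
    input_combination: tuple[str, ...] = (),
) -> MetricsReport:
    """Threshold probabilities at 0.5 and tally the confusion matrix.

    ``predictions`` may be probabilities in [0, 1] or already-hard labels;
    a tie at exactly 0.5 counts as positive.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must be the same length")
    counts = ConfusionCounts()
    for p, y in zip(predictions, labels):
        if y not in (0, 1):
            raise ValueError(f"labels must be binary, got {y!r}")
        pred = int(p >= 0.5)
        if pred == 1 and y == 1:
            counts.tp += 1
        elif pred == 0 and y == 0:
            counts.tn += 1
        elif pred == 1 and y == 0:
            counts.fp += 1
        else:
            counts.fn += 1
    return MetricsReport(task=task, counts=counts, input_combination=input_combination)


def evaluate_model(
    model: MSKNet,
    manifest: LabelManifest,
    volumes: dict[str, dict[str, FusedVolume]],
    task: str,
    split: str = "test",
) -> MetricsReport:
    """One deterministic forward pass per exam of the split; 0.5 threshold."""
    records = manifest.subset(split)
    if not records:
        raise ValueError(f"no exams in split {split!r}")
    sequences = model.params_cfg.stream_sequences
    probs, labels = [], []
    for rec in records:
        if rec.exam_id not in volumes:
            raise ValueError(f"missing preprocessed volumes for exam {rec.exam_id!r}")
        streams = {}
        for seq in sequences:
            if seq not in volumes[rec.exam_id]:
                raise ValueError(f"exam {rec.exam_id!r} lacks stream {seq!r}")
            streams[seq] = volumes[rec.exam_id][seq]
        probs.append(model.forward(streams).probability)
        labels.append(rec.labels[task])
    return compute_metrics(probs, labels, task=task, input_combination=tuple(sequences))


def run_ablation(
    manifest: LabelManifest,
    volumes: dict[str, dict[str, FusedVolume]],
    train_config: TrainConfig,
    combinations: Sequence[Sequence[str]] = DEFAULT_COMBINATIONS,
    tasks: Sequence[str] = TASKS,
    backbone: str = "tiny_cnn",
) -> tuple[pd.DataFrame, list[MetricsReport]]:
    """Train and evaluate one MS-KNet per (combination, task) pair.

    Returns a matrix with one row per input combination and task-by-metric
    columns, plus the full reports. Fully seeded: the combination and task indices fold into the
    training seed so every cell is reproducible in isolation.
    """
    combos = [tuple(c) for c in combinations]
    for combo in combos:
        if not 1 <= len(combo) <= 3:
            raise ValueError(f"combination {combo} must have 1-3 sequence types")
    reports: list[MetricsReport] = []
    rows = []
    for combo_idx, combo in enumerate(combos):
        row: dict[str, object] = {"input_combination": "+".join(combo)}
        for task_idx, task in enumerate(tasks):
            seed = (train_config.seed + 1000 * combo_idx + task_idx) % (2**31)
            params = KNetParams(
                backbone=backbone,
                n_streams=len(combo),
                stream_sequences=combo,
                seed=seed,
            )
            cfg = TrainConfig(
                task=task,
                epochs=train_config.epochs,
                learning_rate=train_config.learning_rate,
                seed=seed,
                alpha_policy=train_config.alpha_policy,
                alpha=train_config.alpha,
                clamp_eps=train_config.clamp_eps,
            )
            model = MSKNet(params)
            model, _ = train_model(manifest, volumes, model, cfg)
            report = evaluate_model(model, manifest, volumes, task)
            reports.append(report)
            for metric in ("accuracy", "sensitivity", "specificity"):
                value = getattr(report, metric)
                row[f"{task}_{metric}"] = _round1(value) if value is not None else "NA"
        rows.append(row)
    return pd.DataFrame(rows), reports
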