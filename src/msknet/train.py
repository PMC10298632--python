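"""Training with class-weighted binary cross-entropy.

The objective for one exam is

    L = -alpha * y * log(p) - (1 - y) * log(1 - p)

where ``alpha`` multiplies only the positive term, compensating class
imbalance; by default alpha is the negative/positive count ratio of the
training split, so a rare positive class is up-weighted. Optimization is
plain exam-at-a-time Adam: slice counts vary between exams, so an exam is
the natural batch.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from msknet._nn import Adam
from msknet.dicom_io import TASKS, LabelManifest
from msknet.model import KNet, KNetParams, MSKNet, _sigmoid
from msknet.preprocess import FusedVolume


@dataclass
class TrainConfig:
    task: str = "abnormality"
    epochs: int = 20
    learning_rate: float = 1e-3
    batch: int = 1
    optimizer: str = "adam"
    seed: int = 0
    alpha_policy: str = "auto_neg_over_pos"
    alpha: float | None = None
    clamp_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.alpha_policy not in ("auto_neg_over_pos", "fixed"):
            raise ValueError(f"unknown alpha_policy {self.alpha_policy!r}")
        if self.alpha_policy == "fixed" and (self.alpha is None or self.alpha <= 0):
            raise ValueError("fixed alpha_policy requires alpha > 0")


def weighted_bce(y_hat, y, alpha: float = 1.0, eps: float = 1e-7) -> float:
    """Class-weighted binary cross-entropy, averaged over the batch.

    ``alpha`` scales only the positive (y=1) term. Predictions are clamped
    to [eps, 1-eps] so the loss stays finite.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    y_hat = np.clip(np.asarray(y_hat, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError("y_hat and y must have the same shape")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0 or 1")
    loss = -alpha * y * np.log(y_hat) - (1.0 - y) * np.log(1.0 - y_hat)
    return float(loss.mean())


def bce_grad_logit(p: float, y: int, alpha: float) -> float:
    """d(weighted BCE)/d(logit) for a single example (reduces to p - y at alpha=1)."""
    return -alpha * y * (1.0 - p) + (1 - y) * p


def compute_alpha(manifest: LabelManifest, task: str) -> float:
    """Negative/positive ratio on the training split; errors if a class is absent."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    labels = [r.labels[task] for r in manifest.train_records]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate task {task!r}: training split has {n_pos} positives "
            f"and {n_neg} negatives"
        )
    return n_neg / n_pos


def train_model(
    manifest: LabelManifest,
    volumes: dict[str, dict[str, FusedVolume]],
    model: MSKNet,
    config: TrainConfig,
    train_ids: list[str] | None = None,
) -> tuple[MSKNet, pd.DataFrame]:
    """Optimize ``model`` in place on the manifest's training split.

    ``volumes`` maps exam_id -> sequence_type -> FusedVolume (already
    preprocessed with training-split statistics). The loop never touches a
    test exam: an explicit ``train_ids`` entry that the manifest assigns to
    the test split is a hard error. Returns the model and a per-epoch log
    (epoch, mean_loss, seed); the same seed reproduces the log exactly.
    """
    split = manifest.split
    if train_ids is None:
        train_ids = [r.exam_id for r in manifest.train_records]
    for exam_id in train_ids:
        if split.get(exam_id) != "train":
            raise ValueError(f"exam {exam_id!r} is not in the training split")
        if exam_id not in volumes:
            raise ValueError(f"no preprocessed volumes for train exam {exam_id!r}")
    if not train_ids:
        raise ValueError("empty training set")

    labels = {r.exam_id: r.labels[config.task] for r in manifest.records}
    if config.alpha_policy == "fixed":
        alpha = float(config.alpha)
    else:
        alpha = compute_alpha(manifest, config.task)

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    grads = model.gradients()
    rng = np.random.default_rng(config.seed)
    sequences = model.params_cfg.stream_sequences

    log_rows = []
    for epoch in range(config.epochs):
        order = np.array(train_ids)
        rng.shuffle(order)
        losses = []
        for exam_id in order:
            streams = {seq: volumes[exam_id][seq] for seq in sequences}
            y = labels[exam_id]
            logit = model.forward_logit(streams)
            p = _sigmoid(logit)
            losses.append(weighted_bce(np.array([p]), np.array([y]), alpha, config.clamp_eps))
            Adam.zero_grads(grads)
            model.backward(bce_grad_logit(p, y, alpha))
            optimizer.step(grads)
        log_rows.append(
            {"epoch": epoch, "mean_loss": float(np.mean(losses)), "seed": config.seed}
        )
    return model, pd.DataFrame(log_rows)


def save_checkpoint(
    model: MSKNet, path: str | os.PathLike, stats_fingerprint: str = ""
) -> Path:
    """Write weights (.npz) plus a JSON sidecar with config and stats fingerprint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = {k.replace("/", "_"): v for k, v in model.parameters().items()}
    np.savez(path, **flat)
    cfg = asdict(model.params_cfg)
    cfg["spatial_out"] = list(cfg["spatial_out"])
    cfg["stream_sequences"] = list(cfg["stream_sequences"])
    meta = {"params": cfg, "stats_fingerprint": stats_fingerprint}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_checkpoint(path: str | os.PathLike) -> tuple[MSKNet, str]:
    """Rebuild the model from a checkpoint; returns (model, stats fingerprint)."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    cfg = meta["params"]
    params = KNetParams(
        backbone=cfg["backbone"],
        feature_channels=cfg["feature_channels"],
        spatial_out=tuple(cfg["spatial_out"]),
        embed_dim=cfg["embed_dim"],
        n_streams=cfg["n_streams"],
        stream_sequences=tuple(cfg["stream_sequences"]),
        seed=cfg["seed"],
    )
    model = KNet(params) if params.n_streams == 1 else MSKNet(params)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
        model.set_parameters({k: data[k] for k in data.files})
    return model, meta["stats_fingerprint"]
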