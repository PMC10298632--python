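"""Glue between modules: cohort-level preprocessing in memory and on disk.

Normalization statistics are always fitted on the training split only and
travel with the produced volumes (and later with checkpoints) as a
fingerprint string, so a model can refuse data preprocessed under different
statistics.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

from msknet.dicom_io import (
    LabelManifest,
    MRISeries,
    load_manifest,
    read_series,
    resize_series,
)
from msknet.preprocess import (
    FULL_RANGE,
    FusedVolume,
    IntensityWindow,
    NormStats,
    fit_norm_stats,
    fuse,
    load_fused,
    save_fused,
)
from msknet.synthetic_phantom import PhantomExam

Volumes = dict[str, dict[str, FusedVolume]]


def fuse_cohort(
    exams: list[PhantomExam],
    manifest: LabelManifest,
    window: IntensityWindow = FULL_RANGE,
    sequence_types: tuple[str, ...] | None = None,
) -> tuple[Volumes, NormStats]:
    """Resize, window, normalize and fuse a generated cohort in memory.

    Statistics come from the training split's windowed pixels only.
    """
    train_ids = {r.exam_id for r in manifest.train_records}
    resized: dict[str, dict[str, MRISeries]] = {}
    for exam in exams:
        resized[exam.exam_id] = {}
        for seq, series in exam.series.items():
            if sequence_types is not None and seq not in sequence_types:
                continue
            resized[exam.exam_id][seq] = resize_series(series, 224)
    train_series = [
        s for exam_id, by_seq in resized.items() if exam_id in train_ids
        for s in by_seq.values()
    ]
    stats = fit_norm_stats(train_series, window=window, source="train")
    del train_series
    volumes: Volumes = {}
    for exam_id in list(resized):
        by_seq = resized.pop(exam_id)  # release float64 intermediates as we go
        volumes[exam_id] = {seq: fuse(series, stats) for seq, series in by_seq.items()}
    return volumes, stats


def preprocess_directory(
    data_dir: str | os.PathLike,
    out_dir: str | os.PathLike,
    window: IntensityWindow = FULL_RANGE,
) -> tuple[Volumes, NormStats]:
    """Disk pipeline: read the DICOM tree + manifest, fuse, persist volumes.

    ``data_dir`` must contain ``manifest.csv`` whose per-sequence columns
    point at series directories. Writes one .npy/.json pair per series and
    a cohort-level ``stats.json`` into ``out_dir``.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    manifest = load_manifest(data_dir / "manifest.csv")
    train_ids = {r.exam_id for r in manifest.train_records}

    resized: dict[str, dict[str, MRISeries]] = {}
    for rec in manifest.records:
        resized[rec.exam_id] = {}
        for seq, rel_path in rec.series_paths.items():
            series_path = Path(rel_path)
            if not series_path.is_absolute():
                series_path = data_dir / series_path
            series = read_series(series_path, sequence_type=seq)
            series.exam_id = rec.exam_id
            resized[rec.exam_id][seq] = resize_series(series, 224)

    train_series = [
        s for exam_id, by_seq in resized.items() if exam_id in train_ids
        for s in by_seq.values()
    ]
    stats = fit_norm_stats(train_series, window=window, source="train")

    out_dir.mkdir(parents=True, exist_ok=True)
    volumes: Volumes = {}
    for exam_id, by_seq in resized.items():
        volumes[exam_id] = {}
        for seq, series in by_seq.items():
            volume = fuse(series, stats)
            save_fused(volume, stats, out_dir)
            volumes[exam_id][seq] = volume
    (out_dir / "stats.json").write_text(
        json.dumps(
            {
                "fingerprint": stats.fingerprint(),
                "mean": stats.mean,
                "sd": stats.sd,
                "window": [stats.window.low, stats.window.high],
                "source": stats.source,
            },
            indent=1,
        )
    )
    return volumes, stats


def load_feature_dir(features_dir: str | os.PathLike) -> tuple[Volumes, str]:
    """Load every fused volume written by :func:`preprocess_directory`."""
    features_dir = Path(features_dir)
    fingerprint = json.loads((features_dir / "stats.json").read_text())["fingerprint"]
    volumes: Volumes = {}
    for npy_path in sorted(features_dir.glob("*.npy")):
        volume, fp = load_fused(npy_path)
        if fp != fingerprint:
            raise ValueError(f"{npy_path.name} was preprocessed with different statistics")
        volumes.setdefault(volume.exam_id, {})[volume.sequence_type] = volume
    if not volumes:
        raise ValueError(f"no fused volumes found in {features_dir}")
    return volumes, fingerprint
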