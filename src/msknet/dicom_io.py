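"""DICOM series I/O, spatial resizing, and the exam/label manifest.

A knee MRI exam is a set of series, one per acquisition sequence
(coronal hybrid, axial T2, sagittal T1, sagittal T2), each a stack of
``s`` grayscale slices. Series are read into ``MRISeries`` containers
with slices ordered by InstanceNumber, rescale slope/intercept applied,
and are resized to the model's fixed 224x224 spatial grid. Exam-level
binary labels (abnormality, meniscus tear, bone edema) live in a CSV
manifest alongside the train/test split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pydicom
from skimage.transform import resize as _sk_resize

#: Canonical sequence-type tokens, in manifest column order.
SEQUENCE_TYPES: tuple[str, ...] = (
    "coronal_hybrid",
    "axial_t2",
    "sagittal_t1",
    "sagittal_t2",
)

#: The three binary classification tasks.
TASKS: tuple[str, ...] = ("abnormality", "meniscus", "bone_edema")

_MANIFEST_COLUMNS = ["exam_id", "patient_id", "split"] + list(SEQUENCE_TYPES) + list(TASKS)


@dataclass
class MRISeries:
    """One sequence's slice stack: ``pixels`` has shape ``s x h x w``."""

    exam_id: str
    sequence_type: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be 3-D (s,h,w), got {self.pixels.shape}")
        if self.s < 1:
            raise ValueError("series must contain at least one slice")
        if self.sequence_type not in SEQUENCE_TYPES:
            raise ValueError(f"unknown sequence_type {self.sequence_type!r}")

    @property
    def s(self) -> int:
        return self.pixels.shape[0]

    @property
    def h(self) -> int:
        return self.pixels.shape[1]

    @property
    def w(self) -> int:
        return self.pixels.shape[2]


@dataclass
class ExamRecord:
    """Manifest row: one exam with its per-sequence paths and task labels."""

    exam_id: str
    patient_id: str
    series_paths: dict[str, str] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for task, value in self.labels.items():
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
            if value not in (0, 1):
                raise ValueError(f"label for {task!r} must be 0 or 1, got {value!r}")
        for seq in self.series_paths:
            if seq not in SEQUENCE_TYPES:
                raise ValueError(f"unknown sequence_type {seq!r}")
        # An exam with a torn meniscus or bone edema is by definition abnormal.
        if (self.labels.get("meniscus") == 1 or self.labels.get("bone_edema") == 1) and (
            self.labels.get("abnormality") != 1
        ):
            raise ValueError(
                f"exam {self.exam_id}: abnormality=0 is inconsistent with a "
                "positive meniscus/bone_edema label"
            )


@dataclass
class LabelManifest:
    """All exam records plus the train/test split assignment."""

    records: list[ExamRecord]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.exam_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate exam_id in manifest")
        for exam_id, part in self.split.items():
            if part not in ("train", "test"):
                raise ValueError(f"split for {exam_id} must be 'train' or 'test'")
        # At most two exams per patient (one per knee), and a patient's exams
        # never straddle the split — otherwise test performance leaks.
        by_patient: dict[str, list[ExamRecord]] = {}
        for rec in self.records:
            by_patient.setdefault(rec.patient_id, []).append(rec)
        for patient, recs in by_patient.items():
            if len(recs) > 2:
                raise ValueError(f"patient {patient} has {len(recs)} exams (max 2)")
            parts = {self.split.get(r.exam_id) for r in recs}
            if len(parts - {None}) > 1:
                raise ValueError(f"patient {patient} appears in both splits")

    def subset(self, part: str) -> list[ExamRecord]:
        return [r for r in self.records if self.split.get(r.exam_id) == part]

    @property
    def train_records(self) -> list[ExamRecord]:
        return self.subset("train")

    @property
    def test_records(self) -> list[ExamRecord]:
        return self.subset("test")


def read_series(path: str | os.PathLike, sequence_type: str | None = None) -> MRISeries:
    """Read a directory of single-frame DICOM files into an ``MRISeries``.

    Slices are ordered by InstanceNumber (falling back to the position along
    the slice normal when InstanceNumber is absent) and RescaleSlope/Intercept
    are applied. The directory must contain exactly one series.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {path}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"{path} mixes {len(uids)} SeriesInstanceUIDs")

    def sort_key(ds: pydicom.Dataset) -> float:
        if getattr(ds, "InstanceNumber", None) is not None:
            return float(ds.InstanceNumber)
        # Fall back to position along the slice-normal axis.
        ori = np.asarray(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(ori[:3], ori[3:])
        return float(np.dot(normal, np.asarray(ds.ImagePositionPatient, dtype=float)))

    datasets.sort(key=sort_key)

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"{path} has inconsistent slice shapes {shapes}")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)

    if sequence_type is None:
        sequence_type = str(getattr(datasets[0], "SeriesDescription", ""))
    exam_id = str(getattr(datasets[0], "StudyID", "")) or str(
        getattr(datasets[0], "PatientID", "unknown")
    )
    return MRISeries(exam_id=exam_id, sequence_type=sequence_type, pixels=np.stack(slices))


def resize_series(series: MRISeries, size: int = 224) -> MRISeries:
    """Resize every slice to ``size x size`` (bilinear); slice count unchanged."""
    if size <= 0:
        raise ValueError("target size must be positive")
    if series.h < 2 or series.w < 2:
        raise ValueError("slices must be at least 2x2 to resize")
    if (series.h, series.w) == (size, size):
        return MRISeries(series.exam_id, series.sequence_type, series.pixels.copy())
    downscaling = series.h > size or series.w > size
    out = np.empty((series.s, size, size), dtype=np.float64)
    for i in range(series.s):
        out[i] = _sk_resize(
            series.pixels[i],
            (size, size),
            order=1,
            anti_aliasing=downscaling,
            preserve_range=True,
        )
    return MRISeries(series.exam_id, series.sequence_type, out)


def save_manifest(manifest: LabelManifest, path: str | os.PathLike) -> None:
    """Write the manifest as a CSV with one row per exam."""
    rows = []
    for rec in manifest.records:
        row: dict[str, object] = {
            "exam_id": rec.exam_id,
            "patient_id": rec.patient_id,
            "split": manifest.split.get(rec.exam_id, ""),
        }
        for seq in SEQUENCE_TYPES:
            row[seq] = rec.series_paths.get(seq, "")
        for task in TASKS:
            row[task] = rec.labels[task]
        rows.append(row)
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def load_manifest(path: str | os.PathLike) -> LabelManifest:
    """Load a manifest CSV; label-consistency invariants are re-validated."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    records, split = [], {}
    for _, row in df.iterrows():
        labels = {}
        for task in TASKS:
            raw = row[task].strip()
            if raw not in ("0", "1"):
                raise ValueError(f"non-binary label {raw!r} for task {task}")
            labels[task] = int(raw)
        paths = {seq: row[seq] for seq in SEQUENCE_TYPES if row[seq]}
        records.append(
            ExamRecord(
                exam_id=row["exam_id"],
                patient_id=row["patient_id"],
                series_paths=paths,
                labels=labels,
            )
        )
        if row["split"]:
            split[row["exam_id"]] = row["split"]
    return LabelManifest(records=records, split=split)


def make_split(
    records: Iterable[ExamRecord], test_fraction: float, seed: int
) -> dict[str, str]:
    """Assign train/test by patient so no patient straddles the split."""
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError("test_fraction must be in [0, 1]")
    by_patient: dict[str, list[str]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec.exam_id)
    patients = sorted(by_patient)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_exams = sum(len(v) for v in by_patient.values())
    target_test = round(test_fraction * n_exams)
    split: dict[str, str] = {}
    assigned_test = 0
    for patient in patients:
        part = "test" if assigned_test < target_test else "train"
        for exam_id in by_patient[patient]:
            split[exam_id] = part
        if part == "test":
            assigned_test += len(by_patient[patient])
    return split


def _percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, computed exactly."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def summarize_manifest(manifest: LabelManifest) -> pd.DataFrame:
    """Per-split and overall positive counts and percentages for each task.

    Returns a tidy table with columns
    ``split, task, n_exams, positives, percent`` where ``percent`` is
    rounded half-up to one decimal place.
    """
    if not manifest.records:
        raise ValueError("empty manifest")
    groups: Mapping[str, list[ExamRecord]] = {
        "train": manifest.train_records,
        "test": manifest.test_records,
        "overall": manifest.records,
    }
    rows = []
    for name, recs in groups.items():
        if not recs:
            continue
        for task in TASKS:
            pos = sum(r.labels[task] for r in recs)
            rows.append(
                {
                    "split": name,
                    "task": task,
                    "n_exams": len(recs),
                    "positives": pos,
                    "percent": _percent(pos, len(recs)),
                }
            )
    return pd.DataFrame(rows)
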