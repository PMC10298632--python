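"""Synthetic multi-sequence knee-phantom generator.

Produces cohorts of exam-like DICOM series with planted lesion signal so the
preprocessing, model, training and evaluation stages can be exercised without
patient data. The anatomy is a deliberately simple smooth intensity field —
two bone-like ellipses separated by a joint-space band, extruded across
slices with slow through-slice drift — not an anatomically faithful knee.

Lesion conventions:

* meniscus tear  -> crescent-shaped hypointense discontinuity inside the
  joint band, present on at least three consecutive slices;
* bone edema     -> diffuse hyperintense Gaussian blob inside a bone ellipse;
* "other" abnormality -> hyperintense rim segment at the anatomy border,
  planted so the overall abnormality prevalence can exceed the union of the
  two specific lesions (as it does in real cohorts).

Every sequence type of an exam is a deterministic contrast transform of the
same anatomy field plus independent acquisition noise, so multi-stream
fusion can be exercised without registration machinery. A ``signal_sequences``
knob restricts which sequences actually render the lesions, enabling
experiments where only one stream carries class signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import gaussian_filter

from msknet.dicom_io import (
    SEQUENCE_TYPES,
    TASKS,
    ExamRecord,
    LabelManifest,
    MRISeries,
    make_split,
)

# Fixed intensity landmarks of the phantom (arbitrary scanner units).
_BACKGROUND = 100.0
_BONE = 400.0
_BAND = 250.0
_INTENSITY_TOP = 500.0  # window top used by the inverted-contrast transform

_UID_ROOT = "1.2.826.0.1.3680043.10.1457."


@dataclass
class PhantomConfig:
    """Cohort-level knobs of the generator.

    ``lesion_contrast`` is dimensionless: the planted lesion amplitude is
    ``lesion_contrast * noise_sd``, so contrast >= 3 guarantees lesions sit
    well above the acquisition noise floor. Defaults mirror the prevalence
    structure of a realistic knee-MRI cohort (~71% abnormal, ~31% meniscus
    tears, ~29% bone edema, edema in ~29% of torn-meniscus exams).
    """

    n_exams: int = 20
    prevalence_abnormal: float = 0.711
    prevalence_meniscus: float = 0.313
    prevalence_edema: float = 0.287
    co_occurrence_rate: float = 0.294
    slice_range: tuple[int, int] = (14, 56)
    image_size: int = 256
    lesion_contrast: float = 10.0
    noise_sd: float = 10.0
    sequence_types: tuple[str, ...] = SEQUENCE_TYPES
    signal_sequences: tuple[str, ...] | None = None
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise ValueError("n_exams must be >= 1")
        for name in ("prevalence_abnormal", "prevalence_meniscus", "prevalence_edema",
                     "co_occurrence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.slice_range
        if not (14 <= lo <= hi <= 56):
            raise ValueError("slice_range must lie within [14, 56]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for seq in self.sequence_types:
            if seq not in SEQUENCE_TYPES:
                raise ValueError(f"unknown sequence_type {seq!r}")
        if self.signal_sequences is not None:
            for seq in self.signal_sequences:
                if seq not in self.sequence_types:
                    raise ValueError(f"signal sequence {seq!r} not in sequence_types")


@dataclass
class PhantomExam:
    """One generated exam: co-registered series, labels, and lesion masks."""

    exam_id: str
    series: dict[str, MRISeries]
    labels: dict[str, int]
    #: task -> boolean s x h x w mask of the planted lesion (empty if negative);
    #: kept so label/signal coupling is directly assertable.
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)


def _draw_labels(rng: np.random.Generator, cfg: PhantomConfig) -> dict[str, int]:
    meniscus = int(rng.random() < cfg.prevalence_meniscus)
    p_edema = cfg.co_occurrence_rate if meniscus else cfg.prevalence_edema
    edema = int(rng.random() < p_edema)
    # Probability that an exam already carries a specific lesion.
    p_specific = cfg.prevalence_meniscus + (1 - cfg.prevalence_meniscus) * cfg.prevalence_edema
    if p_specific < 1.0:
        p_other = max(0.0, (cfg.prevalence_abnormal - p_specific) / (1.0 - p_specific))
    else:
        p_other = 0.0
    other = 0
    if not (meniscus or edema):
        other = int(rng.random() < p_other)
    return {
        "meniscus": meniscus,
        "bone_edema": edema,
        "abnormality": int(meniscus or edema or other),
        "_other": other,
    }


def _anatomy(rng: np.random.Generator, s: int, n: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Smooth ellipse-and-band field extruded across slices with slow drift.

    Returns the s x n x n anatomy, the anatomy mask, and the geometry dict
    used for lesion placement.
    """
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    # Mild per-exam jitter of the base geometry; kept small so that the
    # dominant between-exam variation is the lesion, not the anatomy.
    cx = 0.5 + rng.uniform(-0.01, 0.01)
    band_y = 0.5 + rng.uniform(-0.01, 0.01)
    band_half = 0.06 + rng.uniform(-0.004, 0.004)
    # Slow sinusoidal through-slice drift of the whole geometry.
    phase = rng.uniform(0, 2 * np.pi)
    drift = 0.01 * np.sin(2 * np.pi * np.arange(s) / max(s, 2) + phase)

    vol = np.empty((s, n, n))
    mask = np.empty((s, n, n), dtype=bool)
    for k in range(s):
        bx = cx + drift[k]
        femur = ((yy - (band_y - band_half - 0.16)) / 0.15) ** 2 + ((xx - bx) / 0.28) ** 2 <= 1.0
        tibia = ((yy - (band_y + band_half + 0.16)) / 0.15) ** 2 + ((xx - bx) / 0.28) ** 2 <= 1.0
        band = (np.abs(yy - band_y) <= band_half) & (np.abs(xx - bx) <= 0.26)
        img = np.full((n, n), _BACKGROUND)
        img[femur | tibia] = _BONE
        img[band] = _BAND
        vol[k] = gaussian_filter(img, sigma=n / 96.0)
        mask[k] = femur | tibia | band
    geom = {"cx": cx, "band_y": band_y, "band_half": band_half, "drift": drift}
    return vol, mask, geom


def _lesion_slices(rng: np.random.Generator, s: int) -> slice:
    """A run of consecutive slices, >= 3 and covering most of the stack.

    Real tears and edema are visible across a large contiguous portion of
    the stack; lesions here span between ~60% and all slices (never fewer
    than three), uniformly placed.
    """
    low = max(3, int(np.ceil(0.6 * s)))
    length = int(rng.integers(low, s + 1))
    start = int(rng.integers(0, s - length + 1))
    return slice(start, start + length)


def _meniscus_lesion(
    rng: np.random.Generator, s: int, n: int, geom: dict, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Crescent-shaped hypointense discontinuity inside the joint band."""
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    sl = _lesion_slices(rng, s)
    side = rng.choice([-1.0, 1.0])
    lx = geom["cx"] + side * rng.uniform(0.05, 0.12)
    ly = geom["band_y"]
    r_outer = 0.15
    outer = (yy - ly) ** 2 + (xx - lx) ** 2 <= r_outer**2
    inner = (yy - ly) ** 2 + (xx - (lx + side * 0.07)) ** 2 <= (0.7 * r_outer) ** 2
    crescent = outer & ~inner
    delta = np.zeros((s, n, n))
    mask = np.zeros((s, n, n), dtype=bool)
    for k in range(sl.start, sl.stop):
        bx_shift = geom["drift"][k]
        rolled = np.roll(crescent, int(round(bx_shift * n)), axis=1)
        delta[k][rolled] = -amplitude
        mask[k] = rolled
    return delta, mask


def _edema_lesion(
    rng: np.random.Generator, s: int, n: int, geom: dict, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse hyperintense Gaussian blob inside a bone ellipse."""
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    sl = _lesion_slices(rng, s)
    above = rng.choice([True, False])  # femur or tibia
    offset = geom["band_half"] + 0.16
    ly = geom["band_y"] + (-offset if above else offset) + rng.uniform(-0.05, 0.05)
    lx = geom["cx"] + rng.uniform(-0.10, 0.10)
    sigma = rng.uniform(0.08, 0.12)
    blob = np.exp(-(((yy - ly) ** 2 + (xx - lx) ** 2) / (2 * sigma**2)))
    delta = np.zeros((s, n, n))
    mask = np.zeros((s, n, n), dtype=bool)
    for k in range(sl.start, sl.stop):
        rolled = np.roll(blob, int(round(geom["drift"][k] * n)), axis=1)
        delta[k] += amplitude * rolled
        mask[k] = rolled > 0.25
    return delta, mask


def _other_lesion(
    rng: np.random.Generator, s: int, n: int, geom: dict, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hyperintense rim segment at the joint margin (effusion-like)."""
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    sl = _lesion_slices(rng, s)
    side = rng.choice([-1.0, 1.0])
    lx = geom["cx"] + side * 0.30
    ly = geom["band_y"] + rng.uniform(-0.1, 0.1)
    rim = ((yy - ly) ** 2 + ((xx - lx) / 0.35) ** 2 <= 0.12**2)
    delta = np.zeros((s, n, n))
    mask = np.zeros((s, n, n), dtype=bool)
    for k in range(sl.start, sl.stop):
        delta[k][rim] = amplitude
        mask[k] = rim
    return delta, mask


def _sequence_transform(seq: str, anatomy: np.ndarray) -> np.ndarray:
    """Deterministic per-sequence contrast transform of the shared anatomy."""
    if seq == "sagittal_t1":
        return anatomy
    if seq == "axial_t2":
        return np.clip(_INTENSITY_TOP - anatomy, 0.0, None)
    if seq == "coronal_hybrid":
        return 0.5 * (anatomy + np.clip(_INTENSITY_TOP - anatomy, 0.0, None))
    if seq == "sagittal_t2":
        # Affine contrast stretch distinct from T1 but monotone in the anatomy.
        return 0.6 * anatomy + 120.0
    raise ValueError(f"unknown sequence_type {seq!r}")


def generate_cohort(config: PhantomConfig) -> tuple[list[PhantomExam], LabelManifest]:
    """Generate ``config.n_exams`` phantom exams plus their label manifest.

    The output is a pure function of ``config`` (including ``config.seed``):
    the same configuration yields bit-identical pixel arrays and labels.
    Pixel values are pre-quantized to integers so the DICOM writer's uint16
    round trip is lossless.
    """
    rng = np.random.default_rng(config.seed)
    amplitude = config.lesion_contrast * config.noise_sd
    signal = (
        set(config.sequence_types)
        if config.signal_sequences is None
        else set(config.signal_sequences)
    )
    exams: list[PhantomExam] = []
    records: list[ExamRecord] = []
    for idx in range(config.n_exams):
        exam_id = f"phantom-{idx:04d}"
        labels = _draw_labels(rng, config)
        s = int(rng.integers(config.slice_range[0], config.slice_range[1] + 1))
        n = config.image_size
        anatomy, _mask, geom = _anatomy(rng, s, n)

        lesion_total = np.zeros_like(anatomy)
        masks: dict[str, np.ndarray] = {}
        if labels["meniscus"]:
            delta, m = _meniscus_lesion(rng, s, n, geom, amplitude)
            lesion_total += delta
            masks["meniscus"] = m
        if labels["bone_edema"]:
            delta, m = _edema_lesion(rng, s, n, geom, amplitude)
            lesion_total += delta
            masks["bone_edema"] = m
        if labels["_other"]:
            delta, m = _other_lesion(rng, s, n, geom, amplitude)
            lesion_total += delta
            masks["abnormality"] = m
        if "abnormality" not in masks and masks:
            masks["abnormality"] = np.any([m for m in masks.values()], axis=0)
        # Partial-volume effect: lesion boundaries are as soft as the anatomy's.
        if masks:
            lesion_total = gaussian_filter(lesion_total, sigma=(0.0, n / 96.0, n / 96.0))

        series: dict[str, MRISeries] = {}
        for seq in config.sequence_types:
            base = anatomy + lesion_total if seq in signal else anatomy
            img = _sequence_transform(seq, base)
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
            img = np.round(np.clip(img, 0.0, 65535.0))
            series[seq] = MRISeries(exam_id=exam_id, sequence_type=seq, pixels=img)

        task_labels = {t: labels[t] for t in TASKS}
        exams.append(
            PhantomExam(exam_id=exam_id, series=series, labels=task_labels, lesion_masks=masks)
        )
        records.append(
            ExamRecord(
                exam_id=exam_id,
                patient_id=f"P{idx:04d}",
                series_paths={},
                labels=task_labels,
            )
        )

    split = make_split(records, config.test_fraction, seed=int(rng.integers(2**31)))
    return exams, LabelManifest(records=records, split=split)


def write_dicom(exam: PhantomExam, out_dir: str | os.PathLike) -> list[Path]:
    """Write one DICOM Part 10 file per slice per series under ``out_dir``.

    Layout: ``out_dir/<exam_id>/<sequence_type>/slice_NNN.dcm``; monotone
    InstanceNumber, one SeriesInstanceUID per sequence. Returns all paths.
    """
    out_dir = Path(out_dir)
    paths: list[Path] = []
    study_uid = generate_uid(prefix=_UID_ROOT, entropy_srcs=[exam.exam_id])
    for seq, series in exam.series.items():
        series_dir = out_dir / exam.exam_id / seq
        series_dir.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid(prefix=_UID_ROOT, entropy_srcs=[exam.exam_id, seq])
        arr = series.pixels
        if arr.min() < 0 or arr.max() > 65535 or not np.allclose(arr, np.round(arr)):
            raise ValueError("phantom pixels must be integers in [0, 65535]")
        for i in range(series.s):
            ds = pydicom.Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
                prefix=_UID_ROOT, entropy_srcs=[exam.exam_id, seq, str(i)]
            )
            ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.StudyID = exam.exam_id
            ds.PatientID = exam.exam_id
            ds.PatientName = exam.exam_id
            ds.Modality = "MR"
            ds.SeriesDescription = seq
            ds.InstanceNumber = i + 1
            ds.ImagePositionPatient = [0.0, 0.0, float(i) * 4.0]
            ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
            ds.PixelSpacing = [0.5, 0.5]
            ds.SliceThickness = 4.0
            ds.Rows, ds.Columns = series.h, series.w
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = 0.0
            ds.PixelData = arr[i].astype(np.uint16).tobytes()
            path = series_dir / f"slice_{i + 1:03d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths
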