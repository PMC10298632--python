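"""Feature-fusion preprocessing.

The pipeline per series: zero pixels outside a configurable intensity
range of interest, z-normalize with mean/sd fitted on the windowed pixels
of the whole training split (z = (x - x̄)/σ), and stack three channels per
slice — the normalized original, a local-binary-pattern texture map, and
the low-pass (LL) subband of a single-level Haar wavelet transform — into
an ``s x 3 x 224 x 224`` fused volume.

LBP and DWT are computed on the windowed, pre-normalization image; LBP is
insensitive to the affine rescaling either way, and the Haar transform is
linear so the choice only affects the channel scale, which is harmonized by
per-slice standardization of channels 1-2.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from skimage.transform import resize as _sk_resize

from msknet.dicom_io import MRISeries

logger = logging.getLogger(__name__)

#: Clockwise neighbor offsets starting at the top-left pixel; the first
#: offset maps to the most significant bit of the 8-bit code.
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass(frozen=True)
class IntensityWindow:
    """Range of interest [low, high]; pixels outside are zeroed."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window low ({self.low}) must be < high ({self.high})")


#: Permissive default: keeps every pixel a 16-bit scanner can produce.
FULL_RANGE = IntensityWindow(low=0.0, high=65535.0)


@dataclass(frozen=True)
class NormStats:
    """Training-split normalization statistics (x̄ and σ) plus their window."""

    mean: float
    sd: float
    window: IntensityWindow = FULL_RANGE
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def fingerprint(self) -> str:
        return (
            f"mean={self.mean:.9g};sd={self.sd:.9g};"
            f"window=[{self.window.low:.9g},{self.window.high:.9g}]"
        )


@dataclass
class FusedVolume:
    """Preprocessed stack: channel 0 = normalized original, 1 = LBP, 2 = DWT.

    Stored as float32: preprocessing is computed in float64 and cast once,
    halving the memory footprint of a cohort held in RAM.
    """

    exam_id: str
    sequence_type: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[1:] != (3, 224, 224):
            raise ValueError(f"fused volume must be s x 3 x 224 x 224, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fused volume contains non-finite values")

    @property
    def s(self) -> int:
        return self.data.shape[0]


def apply_window(series: MRISeries, window: IntensityWindow) -> MRISeries:
    """Zero every pixel strictly outside [low, high]; in-range pixels unchanged."""
    x = series.pixels
    out = np.where((x < window.low) | (x > window.high), 0.0, x)
    return MRISeries(series.exam_id, series.sequence_type, out)


def fit_norm_stats(
    training_series: list[MRISeries],
    window: IntensityWindow = FULL_RANGE,
    source: str = "train",
) -> NormStats:
    """Mean and population sd over all windowed pixels of the training split.

    Zeroed out-of-window pixels are included, matching what the network sees.
    Raises on a constant (zero-variance) training set.
    """
    if not training_series:
        raise ValueError("need at least one training series")
    total = 0
    acc = 0.0
    acc_sq = 0.0
    for series in training_series:
        x = apply_window(series, window).pixels
        total += x.size
        acc += float(x.sum())
        acc_sq += float(np.square(x).sum())
    mean = acc / total
    var = acc_sq / total - mean**2
    sd = float(np.sqrt(max(var, 0.0)))
    if sd <= 0.0:
        raise ValueError("degenerate training set: windowed pixels are constant (sd = 0)")
    return NormStats(mean=mean, sd=sd, window=window, source=source)


def normalize(series: MRISeries, stats: NormStats) -> MRISeries:
    """z = (x - mean) / sd, applied pixelwise."""
    z = (series.pixels - stats.mean) / stats.sd
    return MRISeries(series.exam_id, series.sequence_type, z)


def lbp_map(slice2d: np.ndarray) -> np.ndarray:
    """Classic 8-neighbor radius-1 local binary pattern of one slice.

    Bit ``b`` of the code (MSB first) is set iff the corresponding neighbor
    — taken clockwise starting at the top-left pixel — is >= the center.
    Borders are handled by edge replication; codes lie in [0, 255]. A
    constant image therefore maps to the all-ties code 255.
    """
    x = np.asarray(slice2d, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"lbp_map expects a 2-D slice, got shape {x.shape}")
    padded = np.pad(x, 1, mode="edge")
    h, w = x.shape
    code = np.zeros((h, w), dtype=np.uint8)
    for bit, (dy, dx) in enumerate(_LBP_OFFSETS):
        neighbor = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        code |= ((neighbor >= x).astype(np.uint8)) << (7 - bit)
    return code


def haar_subbands(slice2d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-level orthonormal 2-D Haar decomposition: (LL, LH, HL, HH)."""
    x = np.asarray(slice2d, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {x.shape}")
    if x.shape[0] % 2 or x.shape[1] % 2:
        raise ValueError(f"Haar DWT requires even spatial dimensions, got {x.shape}")
    ll, (lh, hl, hh) = pywt.dwt2(x, "haar")
    return ll, lh, hl, hh


def dwt_map(slice2d: np.ndarray) -> np.ndarray:
    """Low-pass (LL) Haar subband of one slice, upsampled back to input size.

    The orthonormal Haar LL of a constant image valued ``c`` is the constant
    ``2c``; no rescaling is applied, channel harmonization happens in
    :func:`fuse`.
    """
    ll, _, _, _ = haar_subbands(slice2d)
    h, w = np.asarray(slice2d).shape
    return _sk_resize(ll, (h, w), order=1, anti_aliasing=False, preserve_range=True)


def _standardize_slice(channel: np.ndarray) -> np.ndarray:
    """Zero-mean unit-sd per slice; constant slices fall back to zeros."""
    mean = channel.mean()
    sd = channel.std()
    if sd == 0.0:
        logger.warning("constant texture channel; falling back to zeros")
        return np.zeros_like(channel, dtype=np.float64)
    return (channel - mean) / sd


def fuse(series: MRISeries, stats: NormStats) -> FusedVolume:
    """Stack normalized original + LBP + DWT channels into s x 3 x 224 x 224.

    The series must already be resized to 224 x 224. Channel 0 is the
    windowed, z-normalized image; channels 1 and 2 are the LBP and DWT maps
    of the windowed (pre-normalization) image, each standardized per slice.
    """
    if (series.h, series.w) != (224, 224):
        raise ValueError(f"fuse expects 224 x 224 slices, got {series.h} x {series.w}")
    windowed = apply_window(series, stats.window)
    normalized = normalize(windowed, stats)
    out = np.empty((series.s, 3, 224, 224), dtype=np.float64)
    for i in range(series.s):
        out[i, 0] = normalized.pixels[i]
        out[i, 1] = _standardize_slice(lbp_map(windowed.pixels[i]).astype(np.float64))
        out[i, 2] = _standardize_slice(dwt_map(windowed.pixels[i]))
    return FusedVolume(exam_id=series.exam_id, sequence_type=series.sequence_type, data=out)


def save_fused(volume: FusedVolume, stats: NormStats, directory: str | os.PathLike) -> Path:
    """Persist a fused volume as .npy with a JSON sidecar; returns the .npy path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{volume.exam_id}_{volume.sequence_type}"
    npy_path = directory / f"{stem}.npy"
    np.save(npy_path, volume.data)
    sidecar = {
        "exam_id": volume.exam_id,
        "sequence_type": volume.sequence_type,
        "stats_fingerprint": stats.fingerprint(),
        "mean": stats.mean,
        "sd": stats.sd,
        "window": [stats.window.low, stats.window.high],
        "source": stats.source,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return npy_path


def load_fused(npy_path: str | os.PathLike) -> tuple[FusedVolume, str]:
    """Load a fused volume and the fingerprint of the stats that produced it."""
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    data = np.load(npy_path)
    volume = FusedVolume(
        exam_id=meta["exam_id"], sequence_type=meta["sequence_type"], data=data
    )
    return volume, meta["stats_fingerprint"]
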