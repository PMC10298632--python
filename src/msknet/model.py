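"""KNet and MS-KNet: slice-aggregating CNN classifiers for MRI stacks.

KNet processes one fused volume (s x 3 x 224 x 224): a convolutional
backbone extracts per-slice features (s x 256 x 7 x 7), spatial average
pooling reduces them to s x 256, a learned linear score plus softmax over
slices forms attention weights, and the weighted sum is a 256-dim exam
embedding fed to a linear + logistic head. The slice count s is free, so
exams with anywhere from a handful to dozens of slices share one model.

MS-KNet runs one backbone+attention branch per input sequence (up to
three), averages the branch embeddings, and applies a single shared head —
fusion happens before classification.

Backbones:

* ``tiny_cnn``           — three strided conv/ReLU stages straight to
                           256 x 7 x 7; small enough to train on a CPU.
* ``alexnet_random``     — the stock five-conv AlexNet feature stack
                           (randomly initialized) with adaptive average
                           pooling from 6x6 to the 7x7 contract.
* ``alexnet_pretrained`` — requires downloaded ImageNet weights, which this
                           package does not bundle; constructing it raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from msknet._nn import AdaptiveAvgPool2d, Conv2d, MaxPool2d, ReLU, Sequential
from msknet.dicom_io import SEQUENCE_TYPES
from msknet.preprocess import FusedVolume

BACKBONES = ("tiny_cnn", "alexnet_random", "alexnet_pretrained")


@dataclass
class KNetParams:
    """Model configuration shared by KNet and MS-KNet."""

    backbone: str = "tiny_cnn"
    feature_channels: int = 256
    spatial_out: tuple[int, int] = (7, 7)
    embed_dim: int = 256
    n_streams: int = 1
    stream_sequences: tuple[str, ...] = ("sagittal_t1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.n_streams not in (1, 2, 3):
            raise ValueError("n_streams must be 1, 2, or 3")
        if len(self.stream_sequences) != self.n_streams:
            raise ValueError("stream_sequences length must equal n_streams")
        for seq in self.stream_sequences:
            if seq not in SEQUENCE_TYPES:
                raise ValueError(f"unknown sequence_type {seq!r}")


@dataclass
class Prediction:
    """Probability plus the hard label at the fixed 0.5 threshold."""

    probability: float
    label: int = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        # Ties at exactly 0.5 resolve to the positive class.
        self.label = int(self.probability >= 0.5)


def _build_backbone(params: KNetParams, rng: np.random.Generator) -> Sequential:
    if params.backbone == "tiny_cnn":
        return Sequential(
            [
                Conv2d(3, 16, kernel=8, stride=8, rng=rng),
                ReLU(),
                Conv2d(16, 64, kernel=2, stride=2, rng=rng),
                ReLU(),
                Conv2d(64, params.feature_channels, kernel=2, stride=2, rng=rng),
                ReLU(),
                AdaptiveAvgPool2d(params.spatial_out),
            ]
        )
    if params.backbone == "alexnet_random":
        return Sequential(
            [
                Conv2d(3, 64, kernel=11, stride=4, padding=2, rng=rng),
                ReLU(),
                MaxPool2d(kernel=3, stride=2),
                Conv2d(64, 192, kernel=5, stride=1, padding=2, rng=rng),
                ReLU(),
                MaxPool2d(kernel=3, stride=2),
                Conv2d(192, 384, kernel=3, stride=1, padding=1, rng=rng),
                ReLU(),
                Conv2d(384, params.feature_channels, kernel=3, stride=1, padding=1, rng=rng),
                ReLU(),
                Conv2d(params.feature_channels, params.feature_channels, kernel=3, stride=1,
                       padding=1, rng=rng),
                ReLU(),
                MaxPool2d(kernel=3, stride=2),
                AdaptiveAvgPool2d(params.spatial_out),
            ]
        )
    raise RuntimeError(
        "alexnet_pretrained needs ImageNet weights, which are not bundled; "
        "use 'alexnet_random' or 'tiny_cnn'"
    )


class _Branch:
    """Backbone + spatial pooling + softmax slice attention for one stream."""

    def __init__(self, params: KNetParams, rng: np.random.Generator) -> None:
        self.params_cfg = params
        self.backbone = _build_backbone(params, rng)
        d = params.embed_dim
        self.attn_w = rng.normal(0.0, 1.0 / np.sqrt(d), size=d)
        self.attn_b = np.zeros(1)
        self.attn_w_grad = np.zeros_like(self.attn_w)
        self.attn_b_grad = np.zeros_like(self.attn_b)
        self._cache: dict | None = None

    # ---- forward pieces -------------------------------------------------
    def extract_slice_features(self, volume: FusedVolume) -> np.ndarray:
        feats = self.backbone.forward(volume.data)
        expected = (volume.s, self.params_cfg.feature_channels, *self.params_cfg.spatial_out)
        if feats.shape != expected:
            raise ValueError(f"backbone produced {feats.shape}, expected {expected}")
        return feats

    @staticmethod
    def pool_slices(features: np.ndarray) -> np.ndarray:
        if features.ndim != 4:
            raise ValueError(f"expected s x C x H x W features, got {features.shape}")
        return features.mean(axis=(2, 3))

    def aggregate_slices(self, pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Softmax-attention weighted sum over slices -> (embedding, weights)."""
        if pooled.ndim != 2 or pooled.shape[0] < 1:
            raise ValueError(f"expected s x d pooled features with s >= 1, got {pooled.shape}")
        scores = pooled @ self.attn_w + self.attn_b[0]
        scores = scores - scores.max()
        weights = np.exp(scores)
        weights /= weights.sum()
        return weights @ pooled, weights

    def forward(self, volume: FusedVolume) -> np.ndarray:
        feats = self.extract_slice_features(volume)
        pooled = self.pool_slices(feats)
        embedding, weights = self.aggregate_slices(pooled)
        self._cache = {"pooled": pooled, "weights": weights, "feat_shape": feats.shape}
        return embedding

    # ---- backward -------------------------------------------------------
    def backward(self, d_embedding: np.ndarray) -> None:
        cache = self._cache
        pooled, weights = cache["pooled"], cache["weights"]
        # embedding = sum_i a_i * pooled_i
        d_pooled = weights[:, None] * d_embedding[None, :]
        d_weights = pooled @ d_embedding
        # softmax backward
        d_scores = weights * (d_weights - float(weights @ d_weights))
        self.attn_w_grad += pooled.T @ d_scores
        self.attn_b_grad += d_scores.sum(keepdims=True)
        d_pooled += d_scores[:, None] * self.attn_w[None, :]
        # undo spatial mean pooling
        s, c, h, w = cache["feat_shape"]
        d_feats = np.broadcast_to(d_pooled[:, :, None, None] / (h * w), (s, c, h, w))
        self.backbone.backward(np.ascontiguousarray(d_feats))

    # ---- parameter access ----------------------------------------------
    def named_params(self, prefix: str) -> dict[str, np.ndarray]:
        out = self.backbone.named_params(f"{prefix}.backbone")
        out[f"{prefix}.attn.w"] = self.attn_w
        out[f"{prefix}.attn.b"] = self.attn_b
        return out

    def named_grads(self, prefix: str) -> dict[str, np.ndarray]:
        out = self.backbone.named_grads(f"{prefix}.backbone")
        out[f"{prefix}.attn.w"] = self.attn_w_grad
        out[f"{prefix}.attn.b"] = self.attn_b_grad
        return out


class _Head:
    """Linear embed_dim -> 1 with logistic output."""

    def __init__(self, embed_dim: int, rng: np.random.Generator) -> None:
        self.w = rng.normal(0.0, 1.0 / np.sqrt(embed_dim), size=embed_dim)
        self.b = np.zeros(1)
        self.w_grad = np.zeros_like(self.w)
        self.b_grad = np.zeros_like(self.b)
        self._z: np.ndarray | None = None

    def forward(self, z: np.ndarray) -> float:
        self._z = z
        return float(z @ self.w + self.b[0])

    def backward(self, d_logit: float) -> np.ndarray:
        self.w_grad += d_logit * self._z
        self.b_grad += d_logit
        return d_logit * self.w


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


class MSKNet:
    """Multi-stream KNet: one branch per sequence, mean-fused, shared head."""

    def __init__(self, params: KNetParams) -> None:
        self.params_cfg = params
        rng = np.random.default_rng(params.seed)
        self.branches: dict[str, _Branch] = {
            seq: _Branch(params, rng) for seq in params.stream_sequences
        }
        self.head = _Head(params.embed_dim, rng)

    # ---- forward --------------------------------------------------------
    def forward_logit(self, streams: dict[str, FusedVolume]) -> float:
        for seq in self.params_cfg.stream_sequences:
            if seq not in streams:
                raise ValueError(f"missing stream {seq!r}")
        embeddings = [
            self.branches[seq].forward(streams[seq])
            for seq in self.params_cfg.stream_sequences
        ]
        fused = np.mean(embeddings, axis=0)
        self._fused = fused
        return self.head.forward(fused)

    def forward(self, streams: dict[str, FusedVolume]) -> Prediction:
        return Prediction(probability=_sigmoid(self.forward_logit(streams)))

    # ---- backward -------------------------------------------------------
    def backward(self, d_logit: float) -> None:
        d_fused = self.head.backward(d_logit)
        share = d_fused / len(self.branches)
        for seq in self.params_cfg.stream_sequences:
            self.branches[seq].backward(share)

    # ---- parameters -----------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for seq, branch in self.branches.items():
            out.update(branch.named_params(f"branch.{seq}"))
        out["head.w"] = self.head.w
        out["head.b"] = self.head.b
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for seq, branch in self.branches.items():
            out.update(branch.named_grads(f"branch.{seq}"))
        out["head.w"] = self.head.w_grad
        out["head.b"] = self.head.b_grad
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for key, arr in values.items():
            params[key][...] = arr


class KNet(MSKNet):
    """Single-stream KNet; a one-branch MS-KNet with a convenience API."""

    def __init__(self, params: KNetParams) -> None:
        if params.n_streams != 1:
            raise ValueError("KNet is single-stream; use MSKNet for n_streams > 1")
        super().__init__(params)

    @property
    def branch(self) -> _Branch:
        return next(iter(self.branches.values()))

    def forward_volume(self, volume: FusedVolume) -> tuple[Prediction, np.ndarray]:
        seq = self.params_cfg.stream_sequences[0]
        logit = self.forward_logit({seq: volume})
        return Prediction(probability=_sigmoid(logit)), self._fused


# ---- module-level operations -------------------------------------------

def extract_slice_features(volume: FusedVolume, model: MSKNet, stream: str | None = None
                           ) -> np.ndarray:
    """Per-slice backbone features, shape s x 256 x 7 x 7 (no cross-slice mixing)."""
    stream = stream or model.params_cfg.stream_sequences[0]
    return model.branches[stream].extract_slice_features(volume)


def pool_slices(features: np.ndarray) -> np.ndarray:
    """Mean over the spatial grid per channel per slice: s x C x H x W -> s x C."""
    return _Branch.pool_slices(features)


def aggregate_slices(pooled: np.ndarray, model: MSKNet, stream: str | None = None
                     ) -> np.ndarray:
    """Attention-weighted slice aggregation to the 256-dim exam embedding."""
    stream = stream or model.params_cfg.stream_sequences[0]
    embedding, _ = model.branches[stream].aggregate_slices(pooled)
    return embedding


def forward_knet(volume: FusedVolume, model: KNet) -> tuple[Prediction, np.ndarray]:
    """Full single-stream forward pass -> (Prediction, exam embedding)."""
    return model.forward_volume(volume)


def forward_msknet(streams: dict[str, FusedVolume], model: MSKNet) -> Prediction:
    """Multi-stream forward pass with mean embedding fusion."""
    return model.forward(streams)
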