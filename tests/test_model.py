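"""Shape contracts, pooling/aggregation semantics, and stream fusion."""

import numpy as np
import pytest

from msknet.model import (
    KNet,
    KNetParams,
    MSKNet,
    Prediction,
    aggregate_slices,
    extract_slice_features,
    forward_knet,
    forward_msknet,
    pool_slices,
)
from msknet.preprocess import FusedVolume


def _volume(s: int, seed: int = 0, seq: str = "sagittal_t1") -> FusedVolume:
    data = np.random.default_rng(seed).normal(size=(s, 3, 224, 224))
    return FusedVolume("e", seq, data)


@pytest.fixture(scope="module")
def knet():
    return KNet(KNetParams(backbone="tiny_cnn", seed=3))


class TestPrediction:
    def test_threshold_rule(self):
        assert Prediction(0.49).label == 0
        assert Prediction(0.51).label == 1
        assert Prediction(0.5).label == 1  # tie resolves positive

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            Prediction(1.5)


class TestSliceFeatures:
    def test_shape_contract(self, knet):
        feats = extract_slice_features(_volume(14), knet)
        assert feats.shape == (14, 256, 7, 7)

    def test_per_slice_independence(self, knet):
        vol = _volume(4, seed=1)
        dup = FusedVolume("e", "sagittal_t1", np.concatenate([vol.data, vol.data[2:3]]))
        feats = extract_slice_features(dup, knet)
        assert np.array_equal(feats[2], feats[4])

    def test_permutation_equivariance(self, knet):
        vol = _volume(5, seed=2)
        perm = np.array([3, 0, 4, 1, 2])
        feats = extract_slice_features(vol, knet)
        feats_perm = extract_slice_features(
            FusedVolume("e", "sagittal_t1", vol.data[perm]), knet
        )
        assert np.allclose(feats_perm, feats[perm])


class TestPoolSlices:
    def test_constant_features(self):
        feats = np.ones((3, 256, 7, 7))
        assert np.array_equal(pool_slices(feats), np.ones((3, 256)))

    def test_matches_explicit_mean_oracle(self, rng):
        feats = rng.normal(size=(4, 256, 7, 7))
        pooled = pool_slices(feats)
        oracle = np.array(
            [[feats[i, c].ravel().sum() / 49 for c in range(256)] for i in range(4)]
        )
        assert np.allclose(pooled, oracle, atol=1e-6)


class TestAggregateSlices:
    def test_single_slice_is_identity(self, knet, rng):
        pooled = rng.normal(size=(1, 256))
        assert np.allclose(aggregate_slices(pooled, knet), pooled[0])

    def test_identical_slices_collapse(self, knet, rng):
        row = rng.normal(size=256)
        pooled = np.tile(row, (6, 1))
        assert np.allclose(aggregate_slices(pooled, knet), row)

    def test_permutation_invariance(self, knet, rng):
        for s in (2, 4, 6):
            pooled = rng.normal(size=(s, 256))
            perm = np.random.default_rng(s).permutation(s)
            assert np.allclose(
                aggregate_slices(pooled, knet), aggregate_slices(pooled[perm], knet)
            )

    def test_weights_are_probability_vector(self, knet, rng):
        pooled = rng.normal(size=(8, 256))
        _, weights = knet.branch.aggregate_slices(pooled)
        assert np.all(weights >= 0)
        assert weights.sum() == pytest.approx(1.0, abs=1e-6)


class TestForward:
    def test_zero_head_gives_half(self, knet):
        saved = (knet.head.w.copy(), knet.head.b.copy())
        knet.head.w[:] = 0.0
        knet.head.b[:] = 0.0
        pred, _ = forward_knet(_volume(3), knet)
        knet.head.w[:], knet.head.b[:] = saved
        assert pred.probability == 0.5
        assert pred.label == 1

    def test_deterministic(self, knet):
        vol = _volume(3, seed=5)
        p1, _ = forward_knet(vol, knet)
        p2, _ = forward_knet(vol, knet)
        assert p1.probability == p2.probability

    def test_slice_permutation_invariance(self, knet):
        vol = _volume(6, seed=6)
        perm = np.random.default_rng(0).permutation(6)
        p1, z1 = forward_knet(vol, knet)
        p2, z2 = forward_knet(FusedVolume("e", "sagittal_t1", vol.data[perm]), knet)
        assert np.allclose(z1, z2)
        assert p1.probability == pytest.approx(p2.probability, abs=1e-12)

    @pytest.mark.parametrize("s", [14, 30, 56])
    def test_shape_chain_for_study_slice_counts(self, knet, s):
        """s x 3 x 224 x 224 -> s x 256 x 7 x 7 -> s x 256 -> 256 -> probability."""
        vol = _volume(s, seed=s)
        feats = extract_slice_features(vol, knet)
        assert feats.shape == (s, 256, 7, 7)
        pooled = pool_slices(feats)
        assert pooled.shape == (s, 256)
        embedding = aggregate_slices(pooled, knet)
        assert embedding.shape == (256,)
        pred, _ = forward_knet(vol, knet)
        assert 0.0 <= pred.probability <= 1.0


class TestMSKNet:
    def test_single_stream_equals_knet(self):
        params = KNetParams(seed=9)
        knet = KNet(params)
        msk = MSKNet(params)
        vol = _volume(4, seed=7)
        p_single, _ = forward_knet(vol, knet)
        p_multi = forward_msknet({"sagittal_t1": vol}, msk)
        assert p_multi.probability == pytest.approx(p_single.probability, abs=1e-12)

    def test_tied_identical_streams_equal_single_stream(self):
        """Three branches with tied weights fed the same volume reproduce the
        single-stream output (mean of equal embeddings)."""
        single = KNet(KNetParams(seed=11))
        triple = MSKNet(
            KNetParams(
                n_streams=3,
                stream_sequences=("coronal_hybrid", "axial_t2", "sagittal_t1"),
                seed=12,
            )
        )
        src = single.parameters()
        tied = {}
        for seq in triple.params_cfg.stream_sequences:
            for key, val in src.items():
                if key.startswith("branch.sagittal_t1"):
                    tied[key.replace("branch.sagittal_t1", f"branch.{seq}")] = val
        tied["head.w"] = src["head.w"]
        tied["head.b"] = src["head.b"]
        triple.set_parameters(tied)

        data = np.random.default_rng(8).normal(size=(5, 3, 224, 224))
        streams = {
            seq: FusedVolume("e", seq, data)
            for seq in triple.params_cfg.stream_sequences
        }
        p_triple = forward_msknet(streams, triple)
        p_single, _ = forward_knet(FusedVolume("e", "sagittal_t1", data), single)
        assert p_triple.probability == pytest.approx(p_single.probability, rel=1e-12)

    def test_stream_order_irrelevant(self):
        msk = MSKNet(
            KNetParams(
                n_streams=2, stream_sequences=("axial_t2", "sagittal_t1"), seed=13
            )
        )
        a, b = _volume(3, 1, "axial_t2"), _volume(3, 2, "sagittal_t1")
        p1 = forward_msknet({"axial_t2": a, "sagittal_t1": b}, msk)
        p2 = forward_msknet({"sagittal_t1": b, "axial_t2": a}, msk)
        assert p1.probability == p2.probability

    def test_missing_stream_rejected(self):
        msk = MSKNet(
            KNetParams(n_streams=2, stream_sequences=("axial_t2", "sagittal_t1"), seed=1)
        )
        with pytest.raises(ValueError, match="missing stream"):
            forward_msknet({"axial_t2": _volume(3, 1, "axial_t2")}, msk)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            KNetParams(n_streams=4, stream_sequences=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            KNetParams(n_streams=2, stream_sequences=("sagittal_t1",))


def test_alexnet_random_backbone_meets_shape_contract():
    """The stock AlexNet feature stack (random init) also satisfies the
    s x 256 x 7 x 7 contract via adaptive average pooling."""
    knet = KNet(KNetParams(backbone="alexnet_random", seed=4))
    feats = extract_slice_features(_volume(2, seed=3), knet)
    assert feats.shape == (2, 256, 7, 7)


def test_alexnet_pretrained_unavailable():
    with pytest.raises(RuntimeError, match="weights"):
        KNet(KNetParams(backbone="alexnet_pretrained", seed=0))
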