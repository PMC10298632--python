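"""Windowing, z-normalization, LBP, Haar DWT, and channel fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msknet.dicom_io import MRISeries
from msknet.preprocess import (
    FULL_RANGE,
    IntensityWindow,
    NormStats,
    apply_window,
    dwt_map,
    fit_norm_stats,
    fuse,
    haar_subbands,
    lbp_map,
    normalize,
)


def _series(pixels: np.ndarray) -> MRISeries:
    return MRISeries("e", "sagittal_t1", pixels)


class TestWindow:
    def test_definition(self):
        series = _series(np.array([[[5.0, 50.0, 500.0]]]))
        out = apply_window(series, IntensityWindow(10, 100))
        assert out.pixels.tolist() == [[[0.0, 50.0, 0.0]]]

    def test_full_range_is_identity(self, rng):
        pix = rng.uniform(0, 1000, size=(3, 16, 16))
        out = apply_window(_series(pix), FULL_RANGE)
        assert np.array_equal(out.pixels, pix)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            IntensityWindow(10, 10)

    def test_idempotent(self, rng):
        pix = rng.uniform(0, 1000, size=(2, 16, 16))
        window = IntensityWindow(100, 600)
        once = apply_window(_series(pix), window)
        twice = apply_window(once, window)
        assert np.array_equal(once.pixels, twice.pixels)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_zeroed_fraction_matches_brute_force(self, seed):
        pix = np.random.default_rng(seed).uniform(0, 1000, size=(2, 8, 8))
        window = IntensityWindow(200, 700)
        out = apply_window(_series(pix), window)
        outside = sum(
            1 for v in pix.ravel() if v < window.low or v > window.high
        )  # brute-force scan
        changed = int(np.sum(out.pixels != pix))
        assert changed == outside - sum(1 for v in pix.ravel() if v == 0.0)


class TestNormStats:
    def test_hand_arithmetic(self):
        series = _series(np.array([[[0.0, 0.0], [10.0, 10.0]]]))
        stats = fit_norm_stats([series])
        assert stats.mean == 5.0
        assert stats.sd == 5.0

    def test_constant_training_set_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_norm_stats([_series(np.full((2, 4, 4), 7.0))])

    def test_matches_two_pass_oracle(self, small_cohort):
        exams, _ = small_cohort
        series = [e.series["sagittal_t1"] for e in exams]
        stats = fit_norm_stats(series)
        pooled = np.concatenate([s.pixels.ravel() for s in series])
        assert stats.mean == pytest.approx(pooled.mean(), rel=1e-6)
        assert stats.sd == pytest.approx(pooled.std(), rel=1e-6)

    def test_normalize_arithmetic(self):
        stats = NormStats(mean=100.0, sd=10.0)
        out = normalize(_series(np.array([[[120.0, 100.0]]])), stats)
        assert out.pixels.tolist() == [[[2.0, 0.0]]]

    def test_self_normalization_identity(self, small_cohort):
        """Normalizing the training set with its own statistics yields
        global mean 0 and sd 1 to 1e-6."""
        exams, _ = small_cohort
        series = [e.series["axial_t2"] for e in exams]
        stats = fit_norm_stats(series)
        pooled = np.concatenate(
            [normalize(s, stats).pixels.ravel() for s in series]
        )
        assert abs(pooled.mean()) < 1e-6
        assert abs(pooled.std() - 1.0) < 1e-6


class TestLBP:
    def test_constant_image_codes_255(self):
        assert np.all(lbp_map(np.full((8, 8), 3.0)) == 255)

    def test_hand_worked_patch(self):
        """Center 5 with clockwise-from-top-left neighbors [6,7,8,9,1,2,3,4]:
        comparisons >= give bits 11110000 (MSB = top-left) = 240."""
        patch = np.array(
            [
                [6.0, 7.0, 8.0],
                [4.0, 5.0, 9.0],
                [3.0, 2.0, 1.0],
            ]
        )
        assert lbp_map(patch)[1, 1] == 0b11110000 == 240

    def test_matches_brute_force_oracle(self, rng):
        """Pixelwise agreement with an explicit nested-loop evaluation."""
        x = rng.uniform(0, 100, size=(12, 12))
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
        padded = np.pad(x, 1, mode="edge")
        expected = np.zeros_like(x, dtype=int)
        for i in range(12):
            for j in range(12):
                code = 0
                for bit, (dy, dx) in enumerate(offsets):
                    if padded[1 + i + dy, 1 + j + dx] >= x[i, j]:
                        code |= 1 << (7 - bit)
                expected[i, j] = code
        assert np.array_equal(lbp_map(x), expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_monotone_invariance_on_tie_free_images(self, seed):
        """A strictly increasing intensity transform leaves the code map
        unchanged when no two neighbors are equal."""
        gen = np.random.default_rng(seed)
        # a permutation of distinct values -> tie-free by construction
        x = gen.permutation(32 * 32).reshape(32, 32).astype(float)
        transformed = np.exp(x / 1024.0) + 3.0 * x
        assert np.array_equal(lbp_map(x), lbp_map(transformed))

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            lbp_map(np.zeros((2, 4, 4)))


class TestDWT:
    def test_constant_maps_to_twice_value(self):
        out = dwt_map(np.full((16, 16), 3.5))
        assert np.allclose(out, 7.0)

    def test_ll_matches_filter_bank_oracle(self, rng):
        """Direct 2x2 Haar filter bank: LL[i,j] = (sum of the 2x2 block)/2."""
        x = rng.uniform(0, 10, size=(16, 16))
        ll, _, _, _ = haar_subbands(x)
        oracle = (x[0::2, 0::2] + x[0::2, 1::2] + x[1::2, 0::2] + x[1::2, 1::2]) / 2.0
        assert np.allclose(ll, oracle, atol=1e-6)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=(64, 64))
        energy = sum(np.square(b).sum() for b in haar_subbands(x))
        assert energy == pytest.approx(np.square(x).sum(), rel=1e-4)

    def test_ll_map_is_low_pass(self, rng):
        """Per-slice variance of the exported LL map is bounded by 4x the
        input variance (the Haar LL gain)."""
        x = rng.normal(size=(64, 64))
        assert dwt_map(x).var() <= 4.0 * x.var() + 1e-9

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError, match="even"):
            dwt_map(np.zeros((15, 16)))


@pytest.fixture(scope="module")
def fused(small_volumes):
    volumes, stats = small_volumes
    first = next(iter(volumes.values()))
    return next(iter(first.values())), stats


class TestFuse:
    def test_output_shape(self, fused):
        volume, _ = fused
        assert volume.data.shape == (volume.s, 3, 224, 224)

    def test_channel0_is_normalized_original(self, small_cohort, small_volumes):
        exams, _ = small_cohort
        volumes, stats = small_volumes
        from msknet.dicom_io import resize_series

        exam = exams[0]
        series = resize_series(exam.series["sagittal_t1"], 224)
        expected = normalize(apply_window(series, stats.window), stats).pixels
        got = volumes[exam.exam_id]["sagittal_t1"].data[:, 0]
        assert np.array_equal(got, expected.astype(np.float32))

    def test_texture_channels_standardized_per_slice(self, fused):
        volume, _ = fused
        for ch in (1, 2):
            means = volume.data[:, ch].mean(axis=(1, 2))
            sds = volume.data[:, ch].std(axis=(1, 2))
            assert np.all(np.abs(means) < 1e-5)
            assert np.all(np.abs(sds - 1.0) < 1e-5)

    def test_all_finite(self, fused):
        volume, _ = fused
        assert np.all(np.isfinite(volume.data))

    def test_deterministic(self, small_cohort, small_volumes):
        exams, _ = small_cohort
        volumes, stats = small_volumes
        from msknet.dicom_io import resize_series

        exam = exams[0]
        series = resize_series(exam.series["sagittal_t1"], 224)
        again = fuse(series, stats)
        assert np.array_equal(again.data, volumes[exam.exam_id]["sagittal_t1"].data)

    def test_wrong_spatial_size_rejected(self, small_volumes):
        _, stats = small_volumes
        series = _series(np.zeros((2, 64, 64)))
        with pytest.raises(ValueError, match="224"):
            fuse(series, stats)
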