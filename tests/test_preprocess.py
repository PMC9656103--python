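"""Intensity normalization, resampling, quantization and wavelet filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirads3.preprocess import (
    NormalizationError,
    get_preset,
    normalize_by_reference_roi,
    normalize_range_mu3sigma,
    normalize_zscore,
    quantize_fbn,
    resample,
    resample_mask,
    wavelet_decompose,
    wavelet_reconstruct,
    WAVELET_BANDS,
)
from pirads3.volume import ImageVolume, MaskVolume


def _img(rng, shape=(4, 8, 8), spacing=(1.0, 1.0, 2.0)):
    return ImageVolume(rng.random(shape) + 0.5, spacing)


def _roi(shape=(4, 8, 8), spacing=(1.0, 1.0, 2.0)):
    m = np.zeros(shape, dtype=bool)
    m[1:3, 2:5, 2:5] = True
    return MaskVolume(m, spacing)


class TestReferenceRoiNormalization:
    def test_roi_mean_becomes_exactly_one(self, rng):
        img, roi = _img(rng), _roi()
        out = normalize_by_reference_roi(img, roi)
        assert out.voxels[roi.voxels].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        img, roi = _img(rng), _roi()
        out1 = normalize_by_reference_roi(img, roi)
        out2 = normalize_by_reference_roi(img.copy_with(2.0 * img.voxels), roi)
        np.testing.assert_allclose(out1.voxels, out2.voxels, rtol=1e-12)

    def test_unit_mean_roi_is_identity(self, rng):
        img, roi = _img(rng), _roi()
        v = img.voxels.copy()
        v[roi.voxels] -= v[roi.voxels].mean() - 1.0  # force ROI mean to 1
        img = img.copy_with(v)
        out = normalize_by_reference_roi(img, roi)
        np.testing.assert_allclose(out.voxels, img.voxels, rtol=1e-12)

    def test_empty_roi_raises(self, rng):
        img = _img(rng)
        empty = MaskVolume(np.zeros(img.shape, bool), img.spacing)
        with pytest.raises(NormalizationError):
            normalize_by_reference_roi(img, empty)


class TestMu3SigmaNormalization:
    def test_voi_mean_maps_to_midpoint(self, rng):
        img, roi = _img(rng), _roi()
        mu = img.voxels[roi.voxels].mean()
        mid = normalize_range_mu3sigma(
            img.copy_with(np.where(roi.voxels, img.voxels, mu)), roi
        )
        # any voxel whose input equals the VOI mean lands on 0.5
        assert mid.voxels[~roi.voxels] == pytest.approx(0.5, abs=1e-12)

    def test_output_clipped_to_range(self, rng):
        img, roi = _img(rng), _roi()
        v = img.voxels.copy()
        v[0, 0, 0] = 1e6  # far above mu + 3 sigma
        v[0, 0, 1] = -1e6
        out = normalize_range_mu3sigma(img.copy_with(v), roi)
        assert out.voxels[0, 0, 0] == 1.0
        assert out.voxels[0, 0, 1] == 0.0
        assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0

    def test_affine_map_matches_direct_recomputation(self, rng):
        img, roi = _img(rng), _roi()
        vals = img.voxels[roi.voxels]
        mu, sd = vals.mean(), vals.std()
        out = normalize_range_mu3sigma(img, roi)
        expected = np.clip((img.voxels - (mu - 3 * sd)) / (6 * sd), 0, 1)
        np.testing.assert_allclose(out.voxels, expected, rtol=1e-12)

    def test_zero_sigma_raises(self):
        img = ImageVolume(np.ones((4, 8, 8)), (1, 1, 1))
        with pytest.raises(NormalizationError):
            normalize_range_mu3sigma(img, _roi(spacing=(1, 1, 1)))


class TestZscoreNormalization:
    def test_moments_and_idempotence(self, rng):
        out = normalize_zscore(_img(rng))
        assert out.voxels.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.voxels.std() == pytest.approx(1.0, abs=1e-12)
        again = normalize_zscore(out)
        np.testing.assert_allclose(again.voxels, out.voxels, atol=1e-10)

    def test_affine_invariance(self, rng):
        img = _img(rng)
        out1 = normalize_zscore(img)
        out2 = normalize_zscore(img.copy_with(3.0 * img.voxels - 7.0))
        np.testing.assert_allclose(out1.voxels, out2.voxels, atol=1e-10)

    def test_constant_image_raises(self):
        with pytest.raises(NormalizationError):
            normalize_zscore(ImageVolume(np.full((3, 3, 3), 2.0), (1, 1, 1)))


class TestResample:
    def test_native_spacing_is_identity(self, rng):
        img = _img(rng)
        out = resample(img, img.spacing)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_constant_image_reproduced(self):
        img = ImageVolume(np.full((4, 8, 8), 3.5), (1.0, 1.0, 2.0))
        out = resample(img, (0.5, 0.5, 1.0))
        np.testing.assert_allclose(out.voxels, 3.5, rtol=1e-6)

    def test_linear_ramp_interpolated_analytically(self):
        # ramp f(x) = x_mm; cubic b-splines reproduce linear functions
        nx = 32
        vox = np.tile(np.arange(nx, dtype=float), (4, 8, 1))
        img = ImageVolume(vox, (1.0, 1.0, 2.0))
        out = resample(img, (0.5, 1.0, 2.0))
        x_mm = np.arange(out.shape[2]) * 0.5
        # the spline prefilter's mirror-boundary transient decays like
        # 0.268^k from each edge; the deep interior is exact
        interior = slice(24, 40)
        np.testing.assert_allclose(
            out.voxels[2, 4, interior], x_mm[interior], atol=1e-5
        )

    def test_mask_resampling_stays_binary(self):
        m = np.zeros((4, 8, 8), dtype=bool)
        m[1:3, 2:6, 2:6] = True
        out = resample_mask(MaskVolume(m, (1.0, 1.0, 2.0)), (0.5, 0.5, 1.0))
        assert out.voxels.dtype == bool
        assert out.n_voxels > 0

    def test_nonpositive_spacing_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(_img(rng), (0.0, 1.0, 1.0))


class TestQuantizeFBN:
    def test_elementwise_floor_oracle(self, rng):
        vals = rng.random(100)
        img = ImageVolume(vals.reshape(4, 5, 5), (1, 1, 1))
        mask = MaskVolume(np.ones((4, 5, 5), bool), (1, 1, 1))
        q = quantize_fbn(img, mask, 8)
        vmin, vmax = vals.min(), vals.max()
        expected = np.minimum(
            np.floor(8 * (vals - vmin) / (vmax - vmin)).astype(int) + 1, 8
        )
        np.testing.assert_array_equal(q.labels.ravel(), expected)

    def test_constant_roi_maps_to_label_one(self):
        img = ImageVolume(np.full((2, 3, 3), 5.0), (1, 1, 1))
        mask = MaskVolume(np.ones((2, 3, 3), bool), (1, 1, 1))
        q = quantize_fbn(img, mask, 32)
        assert set(np.unique(q.labels)) == {1}

    def test_two_point_range(self):
        img = ImageVolume(np.array([[[0.0, 1.0]]]), (1, 1, 1))
        mask = MaskVolume(np.ones((1, 1, 2), bool), (1, 1, 1))
        q = quantize_fbn(img, mask, 2)
        assert q.labels.tolist() == [[[1, 2]]]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=8, max_size=27))
    def test_monotone_and_shift_invariant(self, values):
        # integer-valued intensities keep the bin arithmetic exact under shift
        values = [float(v) for v in values]
        n = len(values)
        arr = np.zeros(27)
        arr[:n] = values
        img = ImageVolume(arr.reshape(3, 3, 3), (1, 1, 1))
        mask = MaskVolume((np.arange(27) < n).reshape(3, 3, 3), (1, 1, 1))
        q = quantize_fbn(img, mask, 5)
        lab = q.labels.ravel()[:n]
        order = np.argsort(values)
        assert np.all(np.diff(lab[order]) >= 0)
        q2 = quantize_fbn(img.copy_with(img.voxels + 42.0), mask, 5)
        np.testing.assert_array_equal(q.labels, q2.labels)


class TestWavelet:
    def test_constant_image_bands(self):
        img = ImageVolume(np.full((4, 8, 8), 2.0), (1, 1, 1))
        bands = wavelet_decompose(img, WAVELET_BANDS)
        for name, vol in bands.items():
            if "H" in name:
                np.testing.assert_allclose(vol.voxels, 0.0, atol=1e-10)
            else:
                assert vol.voxels.std() == pytest.approx(0.0, abs=1e-10)

    def test_requested_band_count_and_shape(self, rng):
        img = _img(rng)
        bands = wavelet_decompose(img, ("LLL", "LLH", "HHL", "HHH"))
        assert set(bands) == {"LLL", "LLH", "HHL", "HHH"}
        for vol in bands.values():
            assert vol.shape == img.shape

    def test_impulse_response_matches_separable_filter_taps(self):
        # swt bands are circular convolutions with the coif1 dec filters
        # (alignment shift +3); an impulse reads the taps out directly.
        import pywt

        w = pywt.Wavelet("coif1")
        filt = {"L": np.array(w.dec_lo), "H": np.array(w.dec_hi)}
        shape = (8, 16, 16)
        vox = np.zeros(shape)
        pos = (4, 8, 8)
        vox[pos] = 1.0
        bands = wavelet_decompose(ImageVolume(vox, (1, 1, 1)), ("LLH", "HHH"))
        for name in ("LLH", "HHH"):
            expected = np.zeros(shape)
            for idx in np.ndindex(shape):
                val = 1.0
                for ax in range(3):
                    k = (idx[ax] - pos[ax] + 3) % shape[ax]
                    val *= filt[name[ax]][k] if k < 6 else 0.0
                expected[idx] = val
            np.testing.assert_allclose(bands[name].voxels, expected, atol=1e-12)

    def test_roundtrip_reconstruction(self, rng):
        img = _img(rng)
        bands = wavelet_decompose(img, WAVELET_BANDS)
        rec = wavelet_reconstruct(bands)
        np.testing.assert_allclose(rec.voxels, img.voxels, atol=1e-10)

    def test_odd_dimensions_padded(self, rng):
        img = ImageVolume(rng.random((3, 7, 9)), (1, 1, 1))
        bands = wavelet_decompose(img, ("LLL",))
        assert bands["LLL"].shape == (3, 7, 9)

    def test_unknown_band_rejected(self, rng):
        with pytest.raises(ValueError):
            wavelet_decompose(_img(rng), ("LLX",))


class TestPresets:
    def test_proposed_preset_parameters(self):
        p = get_preset("proposed")
        assert p.normalization == "reference_roi"
        assert p.target_spacing == {"t2": (0.4, 0.4, 3.0), "adc": (0.8, 0.8, 3.0)}
        assert p.n_bins_original == {"t2": 32, "adc": 32}
        assert p.n_bins_wavelet == {"t2": 8, "adc": 16}
        assert set(p.wavelet_bands["t2"]) == {"LLL", "LLH", "HHL", "HHH"}

    def test_literature_presets(self):
        h = get_preset("hectors")
        assert h.normalization == "mu3sigma"
        assert h.target_spacing["t2"] == (0.5, 0.5, 0.5)
        assert h.n_bins_original["t2"] == 64
        j = get_preset("jin")
        assert j.normalization == "zscore"
        assert j.target_spacing["t2"] == (1.0, 1.0, 1.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            get_preset("nosuch")
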