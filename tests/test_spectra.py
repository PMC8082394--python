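"""Spectral processing: apodization, integration, peak detection, noise, SNR."""

import numpy as np
import pytest

from hpgluc.spectra import (DynamicSpectrumSeries, NoiseEstimate, PeakWindow,
                            Spectrum, apodize, default_windows, detect_peaks,
                            estimate_noise, integrate_peak, snr)
from hpgluc.synth import (AcquisitionScheme, NoiseSpec, Resonance,
                          render_spectrum_series)

from conftest import single_pool


def _fine_scheme(B0=11.7, n=4096, center=176.25, bw=20.0):
    return AcquisitionScheme(TR_s=3.0, n_timepoints=2, spectral_points=n,
                             bandwidth_ppm=bw, B0_T=B0, center_ppm=center)


def _one_line_series(linewidth_hz=4.0, shift=176.0, amp=1.0, scheme=None):
    scheme = scheme or _fine_scheme()
    res = [Resonance("dGL", shift, linewidth_hz, 15.7, 13.0)]
    return scheme, render_spectrum_series(np.array([[amp], [amp]]), scheme, res)


def _fwhm_hz(spectrum, ref_freq_MHz):
    """Full width at half maximum of the tallest line, by linear interpolation."""
    y = spectrum.real
    x = spectrum.axis_ppm
    p = int(np.argmax(y))
    half = y[p] / 2.0
    left = np.interp(half, y[: p + 1], x[: p + 1])           # ascending y
    right = np.interp(half, y[p:][::-1], x[p:][::-1])
    return abs(left - right) * ref_freq_MHz


class TestApodize:
    def test_zero_broadening_is_identity(self):
        _, series = _one_line_series()
        out = apodize(series, 0.0)
        assert np.array_equal(out.values, series.values)

    def test_linewidths_add_under_broadening(self):
        """A 4 Hz Lorentzian after 5 Hz line broadening is a 9 Hz line."""
        scheme, series = _one_line_series(linewidth_hz=4.0)
        out = apodize(series, 5.0)
        fwhm = _fwhm_hz(out[0], scheme.ref_freq_MHz)
        assert fwhm == pytest.approx(9.0, rel=0.02)

    def test_peak_area_preserved(self):
        # wide axis so the tail difference of the broadened line is < 1e-3
        scheme = _fine_scheme(n=8192, bw=40.0, center=176.0)
        _, series = _one_line_series(amp=2.0, scheme=scheme)
        out = apodize(series, 5.0)
        w = PeakWindow("dGL", 176.0, 18.0)
        a0 = integrate_peak(series[0], w)
        a1 = integrate_peak(out[0], w)
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_negative_broadening_rejected(self):
        _, series = _one_line_series()
        with pytest.raises(ValueError):
            apodize(series, -1.0)


class TestIntegratePeak:
    def test_zero_spectrum_integrates_to_zero(self):
        axis = np.linspace(185, 165, 512)
        assert integrate_peak(Spectrum(np.zeros(512), axis),
                              PeakWindow("x", 176, 0.5)) == 0.0

    def test_lorentzian_wide_window_recovers_area(self):
        """Window of +-10 FWHM captures (2/pi) atan(20) = 0.9682 of a
        unit-area Lorentzian (analytic CDF)."""
        scheme, series = _one_line_series(linewidth_hz=4.0, amp=1.0)
        fwhm_ppm = 4.0 / scheme.ref_freq_MHz
        w = PeakWindow("dGL", 176.0, 10 * fwhm_ppm)
        area = integrate_peak(series[0], w)
        expected = 2.0 / np.pi * np.arctan(20.0)
        assert area == pytest.approx(expected, rel=5e-3)
        assert 0.96 <= area <= 1.00

    def test_linear_in_amplitude(self):
        _, s1 = _one_line_series(amp=1.0)
        _, s3 = _one_line_series(amp=3.0)
        w = PeakWindow("dGL", 176.0, 0.5)
        assert integrate_peak(s3[0], w) == pytest.approx(
            3 * integrate_peak(s1[0], w), rel=1e-12)

    def test_additive_over_disjoint_windows(self):
        _, series = _one_line_series()
        spec = series[0]
        # split in a flat tail region so the one-sample seam is negligible
        lo = PeakWindow("a", 174.5, 0.5)
        hi = PeakWindow("b", 176.3, 1.3)
        both = PeakWindow("ab", 175.8, 1.8)
        assert integrate_peak(spec, lo) + integrate_peak(spec, hi) == \
            pytest.approx(integrate_peak(spec, both), rel=5e-3)

    def test_window_outside_axis_rejected(self):
        _, series = _one_line_series()
        with pytest.raises(ValueError):
            integrate_peak(series[0], PeakWindow("x", 190.0, 0.5))


class TestDetectPeaks:
    def _three_line_spectrum(self, shift_delta=0.0, n=2048):
        scheme = AcquisitionScheme(TR_s=3, n_timepoints=2, spectral_points=n,
                                   bandwidth_ppm=20, B0_T=3.0,
                                   center_ppm=175.0 + shift_delta)
        res = [Resonance("6PG", 178.6 + shift_delta, 8, 25, 15.3),
               Resonance("gGL", 177.0 + shift_delta, 8, 31.7, 12),
               Resonance("dGL", 173.8 + shift_delta, 8, 31.7, 3.4)]
        series = render_spectrum_series(np.array([[0.3, 0.7, 1.0]]), scheme,
                                        res)
        return series[0]

    def test_three_lines_recovered_at_published_shifts(self):
        """6PG (178.6), gamma (177.0) and delta (173.8) are found within
        0.02 ppm, ordered downfield to upfield."""
        spec = self._three_line_spectrum()
        peaks = detect_peaks(spec, min_height=0.5)
        assert len(peaks) == 3
        centers = [p for p, _ in peaks]
        assert centers == sorted(centers, reverse=True)
        for found, true in zip(centers, (178.6, 177.0, 173.8)):
            assert found == pytest.approx(true, abs=0.02)

    def test_translation_covariance(self):
        a = [p for p, _ in detect_peaks(self._three_line_spectrum(),
                                        min_height=0.5)]
        b = [p for p, _ in detect_peaks(self._three_line_spectrum(1.7),
                                        min_height=0.5)]
        for pa, pb in zip(a, b):
            assert pb - pa == pytest.approx(1.7, abs=0.02)

    def test_single_line_single_peak(self):
        _, series = _one_line_series()
        peaks = detect_peaks(series[0], min_height=0.5)
        assert len(peaks) == 1

    def test_pure_noise_rarely_crosses_5_sigma(self):
        """A 5-sigma threshold on pure noise yields an empty list in >=99%
        of 200 seeds (Gaussian tail bound)."""
        scheme = _fine_scheme(n=128)
        res = [single_pool(15.7, 13.0, shift_ppm=176.0)]
        hits = 0
        for seed in range(200):
            series = render_spectrum_series(
                np.zeros((1, 1)), scheme, res, NoiseSpec(sigma=1.0, seed=seed))
            if detect_peaks(series[0], NoiseEstimate(sigma=1.0),
                            snr_threshold=5.0):
                hits += 1
        assert hits <= 2

    def test_zero_sigma_requires_absolute_threshold(self):
        _, series = _one_line_series()
        with pytest.raises(ValueError, match="min_height"):
            detect_peaks(series[0], NoiseEstimate(sigma=0.0))


class TestNoiseAndSNR:
    def test_sigma_recovered_from_pure_noise(self):
        axis = np.linspace(185, 165, 128)
        rng = np.random.default_rng(0)
        spec = Spectrum(rng.normal(0, 1.0, 128)
                        + 1j * rng.normal(0, 1.0, 128), axis)
        est = estimate_noise(spec, (165, 185))
        assert 0.85 <= est.sigma <= 1.15

    def test_zero_input_gives_zero_sigma(self):
        axis = np.linspace(185, 165, 128)
        est = estimate_noise(Spectrum(np.zeros(128), axis), (165, 185))
        assert est.sigma == 0.0

    def test_region_overlapping_resonance_rejected(self):
        axis = np.linspace(185, 165, 128)
        spec = Spectrum(np.zeros(128), axis)
        with pytest.raises(ValueError, match="overlaps"):
            estimate_noise(spec, (173, 175), resonance_shifts=[173.8])

    def test_signal_free_range_matches_outside_voxel_population(self):
        """Noise estimated in a signal-free ppm range agrees with the
        estimate from signal-free data of the same sigma within 20%."""
        scheme = _fine_scheme(n=512)
        res = [single_pool(15.7, 13.0, shift_ppm=176.0)]
        series = render_spectrum_series(np.array([[1.0]] * 8), scheme, res,
                                        NoiseSpec(sigma=0.05, seed=3))
        far = estimate_noise(series, (181.5, 185.5),
                             resonance_shifts=[176.0], guard_ppm=5.0)
        blank = render_spectrum_series(np.zeros((8, 1)), scheme, res,
                                       NoiseSpec(sigma=0.05, seed=4))
        ref = estimate_noise(blank, (167, 185))
        assert abs(far.sigma - ref.sigma) / ref.sigma < 0.2

    def test_snr_is_height_over_sigma(self):
        axis = np.linspace(185, 165, 256)
        y = np.zeros(256)
        y[100] = 10.0
        spec = Spectrum(y.astype(complex), axis)
        w = PeakWindow("x", axis[100], 0.5)
        assert snr(spec, w, NoiseEstimate(sigma=2.0)) == 5.0
        assert snr(Spectrum(2 * y.astype(complex), axis), w,
                   NoiseEstimate(sigma=2.0)) == 10.0

    def test_snr_requires_positive_sigma(self):
        axis = np.linspace(185, 165, 128)
        spec = Spectrum(np.ones(128), axis)
        with pytest.raises(ValueError):
            snr(spec, PeakWindow("x", 176, 0.5), NoiseEstimate(sigma=0.0))


def test_default_windows_are_disjoint():
    ws = sorted(default_windows(), key=lambda w: w.center_ppm)
    for a, b in zip(ws[:-1], ws[1:]):
        assert a.hi_ppm < b.lo_ppm
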