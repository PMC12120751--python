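"""Frequency grid, Gaussian kernel and narrowband filtering."""

import numpy as np
import pytest

import freqness as fn
from freqness.datamodel import VoxelDataset
from freqness.errors import DataError
from freqness.filtering import filter_vector, gaussian_gains, measure_fwhm


class TestFrequencyGrid:
    def test_default_grid_structure(self):
        grid = fn.build_frequency_grid()
        assert len(grid) == 86
        assert grid.centers.min() == pytest.approx(0.2)
        above = grid.centers[grid.centers > 2.4]
        assert np.allclose(np.diff(above), 1.2)
        assert 2.4 in grid.centers

    def test_harmonic_alternation(self):
        # every second center above the stimulation frequency is a multiple of it
        grid = fn.build_frequency_grid()
        above = grid.centers[grid.centers >= 2.4]
        harmonics = above[::2]
        ratios = harmonics / 2.4
        assert np.allclose(ratios, np.round(ratios), atol=1e-9)

    def test_degenerate_grid(self):
        grid = fn.build_frequency_grid(n_below=0, f_max=2.4)
        assert list(grid.centers) == [2.4]

    def test_nyquist_rejection(self):
        with pytest.raises(DataError, match="Nyquist"):
            fn.build_frequency_grid(nyquist=50.0)

    def test_custom_sub_stim_centers(self):
        grid = fn.build_frequency_grid(sub_stim_centers=[0.2, 0.6, 1.0, 1.4, 1.8, 2.2])
        assert np.allclose(grid.centers[:6], [0.2, 0.6, 1.0, 1.4, 1.8, 2.2])

    def test_sub_stim_centers_must_be_below_stim(self):
        with pytest.raises(DataError):
            fn.build_frequency_grid(sub_stim_centers=[0.2, 0.6, 1.0, 1.4, 1.8, 2.5])


class TestFwhmSchedule:
    @pytest.mark.parametrize(
        "center,slope,expected",
        [(2.4, 1.0, 0.3), (2.4, 0.0, 0.3), (24.0, 1.0, 3.0), (10.0, 0.0, 0.3)],
    )
    def test_closed_form(self, center, slope, expected):
        assert fn.fwhm_schedule(center, slope=slope) == pytest.approx(expected)

    def test_strictly_increasing_default(self):
        freqs = np.linspace(0.5, 90, 50)
        widths = [fn.fwhm_schedule(f) for f in freqs]
        assert np.all(np.diff(widths) > 0)


class TestGaussianKernel:
    def test_peak_at_center_bin(self):
        k = fn.design_gaussian_kernel(2.4, 0.3, 75000, 250.0)
        gains = k.rfft_gains()
        freqs = np.arange(len(gains)) * k.bin_width
        assert gains.max() == 1.0
        assert abs(freqs[np.argmax(gains)] - 2.4) <= k.bin_width / 2

    def test_half_gain_at_half_width(self):
        k = fn.design_gaussian_kernel(10.0, 2.0, 10000, 100.0)
        gains = k.rfft_gains()
        freqs = np.arange(len(gains)) * k.bin_width
        for edge in (9.0, 11.0):
            idx = np.argmin(np.abs(freqs - edge))
            assert gains[idx] == pytest.approx(0.5, abs=0.02)

    def test_measured_fwhm_matches_design(self):
        k = fn.design_gaussian_kernel(2.4, 0.3, 75000, 250.0)
        assert measure_fwhm(k) == pytest.approx(0.3, abs=1.0 / 300.0)

    def test_negative_frequency_mirror(self):
        k = fn.design_gaussian_kernel(5.0, 1.0, 1000, 100.0)
        # fftfreq ordering: bin i and bin n-i are +/- the same frequency
        assert np.allclose(k.gains[1:], k.gains[1:][::-1])

    def test_underresolved_kernel_warns(self):
        with pytest.warns(UserWarning, match="under-resolved"):
            fn.design_gaussian_kernel(10.0, 0.01, 100, 100.0)


class TestNarrowbandFilter:
    def _sine_dataset(self, freq, fs=250.0, duration=20.0, n_voxels=3):
        t = np.arange(int(fs * duration)) / fs
        data = np.tile(np.sin(2 * np.pi * freq * t), (n_voxels, 1))
        return VoxelDataset(data=data, sampling_rate=fs)

    def test_zero_input_zero_output(self, rng):
        ds = VoxelDataset(data=np.zeros((3, 1000)) + 1e-30, sampling_rate=100.0)
        k = fn.design_gaussian_kernel(10.0, 1.0, 1000, 100.0)
        out = fn.narrowband_filter(ds, k)
        assert np.allclose(out.data, 0.0, atol=1e-25)

    def test_center_sinusoid_passes_at_unit_gain(self):
        ds = self._sine_dataset(10.0)  # integer cycles in 20 s
        k = fn.design_gaussian_kernel(10.0, 1.0, ds.n_samples, ds.sampling_rate)
        out = fn.narrowband_filter(ds, k)
        assert np.abs(out.data - ds.data).max() < 1e-6

    def test_distant_sinusoid_strongly_attenuated(self):
        k_center, fwhm = 10.0, 1.0
        ds = self._sine_dataset(k_center + 5 * fwhm)
        k = fn.design_gaussian_kernel(k_center, fwhm, ds.n_samples, ds.sampling_rate)
        out = fn.narrowband_filter(ds, k)
        in_rms = ds.data.std()
        out_rms = out.data.std()
        assert out_rms <= in_rms / 1e4

    def test_linearity(self, small_dataset, rng):
        k = fn.design_gaussian_kernel(12.0, 1.5, small_dataset.n_samples, small_dataset.sampling_rate)
        a, b = 2.0, -0.7
        x = small_dataset.data
        y = rng.standard_normal(x.shape)
        left = filter_vector(a * x[0] + b * y[0], k)
        right = a * filter_vector(x[0], k) + b * filter_vector(y[0], k)
        assert np.allclose(left, right, atol=1e-10)

    def test_double_filter_equals_squared_kernel(self, small_dataset):
        k = fn.design_gaussian_kernel(12.0, 2.0, small_dataset.n_samples, small_dataset.sampling_rate)
        once = fn.narrowband_filter(small_dataset, k)
        twice = fn.narrowband_filter(once, k)
        k2 = fn.GaussianKernel(
            gains=k.gains**2, center_frequency=k.center_frequency, fwhm=k.fwhm,
            n_samples=k.n_samples, sampling_rate=k.sampling_rate,
        )
        direct = fn.narrowband_filter(small_dataset, k2)
        assert np.allclose(twice.data, direct.data, atol=1e-10)

    def test_output_power_bounded_by_input(self, small_dataset):
        # all gains <= 1, so filtering cannot add power (Parseval)
        k = fn.design_gaussian_kernel(8.0, 2.0, small_dataset.n_samples, small_dataset.sampling_rate)
        out = fn.narrowband_filter(small_dataset, k)
        centered_in = small_dataset.data - small_dataset.data.mean(1, keepdims=True)
        assert (out.data**2).sum() <= (centered_in**2).sum() + 1e-9

    def test_spectral_centroid_near_center(self, rng):
        data = rng.standard_normal((4, 5000))
        ds = VoxelDataset(data=data, sampling_rate=100.0)
        k = fn.design_gaussian_kernel(20.0, 4.0, 5000, 100.0)
        out = fn.narrowband_filter(ds, k)
        spec = np.abs(np.fft.rfft(out.data, axis=1)) ** 2
        freqs = np.fft.rfftfreq(5000, 0.01)
        centroid = (spec * freqs).sum() / spec.sum()
        assert abs(centroid - 20.0) <= 4.0

    def test_shape_mismatch_rejected(self, small_dataset):
        k = fn.design_gaussian_kernel(10.0, 1.0, 123, 100.0)
        with pytest.raises(DataError, match="kernel built for"):
            fn.narrowband_filter(small_dataset, k)


class TestAnalyticSignal:
    def test_cosine_has_unit_envelope(self):
        fs, f = 250.0, 10.0
        t = np.arange(5000) / fs
        z = fn.analytic_signal(np.cos(2 * np.pi * f * t))
        interior = np.abs(z)[200:-200]
        assert np.allclose(interior, 1.0, atol=1e-3)

    def test_phase_slope_matches_frequency(self):
        fs, f = 250.0, 7.0
        t = np.arange(5000) / fs
        z = fn.analytic_signal(np.cos(2 * np.pi * f * t))
        phase = np.unwrap(np.angle(z))[200:-200]
        slope = np.polyfit(t[200:-200], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=1e-3)

    def test_real_part_is_input(self, rng):
        x = rng.standard_normal(1024)
        assert np.allclose(fn.analytic_signal(x).real, x, atol=1e-10)
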