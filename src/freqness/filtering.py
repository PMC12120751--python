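"""Frequency grid construction and Gaussian frequency-domain filtering.

Narrowband voxel data is obtained by multiplying the FFT of each voxel's time
series with a Gaussian gain profile centered on the scan frequency and
transforming back — a frequency-domain wavelet filter.  The gain is

    G(f) = exp(-4 ln2 (|f| - f0)^2 / w^2)

with ``w`` the full width at half maximum in Hz, evaluated at the FFT bin
frequencies of the full (unsegmented) recording and mirrored over negative
frequencies so the filtered signal stays real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
import scipy.signal

from .datamodel import FrequencyGrid, NarrowbandDataset, VoxelDataset
from .errors import DataError

__all__ = [
    "GaussianKernel",
    "build_frequency_grid",
    "fwhm_schedule",
    "design_gaussian_kernel",
    "narrowband_filter",
    "analytic_signal",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass
class GaussianKernel:
    """Frequency-domain Gaussian gain profile for one scan frequency.

    ``gains`` is defined over the two-sided FFT bin frequencies (numpy
    ``fftfreq`` ordering) of an ``n_samples``-long signal; Hermitian symmetry
    is guaranteed by construction, and the peak gain is normalized to 1 at the
    bin nearest the center frequency.
    """

    gains: np.ndarray
    center_frequency: float
    fwhm: float
    n_samples: int
    sampling_rate: float

    @property
    def bin_width(self) -> float:
        return self.sampling_rate / self.n_samples

    def rfft_gains(self) -> np.ndarray:
        """Gains restricted to the non-negative (rfft) bins."""
        n_r = self.n_samples // 2 + 1
        return self.gains[:n_r].copy()


def fwhm_schedule(
    center: float,
    base_fwhm_at_stim: float = 0.3,
    stimulation_frequency: float = 2.4,
    slope: float = 1.0,
) -> float:
    """Filter bandwidth (FWHM, Hz) as a log10-linear function of frequency.

    ``fwhm(f) = base * 10**(slope * (log10 f - log10 f_stim))``; slope 1 gives
    constant relative bandwidth (the usual wavelet convention), slope 0 a
    constant absolute bandwidth.
    """
    if center <= 0 or base_fwhm_at_stim <= 0 or stimulation_frequency <= 0:
        raise DataError("fwhm_schedule arguments must be positive")
    return float(base_fwhm_at_stim * (center / stimulation_frequency) ** slope)


def build_frequency_grid(
    stimulation_frequency: float = 2.4,
    f_max: float = 97.6,
    step_above: float = 1.2,
    n_below: int = 6,
    step_below: float = 0.2,
    sub_stim_centers: list[float] | None = None,
    fwhm_base: float = 0.3,
    fwhm_log10_slope: float = 1.0,
    nyquist: float | None = None,
) -> FrequencyGrid:
    """Build the scanning grid around a stimulation frequency.

    The grid consists of ``n_below`` centers below the stimulation frequency
    (by default a ``step_below``-spaced ascending series anchored at 0.2 Hz,
    overridable via ``sub_stim_centers``), the stimulation frequency itself,
    and ``stimulation_frequency + k*step_above`` for k = 1, 2, ... while the
    result stays at or below ``f_max``.  With the defaults this yields 86
    centers from 0.2 Hz up to the highest 1.2 Hz lattice point under 97.6 Hz,
    with every second center above the stimulation frequency an integer
    multiple of it.
    """
    if stimulation_frequency <= 0 or step_above <= 0 or step_below <= 0:
        raise DataError("frequencies and steps must be positive")
    if sub_stim_centers is None:
        sub_stim_centers = [0.2 + step_below * k for k in range(n_below)]
    else:
        sub_stim_centers = [float(f) for f in sub_stim_centers]
    if len(sub_stim_centers) != n_below:
        raise DataError(f"expected {n_below} sub-stimulation centers, got {len(sub_stim_centers)}")
    if any(f <= 0 or f >= stimulation_frequency for f in sub_stim_centers):
        raise DataError("sub-stimulation centers must lie in (0, stimulation_frequency)")

    n_above = int(np.floor((f_max - stimulation_frequency) / step_above + 1e-9))
    above = stimulation_frequency + step_above * np.arange(1, n_above + 1)
    centers = np.concatenate([sub_stim_centers, [stimulation_frequency], above])
    if nyquist is not None:
        bad = centers[centers >= nyquist]
        if len(bad):
            raise DataError(f"grid centers at or above Nyquist ({nyquist} Hz): {bad.tolist()}")
    fwhms = np.array(
        [fwhm_schedule(c, fwhm_base, stimulation_frequency, fwhm_log10_slope) for c in centers]
    )
    return FrequencyGrid(centers=centers, fwhms=fwhms, stimulation_frequency=stimulation_frequency)


def gaussian_gains(freqs: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unnormalized Gaussian gain profile evaluated at ``freqs`` (Hz)."""
    return np.exp(-_LN2_4 * (np.abs(freqs) - center) ** 2 / fwhm**2)


def design_gaussian_kernel(
    center: float, fwhm: float, n_samples: int, sampling_rate: float
) -> GaussianKernel:
    """Gaussian frequency-domain kernel for an ``n_samples``-long recording."""
    nyq = sampling_rate / 2.0
    if not 0 < center < nyq:
        raise DataError(f"center frequency {center} Hz outside (0, Nyquist={nyq})")
    if fwhm <= 0:
        raise DataError("fwhm must be positive")
    if n_samples < 16:
        raise DataError("need at least 16 samples")
    bin_width = sampling_rate / n_samples
    if fwhm < bin_width:
        warnings.warn(
            f"kernel FWHM {fwhm} Hz is narrower than one FFT bin ({bin_width:.4g} Hz); "
            "the filter is under-resolved",
            stacklevel=2,
        )
    freqs = sfft.fftfreq(n_samples, d=1.0 / sampling_rate)
    gains = gaussian_gains(freqs, center, fwhm)
    gains /= gains.max()  # peak exactly 1 at the bin nearest the center
    return GaussianKernel(
        gains=gains,
        center_frequency=float(center),
        fwhm=float(fwhm),
        n_samples=int(n_samples),
        sampling_rate=float(sampling_rate),
    )


def _filter_rows(data: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    spectra = sfft.rfft(data, axis=-1)
    spectra *= kernel.rfft_gains()
    return sfft.irfft(spectra, n=kernel.n_samples, axis=-1)


def narrowband_filter(dataset: VoxelDataset, kernel: GaussianKernel) -> NarrowbandDataset:
    """Apply the Gaussian kernel to every voxel row of a broadband dataset."""
    if kernel.n_samples != dataset.n_samples or kernel.sampling_rate != dataset.sampling_rate:
        raise DataError(
            f"kernel built for n_samples={kernel.n_samples}, fs={kernel.sampling_rate}; "
            f"dataset has n_samples={dataset.n_samples}, fs={dataset.sampling_rate}"
        )
    filtered = _filter_rows(dataset.data, kernel)
    return NarrowbandDataset(
        data=filtered,
        sampling_rate=dataset.sampling_rate,
        subject_id=dataset.subject_id,
        condition=dataset.condition,
        coordinates=dataset.coordinates,
        grid_spacing_mm=dataset.grid_spacing_mm,
        center_frequency=kernel.center_frequency,
        fwhm=kernel.fwhm,
    )


def filter_vector(x: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Narrowband-filter a single 1-D time series with the kernel."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != kernel.n_samples:
        raise DataError(f"kernel built for {kernel.n_samples} samples, got {len(x)}")
    return _filter_rows(x[None, :], kernel)[0]


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal ``x + i H(x)`` (Hilbert transform) of a real vector."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 16:
        raise DataError("need at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in input")
    return scipy.signal.hilbert(x)


def measure_fwhm(kernel: GaussianKernel) -> float:
    """Measured full width at half maximum gain of a kernel, in Hz.

    Locates the two half-gain crossings around the peak on the non-negative
    frequency axis by linear interpolation between FFT bins.
    """
    n_r = kernel.n_samples // 2 + 1
    freqs = np.arange(n_r) * kernel.bin_width
    gains = kernel.gains[:n_r]
    peak = int(np.argmax(gains))

    def crossing(idx_range) -> float:
        for i in idx_range:
            lo, hi = sorted((gains[i], gains[i + 1]))
            if lo <= 0.5 <= hi:
                frac = (0.5 - gains[i]) / (gains[i + 1] - gains[i])
                return freqs[i] + frac * kernel.bin_width
        raise DataError("no half-maximum crossing found")

    left = crossing(range(peak - 1, -1, -1))
    right = crossing(range(peak, n_r - 1))
    return float(right - left)
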