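"""Phase-amplitude cross-frequency coupling between network time series.

The low-frequency modulator network's instantaneous phase (Hilbert transform
of its narrowband-filtered time course) is divided into 36 bins of 10 degrees;
the mean instantaneous power of each higher-frequency carrier network within
each phase bin gives a power-over-phase distribution, and the amplitude of a
one-cycle sine fitted to that distribution is the modulation strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import FrequencyGrid, Landscape, NetworkTimeSeries, VoxelDataset
from .errors import DataError
from .filtering import GaussianKernel, analytic_signal, design_gaussian_kernel, filter_vector
from . import ged

__all__ = [
    "SineFit",
    "ModulationProfile",
    "extract_phase",
    "extract_power",
    "power_over_phase",
    "phase_bin_centers",
    "fit_sine",
    "modulation_profile",
    "cfc_scan",
]

DEFAULT_N_BINS = 36


@dataclass
class SineFit:
    """One-cycle sine fit ``A sin(theta + phi) + c`` over the phase axis."""

    amplitude: float
    phase_deg: float
    offset: float


@dataclass
class ModulationProfile:
    """Carrier power distribution over modulator phase, with fitted sine."""

    modulator_frequency: float
    modulator_component: int
    carrier_frequency: float
    carrier_component: int
    bin_power: np.ndarray
    bin_centers: np.ndarray  # degrees, -175 .. +175 for 36 bins
    sine_fit: SineFit
    interpolated_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.bin_power = np.asarray(self.bin_power, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.bin_power.shape != self.bin_centers.shape:
            raise DataError("bin_power and bin_centers must match")
        if np.any(self.bin_power < 0):
            raise DataError("bin powers must be non-negative")

    @property
    def modulation_strength(self) -> float:
        return self.sine_fit.amplitude

    @property
    def relative_strength(self) -> float:
        """Sine amplitude divided by offset: power-normalized modulation depth.

        Comparable across carriers of different absolute power (the raw
        strength carries the carrier's power units).
        """
        return self.sine_fit.amplitude / self.sine_fit.offset


def _narrowband_analytic(y, kernel: GaussianKernel) -> np.ndarray:
    values = y.values if isinstance(y, NetworkTimeSeries) else np.asarray(y, dtype=float)
    return analytic_signal(filter_vector(values, kernel))


def extract_phase(y, kernel: GaussianKernel) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) of the narrowband analytic signal.

    The first and last second are kept in the returned vector but should be
    discarded before binning (edge transients of the filter and Hilbert
    transform); :func:`modulation_profile` applies that guard.
    """
    values = y.values if isinstance(y, NetworkTimeSeries) else np.asarray(y, dtype=float)
    analytic = _narrowband_analytic(values, kernel)
    scale = max(float(np.abs(values).max()), 1.0)
    if np.abs(analytic).max() <= 1e-12 * scale:
        raise DataError("analytic magnitude is (near) zero; phase undefined")
    return np.angle(analytic)


def extract_power(y, kernel: GaussianKernel) -> np.ndarray:
    """Instantaneous power (squared analytic magnitude) of the narrowband signal."""
    analytic = _narrowband_analytic(y, kernel)
    return np.abs(analytic) ** 2


def phase_bin_centers(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Bin centers in degrees for left-closed bins starting at -180 degrees."""
    width = 360.0 / n_bins
    return -180.0 + width * (np.arange(n_bins) + 0.5)


def power_over_phase(
    phase: np.ndarray,
    power: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    max_empty_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean carrier power per modulator phase bin.

    Bins are left-closed, right-open, 360/n_bins degrees wide, starting at
    -180 degrees.  Empty bins are filled by (circular) linear interpolation of
    their neighbors and reported; more than ``max_empty_fraction`` empty bins
    raises (the recording is too short for the modulator frequency).

    Returns ``(bin_power, empty_bin_indices)``.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    power = np.asarray(power, dtype=float).ravel()
    if phase.shape != power.shape:
        raise DataError("phase and power must have equal length")
    if n_bins < 4:
        raise DataError("need at least 4 bins")
    width = 2.0 * np.pi / n_bins
    idx = np.floor((phase + np.pi) / width).astype(int)
    idx[idx == n_bins] = 0  # phase exactly +pi wraps into the first bin
    if np.any((idx < 0) | (idx >= n_bins)):
        raise DataError("phase values outside (-pi, pi]")

    sums = np.bincount(idx, weights=power, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    empty = np.flatnonzero(counts == 0)
    if len(empty) > max_empty_fraction * n_bins:
        raise DataError(
            f"{len(empty)}/{n_bins} phase bins empty; recording too short for this modulator"
        )
    bin_power = np.full(n_bins, np.nan)
    filled = counts > 0
    bin_power[filled] = sums[filled] / counts[filled]
    if len(empty):
        # circular linear interpolation over the filled bins
        centers = phase_bin_centers(n_bins)
        filled_idx = np.flatnonzero(filled)
        bin_power[empty] = np.interp(
            centers[empty],
            np.concatenate([centers[filled_idx] - 360.0, centers[filled_idx], centers[filled_idx] + 360.0]),
            np.tile(bin_power[filled_idx], 3),
        )
    return bin_power, empty


def fit_sine(bin_power: np.ndarray, bin_centers_deg: np.ndarray | None = None) -> SineFit:
    """Closed-form least-squares fit of ``A sin(theta + phi) + c`` (period 360 deg).

    With the period fixed at one cycle the model is linear in
    ``(A cos phi, A sin phi, c)``; the fit projects onto the sin/cos/constant
    basis.  ``A >= 0`` by convention (a negative amplitude is folded into the
    phase).  A flat distribution gives amplitude 0.
    """
    y = np.asarray(bin_power, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite bin powers")
    if bin_centers_deg is None:
        bin_centers_deg = phase_bin_centers(len(y))
    theta = np.deg2rad(np.asarray(bin_centers_deg, dtype=float).ravel())
    design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(theta)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    b_sin, b_cos, offset = coef
    amplitude = float(np.hypot(b_sin, b_cos))
    phase = float(np.rad2deg(np.arctan2(b_cos, b_sin))) if amplitude > 0 else 0.0
    return SineFit(amplitude=amplitude, phase_deg=phase, offset=float(offset))


def modulation_profile(
    modulator: NetworkTimeSeries,
    carrier: NetworkTimeSeries,
    modulator_kernel: GaussianKernel,
    carrier_kernel: GaussianKernel,
    n_bins: int = DEFAULT_N_BINS,
    edge_guard_s: float = 1.0,
) -> ModulationProfile:
    """Phase-amplitude coupling profile for one modulator/carrier pair."""
    phase = extract_phase(modulator, modulator_kernel)
    power = extract_power(carrier, carrier_kernel)
    guard = int(round(edge_guard_s * modulator.sampling_rate))
    if guard > 0 and len(phase) > 2 * guard + n_bins:
        phase = phase[guard:-guard]
        power = power[guard:-guard]
    bin_power, empty = power_over_phase(phase, power, n_bins)
    fit = fit_sine(bin_power)
    return ModulationProfile(
        modulator_frequency=modulator_kernel.center_frequency,
        modulator_component=modulator.component_index,
        carrier_frequency=carrier_kernel.center_frequency,
        carrier_component=carrier.component_index,
        bin_power=bin_power,
        bin_centers=phase_bin_centers(n_bins),
        sine_fit=fit,
        interpolated_bins=empty,
    )


def cfc_scan(
    broad: VoxelDataset,
    landscape: Landscape,
    grid: FrequencyGrid,
    modulator_frequency: float = 2.4,
    modulator_component: int = 1,
    carrier_component: int = 1,
    n_bins: int = DEFAULT_N_BINS,
    edge_guard_s: float = 1.0,
) -> list[ModulationProfile]:
    """Modulation profiles from one low-frequency network to all higher carriers.

    The modulator is the given component of the grid bin nearest
    ``modulator_frequency``; each grid frequency strictly above it contributes
    one carrier (its ``carrier_component``-th network).  Network time series
    are reconstructed from the landscape's stored spatial filters and the
    broadband data, then narrowband filtered with the same kernels used for
    the decomposition.
    """
    mod_idx = grid.nearest_index(modulator_frequency)
    mod_center, mod_fwhm = grid.centers[mod_idx], grid.fwhms[mod_idx]
    key = (broad.subject_id, broad.condition, float(mod_center), int(modulator_component))
    if key not in landscape.filters:
        raise DataError(f"no stored filter for modulator {key}")
    mod_kernel = design_gaussian_kernel(mod_center, mod_fwhm, broad.n_samples, broad.sampling_rate)
    modulator = ged.component_timeseries(
        landscape.filters[key], broad, mod_center, modulator_component
    )

    profiles = []
    for center, fwhm in grid:
        if center <= mod_center:
            continue
        car_key = (broad.subject_id, broad.condition, float(center), int(carrier_component))
        if car_key not in landscape.filters:
            raise DataError(f"no stored filter for carrier {car_key}")
        carrier = ged.component_timeseries(
            landscape.filters[car_key], broad, center, carrier_component
        )
        car_kernel = design_gaussian_kernel(center, fwhm, broad.n_samples, broad.sampling_rate)
        profiles.append(
            modulation_profile(
                modulator, carrier, mod_kernel, car_kernel, n_bins, edge_guard_s
            )
        )
    return profiles
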