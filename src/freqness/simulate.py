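"""Synthetic voxel-space datasets with planted ground truth.

Each dataset is a linear mixture of (i) frequency-specific latent networks —
fixed spatial loading vectors (Gaussian blobs on a 3-D source lattice) times
narrowband oscillatory time courses (Gaussian-filtered noise, so that the
Hilbert phase is non-degenerate), (ii) per-voxel 1/f^beta aperiodic
background, and (iii) per-voxel white noise; optionally the instantaneous
amplitude of one network's source is modulated by another network's phase
(phase-amplitude coupling of depth kappa).

Every stage of the estimation pipeline can therefore be checked against the
planted loadings, source time courses and coupling depth, without any
external recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import VoxelDataset
from .errors import DataError
from .filtering import design_gaussian_kernel, filter_vector, analytic_signal

__all__ = [
    "PlantedNetwork",
    "PacSpec",
    "ConditionEffect",
    "SimulationSpec",
    "make_lattice_coordinates",
    "gaussian_blob_loading",
    "narrowband_noise",
    "one_over_f_noise",
    "simulate_dataset",
    "simulate_group",
    "simulate_group_differences",
    "default_two_network_spec",
    "default_pac_spec",
]


@dataclass
class PlantedNetwork:
    """One latent network: spatial loading (unit max) and source parameters."""

    loading: np.ndarray
    center_frequency: float
    bandwidth: float  # FWHM of the source spectrum, Hz
    amplitude: float  # source RMS in voxel units

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=float).ravel()
        if self.loading.max() <= 0:
            raise DataError("loading must have a positive maximum")
        self.loading = self.loading / self.loading.max()
        if self.center_frequency <= 0 or self.bandwidth <= 0 or self.amplitude < 0:
            raise DataError("invalid network parameters")


@dataclass
class PacSpec:
    """Phase-amplitude coupling between two planted networks."""

    modulator_index: int
    carrier_index: int
    depth: float  # kappa in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise DataError("coupling depth must lie in [0, 1]")


@dataclass
class SimulationSpec:
    """Full description of one synthetic recording."""

    n_voxels: int = 200
    duration_s: float = 120.0
    sampling_rate: float = 250.0
    networks: list[PlantedNetwork] = field(default_factory=list)
    aperiodic_exponent: float = 1.0
    background_rms: float = 1.0
    white_noise_rms: float = 0.5
    pac: PacSpec | None = None
    seed: int = 0
    grid_spacing_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.background_rms < 0 or self.white_noise_rms < 0:
            raise DataError("noise RMS values must be non-negative")
        nyq = self.sampling_rate / 2.0
        for net in self.networks:
            if net.center_frequency >= nyq:
                raise DataError(
                    f"network at {net.center_frequency} Hz at or above Nyquist ({nyq} Hz)"
                )
            if len(net.loading) != self.n_voxels:
                raise DataError("loading length must equal n_voxels")
        if self.pac is not None:
            k = len(self.networks)
            if not (0 <= self.pac.modulator_index < k and 0 <= self.pac.carrier_index < k):
                raise DataError("PAC indices out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))


def make_lattice_coordinates(n_voxels: int, spacing_mm: float = 8.0) -> np.ndarray:
    """First ``n_voxels`` sites of an axis-aligned cubic lattice, MNI-like mm."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    axes = (np.arange(side) - (side - 1) / 2.0) * spacing_mm
    grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[:n_voxels]


def gaussian_blob_loading(
    coordinates: np.ndarray, center_mm: np.ndarray, sigma_mm: float
) -> np.ndarray:
    """Isotropic Gaussian spatial loading over lattice coordinates, unit max."""
    d2 = ((coordinates - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    loading = np.exp(-d2 / (2.0 * sigma_mm**2))
    return loading / loading.max()


def narrowband_noise(
    n_samples: int, sampling_rate: float, center: float, bandwidth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS narrowband oscillation: Gaussian-filtered white noise."""
    kernel = design_gaussian_kernel(center, bandwidth, n_samples, sampling_rate)
    x = filter_vector(rng.standard_normal(n_samples), kernel)
    return x / x.std()


def one_over_f_noise(
    n_samples: int, sampling_rate: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS aperiodic background via spectral shaping: power ~ 1/f^beta."""
    spectrum = np.fft.rfft(rng.standard_normal(n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n_samples)
    return x / x.std()


def _apply_pac(sources: np.ndarray, pac: PacSpec) -> np.ndarray:
    """Multiply the carrier source by (1 + kappa sin(phase_mod)) / (1 + kappa).

    The (1 + kappa) normalization keeps the carrier's mean power approximately
    independent of the coupling depth, isolating coupling from power changes.
    """
    phase = np.angle(analytic_signal(sources[pac.modulator_index]))
    envelope = (1.0 + pac.depth * np.sin(phase)) / (1.0 + pac.depth)
    out = sources.copy()
    out[pac.carrier_index] = sources[pac.carrier_index] * envelope
    return out


def simulate_dataset(spec: SimulationSpec) -> tuple[VoxelDataset, dict]:
    """Generate one voxel dataset and its ground-truth record.

    The truth dict holds the (possibly PAC-modulated) source time courses
    (``sources``, k x T), the loading matrix (``loadings``, k x n_voxels), and
    the spec itself.  Identical spec and seed give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = spec.n_samples
    coords = make_lattice_coordinates(spec.n_voxels, spec.grid_spacing_mm)

    sources = np.zeros((len(spec.networks), n_t))
    for k, net in enumerate(spec.networks):
        sources[k] = net.amplitude * narrowband_noise(
            n_t, spec.sampling_rate, net.center_frequency, net.bandwidth, rng
        )
    if spec.pac is not None and len(spec.networks):
        sources = _apply_pac(sources, spec.pac)

    data = np.zeros((spec.n_voxels, n_t))
    for k, net in enumerate(spec.networks):
        data += np.outer(net.loading, sources[k])
    if spec.background_rms > 0:
        for v in range(spec.n_voxels):
            data[v] += spec.background_rms * one_over_f_noise(
                n_t, spec.sampling_rate, spec.aperiodic_exponent, rng
            )
    if spec.white_noise_rms > 0:
        data += spec.white_noise_rms * rng.standard_normal((spec.n_voxels, n_t))

    dataset = VoxelDataset(
        data=data,
        sampling_rate=spec.sampling_rate,
        coordinates=coords,
        grid_spacing_mm=spec.grid_spacing_mm,
    )
    truth = {
        "sources": sources,
        "loadings": np.array([net.loading for net in spec.networks]),
        "spec": spec,
    }
    return dataset, truth


@dataclass
class ConditionEffect:
    """What the stimulation-like condition adds relative to rest.

    ``added_network`` is planted only in the second (PL-like) condition;
    ``amplitude_scale`` multiplies every shared network's amplitude;
    ``kappa_delta`` is added to the PAC depth (clipped to [0, 1]).
    """

    added_network: PlantedNetwork | None = None
    amplitude_scale: float = 1.0
    kappa_delta: float = 0.0


def _jitter_networks(
    networks: list[PlantedNetwork], rng: np.random.Generator,
    amplitude_jitter: float, loading_jitter: float,
) -> list[PlantedNetwork]:
    out = []
    for net in networks:
        amp = net.amplitude * float(np.exp(amplitude_jitter * rng.standard_normal()))
        loading = net.loading + loading_jitter * rng.standard_normal(len(net.loading))
        loading = np.clip(loading, 0.0, None)
        out.append(replace(net, amplitude=amp, loading=loading))
    return out


def simulate_group(
    spec_base: SimulationSpec,
    n_subjects: int = 26,
    condition_effect: ConditionEffect | None = None,
    seed: int = 0,
    amplitude_jitter: float = 0.1,
    loading_jitter: float = 0.02,
) -> list[dict]:
    """Paired RS-like / PL-like datasets for a group of subjects.

    Each subject gets jittered copies of the base networks (log-normal
    amplitude jitter, additive loading jitter); the two conditions share the
    subject's loadings and differ only by ``condition_effect``.  Independent
    seeds per subject and condition make the recordings independent.
    """
    if n_subjects < 2:
        raise DataError("need at least 2 subjects for a paired design")
    if n_subjects < 5:
        warnings.warn(
            f"{n_subjects} subjects is below the minimum for meaningful paired "
            "group statistics (5)", stacklevel=2,
        )
    effect = condition_effect or ConditionEffect()
    master = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        subject_id = f"sub{s + 1:02d}"
        jitter_rng = np.random.default_rng(master.integers(2**31))
        nets = _jitter_networks(spec_base.networks, jitter_rng, amplitude_jitter, loading_jitter)

        rs_spec = replace(spec_base, networks=nets, seed=int(master.integers(2**31)))
        pl_nets = [replace(n, amplitude=n.amplitude * effect.amplitude_scale) for n in nets]
        if effect.added_network is not None:
            pl_nets = pl_nets + [effect.added_network]
        pl_pac = spec_base.pac
        if pl_pac is not None and effect.kappa_delta:
            pl_pac = replace(pl_pac, depth=float(np.clip(pl_pac.depth + effect.kappa_delta, 0, 1)))
        pl_spec = replace(
            spec_base, networks=pl_nets, pac=pl_pac, seed=int(master.integers(2**31))
        )

        rs_data, rs_truth = simulate_dataset(rs_spec)
        pl_data, pl_truth = simulate_dataset(pl_spec)
        rs_data = replace(rs_data, subject_id=subject_id, condition="RS")
        pl_data = replace(pl_data, subject_id=subject_id, condition="PL")
        subjects.append(
            {"subject_id": subject_id, "RS": rs_data, "PL": pl_data,
             "truth": {"RS": rs_truth, "PL": pl_truth}}
        )
    return subjects


def simulate_group_differences(
    n_subjects: int = 26,
    n_bins: int = 40,
    effect_bins: np.ndarray | list[int] = (),
    effect_size: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Subjects x bins matrix of paired condition differences for calibration.

    Unit-variance Gaussian differences with mean ``effect_size`` (Cohen's d)
    at the listed bins and 0 elsewhere — the group-level shortcut used to
    calibrate the statistical machinery without running the full pipeline per
    subject.
    """
    rng = np.random.default_rng(seed)
    diffs = rng.standard_normal((n_subjects, n_bins))
    diffs[:, list(effect_bins)] += effect_size
    return diffs


def default_two_network_spec(seed: int = 0, n_voxels: int = 200, duration_s: float = 120.0) -> SimulationSpec:
    """Two planted networks at 10.8 and 16.8 Hz in non-overlapping blobs.

    Frequencies sit on default scan-grid centers; source RMS is twice the
    aperiodic background RMS (the default signal-to-noise condition).
    """
    coords = make_lattice_coordinates(n_voxels)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    net1 = PlantedNetwork(
        loading=gaussian_blob_loading(coords, lo + 0.25 * (hi - lo), sigma_mm=12.0),
        center_frequency=10.8, bandwidth=1.0, amplitude=2.0,
    )
    net2 = PlantedNetwork(
        loading=gaussian_blob_loading(coords, lo + 0.75 * (hi - lo), sigma_mm=12.0),
        center_frequency=16.8, bandwidth=1.5, amplitude=2.0,
    )
    return SimulationSpec(
        n_voxels=n_voxels, duration_s=duration_s, networks=[net1, net2], seed=seed
    )


def default_pac_spec(
    seed: int = 0,
    depth: float = 0.8,
    n_voxels: int = 48,
    duration_s: float = 60.0,
    modulator_frequency: float = 2.4,
    carrier_frequency: float = 40.8,
) -> SimulationSpec:
    """Modulator (2.4 Hz) and carrier (~40 Hz) networks with PAC of given depth."""
    coords = make_lattice_coordinates(n_voxels)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    modulator = PlantedNetwork(
        loading=gaussian_blob_loading(coords, lo + 0.2 * (hi - lo), sigma_mm=10.0),
        center_frequency=modulator_frequency, bandwidth=0.3, amplitude=2.0,
    )
    carrier = PlantedNetwork(
        loading=gaussian_blob_loading(coords, lo + 0.8 * (hi - lo), sigma_mm=10.0),
        center_frequency=carrier_frequency, bandwidth=4.0, amplitude=2.0,
    )
    return SimulationSpec(
        n_voxels=n_voxels, duration_s=duration_s,
        networks=[modulator, carrier],
        pac=PacSpec(modulator_index=0, carrier_index=1, depth=depth),
        seed=seed,
    )
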