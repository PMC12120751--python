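"""Core domain containers.

The analysis operates on voxel-space multivariate time series (one matrix of
``n_voxels x n_samples`` per subject and condition, e.g. beamformed MEG
sources), a grid of scan frequencies with per-frequency filter widths, and the
per-frequency network decompositions (eigenvalues, spatial filters, activation
patterns) that together form the "network landscape".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "VoxelDataset",
    "NarrowbandDataset",
    "FrequencyGrid",
    "NetworkDecomposition",
    "NetworkTimeSeries",
    "Landscape",
]


def _as_2d_float(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise DataError(f"expected a 2-D voxels x time matrix, got shape {arr.shape}")
    return arr


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise DataError(f"non-finite value in {what} at index {tuple(int(i) for i in bad)}")


@dataclass
class VoxelDataset:
    """One subject/condition broadband recording in voxel (source) space.

    Parameters
    ----------
    data
        ``n_voxels x n_samples`` real matrix, arbitrary amplitude units.
    sampling_rate
        Sampling frequency in Hz.
    coordinates
        Optional ``n_voxels x 3`` MNI coordinates in mm.
    grid_spacing_mm
        Optional uniform lattice spacing of the source grid.
    """

    data: np.ndarray
    sampling_rate: float
    subject_id: str = "s01"
    condition: str = "RS"
    coordinates: np.ndarray | None = None
    grid_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data)
        _check_finite(self.data, "data")
        self.sampling_rate = float(self.sampling_rate)
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if self.n_voxels < 2:
            raise DataError("need at least 2 voxels")
        if self.n_samples < 2 * self.sampling_rate:
            raise DataError(
                f"need at least 2 s of data ({2 * self.sampling_rate:.0f} samples), "
                f"got {self.n_samples}"
            )
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (self.n_voxels, 3):
                raise DataError(
                    f"coordinates shape {self.coordinates.shape} does not match "
                    f"({self.n_voxels}, 3)"
                )
            if len(np.unique(self.coordinates, axis=0)) != self.n_voxels:
                raise DataError("coordinate rows must be unique")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class NarrowbandDataset(VoxelDataset):
    """Narrowband-filtered copy of a :class:`VoxelDataset`."""

    center_frequency: float = 0.0
    fwhm: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.center_frequency <= 0 or self.fwhm <= 0:
            raise DataError("center_frequency and fwhm must be positive")


@dataclass
class FrequencyGrid:
    """Ordered scan frequencies with matching filter bandwidths (FWHM, Hz)."""

    centers: np.ndarray
    fwhms: np.ndarray
    stimulation_frequency: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.fwhms = np.asarray(self.fwhms, dtype=float)
        if self.centers.ndim != 1 or self.fwhms.shape != self.centers.shape:
            raise DataError("centers and fwhms must be 1-D and the same length")
        if len(self.centers) == 0:
            raise DataError("empty frequency grid")
        if np.any(self.centers <= 0):
            raise DataError("all centers must be > 0")
        if np.any(np.diff(self.centers) <= 0):
            raise DataError("centers must be strictly increasing")
        if np.any(self.fwhms <= 0):
            raise DataError("all fwhms must be > 0")

    def __len__(self) -> int:
        return len(self.centers)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.centers, self.fwhms))

    def nearest_index(self, frequency: float) -> int:
        return int(np.argmin(np.abs(self.centers - frequency)))

    def validate_nyquist(self, nyquist: float) -> None:
        bad = self.centers[self.centers >= nyquist]
        if len(bad):
            raise DataError(f"grid centers at or above Nyquist ({nyquist} Hz): {bad.tolist()}")


@dataclass
class NetworkDecomposition:
    """Eigen-decomposition of one frequency bin.

    ``eigenvalues`` holds the full descending spectrum of the (generalized)
    eigenproblem; ``normalized_eigenvalues`` expresses each as percent of total
    variance (sums to 100).  ``filters``/``patterns`` keep only the leading
    components (columns), ordered by explained variance.
    """

    frequency: float
    eigenvalues: np.ndarray
    normalized_eigenvalues: np.ndarray
    filters: np.ndarray
    patterns: np.ndarray
    method: str = "ged"
    regularization: tuple[float, float] = (1e-6, 0.01)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.normalized_eigenvalues = np.asarray(self.normalized_eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10 * max(1.0, abs(self.eigenvalues[0]))):
            raise DataError("eigenvalues must be sorted descending")
        total = self.normalized_eigenvalues.sum()
        if abs(total - 100.0) > 1e-6:
            raise DataError(f"normalized eigenvalues sum to {total}, expected 100")
        if self.patterns.size:
            maxes = np.abs(self.patterns).max(axis=0)
            if np.any(np.abs(maxes - 1.0) > 1e-9) or np.any(self.patterns < -1e-12):
                raise DataError("each pattern column must lie in [0, 1] with max exactly 1")
        if self.filters.shape[1] > self.filters.shape[0]:
            raise DataError("more components than voxels")

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]


@dataclass
class NetworkTimeSeries:
    """Component time course ``y = w^T X_broad`` for one network."""

    values: np.ndarray
    frequency: float
    component_index: int  # 1-based rank by explained variance
    sampling_rate: float
    subject_id: str = "s01"
    condition: str = "RS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        _check_finite(self.values, "network time series")
        if self.component_index < 1:
            raise DataError("component_index is 1-based")


_EIG_COLUMNS = ["subject", "condition", "frequency_hz", "component", "eigenvalue_pct"]


class Landscape:
    """Network landscape: normalized eigenvalues (and patterns/filters) over
    subjects, conditions, frequencies and component ranks."""

    def __init__(self) -> None:
        self._rows: list[tuple] = []
        self._frame: pd.DataFrame | None = None
        # keyed by (subject, condition, frequency_hz, component)
        self.patterns: dict[tuple, np.ndarray] = {}
        self.filters: dict[tuple, np.ndarray] = {}

    # -- construction -----------------------------------------------------
    def add(
        self,
        subject: str,
        condition: str,
        frequency_hz: float,
        component: int,
        eigenvalue_pct: float,
        pattern: np.ndarray | None = None,
        spatial_filter: np.ndarray | None = None,
    ) -> None:
        key = (subject, condition, float(frequency_hz), int(component))
        self._rows.append(key + (float(eigenvalue_pct),))
        self._frame = None
        if pattern is not None:
            self.patterns[key] = np.asarray(pattern, dtype=float)
        if spatial_filter is not None:
            self.filters[key] = np.asarray(spatial_filter, dtype=float)

    def merge(self, other: "Landscape") -> "Landscape":
        """Absorb another landscape's records (e.g. other subjects/conditions)."""
        self._rows.extend(other._rows)
        self._frame = None
        self.patterns.update(other.patterns)
        self.filters.update(other.filters)
        return self

    # -- access -----------------------------------------------------------
    @property
    def eigenvalues(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(self._rows, columns=_EIG_COLUMNS)
        return self._frame

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def frequencies(self) -> np.ndarray:
        return np.sort(self.eigenvalues["frequency_hz"].unique())

    def subjects(self) -> list[str]:
        return sorted(self.eigenvalues["subject"].unique())

    def select(self, **kwargs) -> pd.DataFrame:
        frame = self.eigenvalues
        for col, val in kwargs.items():
            frame = frame[frame[col] == val]
        return frame

    def eigenvalue(self, subject: str, condition: str, frequency_hz: float, component: int) -> float:
        row = self.select(
            subject=subject, condition=condition, frequency_hz=float(frequency_hz), component=int(component)
        )
        if row.empty:
            raise KeyError((subject, condition, frequency_hz, component))
        return float(row["eigenvalue_pct"].iloc[0])

    def group_mean_sem(self) -> pd.DataFrame:
        """Mean and SEM of eigenvalue_pct over subjects per (condition, frequency, component)."""
        grouped = self.eigenvalues.groupby(["condition", "frequency_hz", "component"])["eigenvalue_pct"]
        out = grouped.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"mean": "mean_pct", "sem": "sem_pct", "count": "n_subjects"})

    def validate(self) -> None:
        """Enforce the ordering invariant: eigenvalue_pct non-increasing in rank."""
        frame = self.eigenvalues
        if frame.empty:
            raise DataError("empty landscape")
        for _, grp in frame.groupby(["subject", "condition", "frequency_hz"]):
            vals = grp.sort_values("component")["eigenvalue_pct"].to_numpy()
            if np.any(np.diff(vals) > 1e-9):
                raise DataError("eigenvalue_pct must be non-increasing in component rank")
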