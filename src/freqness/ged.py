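"""Generalized eigendecomposition of narrowband against broadband covariance.

For each scan frequency, the voxel data filtered at that frequency yields a
narrowband covariance ``S`` which is contrasted against the broadband
reference covariance ``R`` by solving ``S w = lambda R w``.  Eigenvectors are
spatial filters maximizing the narrow-to-broad variance ratio; eigenvalues,
normalized to percent of total variance, trace the eigenspectrum across
frequencies.  Spatial activation patterns are the forward projections
``a = |S w|`` (normalized to max 1) and network time series ``y = w^T X_broad``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import (
    FrequencyGrid,
    Landscape,
    NarrowbandDataset,
    NetworkDecomposition,
    NetworkTimeSeries,
    VoxelDataset,
)
from .errors import DataError
from .filtering import design_gaussian_kernel, narrowband_filter

logger = logging.getLogger(__name__)

__all__ = [
    "CovariancePair",
    "compute_covariances",
    "solve_ged",
    "solve_ged_whitening_oracle",
    "normalize_eigenvalues",
    "component_timeseries",
    "activation_pattern",
    "threshold_pattern_for_display",
    "pca_decomposition",
    "ged_decomposition",
    "scan_frequencies",
]


@dataclass
class CovariancePair:
    """Regularized covariance pair (S narrowband, R broadband reference).

    ``S`` and ``R`` are raw cross-products of the row-mean-centered data (no
    1/(T-1) factor; normalized eigenvalues are invariant to the scaling).  The
    stored matrices already include the diagonal regularization: ``gamma_S``
    added to S's diagonal and ``gamma_R_fraction * trace(R)/n`` to R's.
    """

    S: np.ndarray
    R: np.ndarray
    gamma_S: float = 1e-6
    gamma_R_fraction: float = 0.01

    def __post_init__(self) -> None:
        for name, mat in (("S", self.S), ("R", self.R)):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise DataError(f"{name} must be square")
            scale = max(np.abs(mat).max(), 1e-300)
            if np.abs(mat - mat.T).max() > 1e-10 * scale:
                raise DataError(f"{name} is not symmetric")
        if self.S.shape != self.R.shape:
            raise DataError("S and R must have the same shape")

    @property
    def n_voxels(self) -> int:
        return self.S.shape[0]


def center_rows(data: np.ndarray) -> np.ndarray:
    """Subtract each voxel row's temporal mean."""
    return data - data.mean(axis=1, keepdims=True)


def raw_covariance(data: np.ndarray) -> np.ndarray:
    """Row-centered cross-product ``X X^T``."""
    centered = center_rows(np.asarray(data, dtype=float))
    return centered @ centered.T


def regularize_r(R: np.ndarray, gamma_R_fraction: float) -> np.ndarray:
    """Add ``gamma_R_fraction`` of R's average eigenvalue (trace/n) to its diagonal."""
    n = R.shape[0]
    return R + (gamma_R_fraction * np.trace(R) / n) * np.eye(n)


def compute_covariances(
    broad: VoxelDataset,
    narrow: NarrowbandDataset,
    gamma_S: float = 1e-6,
    gamma_R_fraction: float = 0.01,
) -> CovariancePair:
    """Covariance pair from one broadband dataset and its narrowband copy."""
    if broad.data.shape != narrow.data.shape:
        raise DataError(
            f"broad {broad.data.shape} and narrow {narrow.data.shape} shapes differ"
        )
    variances = broad.data.var(axis=1)
    if np.any(variances == 0):
        warnings.warn(
            f"{int((variances == 0).sum())} zero-variance voxel(s); "
            "diagonal regularization will absorb them",
            stacklevel=2,
        )
    S = raw_covariance(narrow.data) + gamma_S * np.eye(broad.n_voxels)
    R = regularize_r(raw_covariance(broad.data), gamma_R_fraction)
    return CovariancePair(S=S, R=R, gamma_S=gamma_S, gamma_R_fraction=gamma_R_fraction)


def _fix_signs(filters: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Flip each filter so the largest-magnitude entry of its pattern is positive."""
    proj = S @ filters
    idx = np.abs(proj).argmax(axis=0)
    signs = np.sign(proj[idx, np.arange(filters.shape[1])])
    signs[signs == 0] = 1.0
    return filters * signs


def solve_ged(pair: CovariancePair) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``S w = lambda R w``; eigenvalues descending, unit-norm filters.

    Returns ``(eigenvalues, filters)`` with filter columns normalized to unit
    Euclidean length and signs fixed so the largest-magnitude entry of each
    activation pattern is positive.
    """
    if not (np.all(np.isfinite(pair.S)) and np.all(np.isfinite(pair.R))):
        raise DataError("non-finite covariance input")
    eigenvalues, vectors = scipy.linalg.eigh(pair.S, pair.R)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    vectors = vectors / np.linalg.norm(vectors, axis=0, keepdims=True)
    vectors = _fix_signs(vectors, pair.S)
    return eigenvalues, vectors


def solve_ged_whitening_oracle(pair: CovariancePair) -> tuple[np.ndarray, np.ndarray]:
    """Independent route: whiten by ``R^{-1/2}`` and solve the symmetric problem.

    Computes the eigen-decomposition of ``R^{-1/2} S R^{-1/2}`` and maps the
    eigenvectors back through ``R^{-1/2}``.  Used as a cross-check of
    :func:`solve_ged`.
    """
    r_vals, r_vecs = np.linalg.eigh(pair.R)
    if np.any(r_vals <= 0):
        raise DataError("R is not positive definite")
    r_inv_sqrt = (r_vecs / np.sqrt(r_vals)) @ r_vecs.T
    m = r_inv_sqrt @ pair.S @ r_inv_sqrt
    m = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    filters = r_inv_sqrt @ vecs[:, order]
    filters = filters / np.linalg.norm(filters, axis=0, keepdims=True)
    filters = _fix_signs(filters, pair.S)
    return vals, filters


def normalize_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Eigenvalues as percent of total variance (sums to 100)."""
    lam = np.asarray(eigenvalues, dtype=float)
    tol = 1e-8 * max(np.abs(lam).max(), 1e-300)
    if np.any(lam < -tol):
        raise DataError("negative eigenvalues beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0:
        raise DataError("all eigenvalues are zero")
    return lam * (100.0 / total)


def component_timeseries(
    w: np.ndarray,
    broad: VoxelDataset,
    frequency: float = 0.0,
    component_index: int = 1,
) -> NetworkTimeSeries:
    """Network activation time series ``y = w^T X_broad`` (row-centered data)."""
    w = np.asarray(w, dtype=float).ravel()
    if len(w) != broad.n_voxels:
        raise DataError(f"filter length {len(w)} != n_voxels {broad.n_voxels}")
    values = w @ center_rows(broad.data)
    return NetworkTimeSeries(
        values=values,
        frequency=float(frequency),
        component_index=int(component_index),
        sampling_rate=broad.sampling_rate,
        subject_id=broad.subject_id,
        condition=broad.condition,
    )


def activation_pattern(w: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Spatial activation pattern ``|S w|`` scaled to [0, 1] with max 1."""
    w = np.asarray(w, dtype=float).ravel()
    if S.shape[0] != len(w):
        raise DataError("filter/covariance dimension mismatch")
    a = np.abs(S @ w)
    peak = a.max()
    if peak == 0:
        raise DataError("S^T w is identically zero; no pattern")
    return a / peak


def threshold_pattern_for_display(a: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels whose pattern exceeds mean + 1 sample SD."""
    a = np.asarray(a, dtype=float).ravel()
    return a > a.mean() + a.std(ddof=1)


def _build_decomposition(
    eigenvalues: np.ndarray,
    filters: np.ndarray,
    S: np.ndarray,
    frequency: float,
    n_keep: int,
    method: str,
    regularization: tuple[float, float],
) -> NetworkDecomposition:
    n_keep = min(n_keep, filters.shape[1])
    kept = filters[:, :n_keep]
    patterns = np.column_stack([activation_pattern(kept[:, k], S) for k in range(n_keep)])
    return NetworkDecomposition(
        frequency=float(frequency),
        eigenvalues=eigenvalues,
        normalized_eigenvalues=normalize_eigenvalues(eigenvalues),
        filters=kept,
        patterns=patterns,
        method=method,
        regularization=regularization,
    )


def ged_decomposition(
    broad: VoxelDataset,
    narrow: NarrowbandDataset,
    gamma_S: float = 1e-6,
    gamma_R_fraction: float = 0.01,
    n_keep: int = 10,
) -> NetworkDecomposition:
    """Full GED products for one frequency bin."""
    pair = compute_covariances(broad, narrow, gamma_S, gamma_R_fraction)
    eigenvalues, filters = solve_ged(pair)
    return _build_decomposition(
        eigenvalues, filters, pair.S, narrow.center_frequency, n_keep,
        "ged", (gamma_S, gamma_R_fraction),
    )


def pca_decomposition(
    narrow: NarrowbandDataset,
    gamma_S: float = 1e-6,
    n_keep: int = 10,
) -> NetworkDecomposition:
    """PCA variant: eigendecomposition of the narrowband covariance alone.

    Algebraically identical to GED with the reference covariance fixed to the
    identity, so the downstream products (normalized eigenvalues, patterns,
    time series) are directly comparable with the GED backend.
    """
    S = raw_covariance(narrow.data) + gamma_S * np.eye(narrow.n_voxels)
    eigenvalues, vectors = np.linalg.eigh(S)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    filters = vectors[:, order]
    filters = _fix_signs(filters, S)
    return _build_decomposition(
        eigenvalues, filters, S, narrow.center_frequency, n_keep, "pca", (gamma_S, 0.0)
    )


def scan_frequencies(
    broad: VoxelDataset,
    grid: FrequencyGrid,
    method: str = "ged",
    n_keep: int = 10,
    gamma_S: float = 1e-6,
    gamma_R_fraction: float = 0.01,
    store_patterns: bool = True,
    store_filters: bool = True,
) -> Landscape:
    """Scan every grid frequency for one subject/condition.

    The broadband reference covariance is computed once and reused across
    frequencies; per frequency the data is narrowband filtered, the
    (generalized) eigenproblem solved, and the top ``n_keep`` normalized
    eigenvalues (plus patterns/filters) recorded in a :class:`Landscape`.
    """
    if method not in ("ged", "pca"):
        raise DataError(f"unknown method {method!r}")
    if n_keep > broad.n_voxels:
        raise DataError("n_keep exceeds the number of voxels")
    grid.validate_nyquist(broad.nyquist)

    landscape = Landscape()
    R = regularize_r(raw_covariance(broad.data), gamma_R_fraction)
    for center, fwhm in grid:
        logger.info(
            "scan %s/%s f=%.2f Hz (fwhm %.3f Hz, %s)",
            broad.subject_id, broad.condition, center, fwhm, method,
        )
        kernel = design_gaussian_kernel(center, fwhm, broad.n_samples, broad.sampling_rate)
        narrow = narrowband_filter(broad, kernel)
        S = raw_covariance(narrow.data) + gamma_S * np.eye(broad.n_voxels)
        if method == "ged":
            pair = CovariancePair(S=S, R=R, gamma_S=gamma_S, gamma_R_fraction=gamma_R_fraction)
            eigenvalues, filters = solve_ged(pair)
        else:
            decomp = pca_decomposition(narrow, gamma_S, n_keep=n_keep)
            eigenvalues, filters = decomp.eigenvalues, decomp.filters
        normalized = normalize_eigenvalues(eigenvalues)
        for k in range(min(n_keep, filters.shape[1])):
            w = filters[:, k]
            landscape.add(
                broad.subject_id,
                broad.condition,
                center,
                k + 1,
                normalized[k],
                pattern=activation_pattern(w, S) if store_patterns else None,
                spatial_filter=w if store_filters else None,
            )
    return landscape
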