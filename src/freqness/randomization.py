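"""Shuffle controls dissociating spatial from temporal structure.

Label randomization permutes voxel identities once, consistently over the
whole recording: it destroys the anatomical meaning of the activation
patterns but leaves every covariance eigenvalue (hence the eigenspectrum)
exactly invariant.  Point-wise label randomization draws an independent voxel
permutation at every time sample, destroying cross-voxel covariance and
collapsing the leading eigenvalue toward the chance level 100/n_voxels.

Both shuffles operate on already-filtered data (shuffling commutes with the
per-voxel narrowband filter in the consistent case, and re-filtering after a
point-wise shuffle would smear the randomization).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datamodel import NarrowbandDataset, VoxelDataset
from .errors import DataError

__all__ = ["label_shuffle", "pointwise_label_shuffle", "pointwise_permute_rows"]


def _check_pair(broad: VoxelDataset, narrow: NarrowbandDataset) -> None:
    if broad.data.shape != narrow.data.shape:
        raise DataError("broad and narrow datasets must have matching shapes")


def label_shuffle(
    broad: VoxelDataset,
    narrow: NarrowbandDataset,
    seed: int | np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
) -> tuple[VoxelDataset, NarrowbandDataset]:
    """One random voxel permutation applied identically to both matrices.

    Coordinates, when present, are permuted along with the rows.  Pass an
    explicit ``permutation`` (e.g. the identity) to make the draw
    deterministic for testing.
    """
    _check_pair(broad, narrow)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if permutation is None:
        permutation = rng.permutation(broad.n_voxels)
    else:
        permutation = np.asarray(permutation, dtype=int)
        if sorted(permutation.tolist()) != list(range(broad.n_voxels)):
            raise DataError("not a valid voxel permutation")

    def _apply(ds):
        coords = ds.coordinates[permutation] if ds.coordinates is not None else None
        return replace(ds, data=ds.data[permutation], coordinates=coords)

    return _apply(broad), _apply(narrow)


def pointwise_permute_rows(
    matrices: list[np.ndarray],
    rng: np.random.Generator,
    chunk_size: int = 10000,
) -> None:
    """In place: one independent row permutation per time sample, shared
    across all given matrices (same column gets the same permutation)."""
    if not matrices:
        return
    shape = matrices[0].shape
    if any(m.shape != shape for m in matrices):
        raise DataError("all matrices must share one shape")
    n_voxels, n_samples = shape
    for start in range(0, n_samples, chunk_size):
        sl = slice(start, min(start + chunk_size, n_samples))
        keys = rng.random((n_voxels, sl.stop - sl.start), dtype=np.float32)
        idx = np.argsort(keys, axis=0)
        for m in matrices:
            m[:, sl] = np.take_along_axis(m[:, sl], idx, axis=0)


def pointwise_label_shuffle(
    broad: VoxelDataset,
    narrow: NarrowbandDataset,
    seed: int | np.random.Generator | None = None,
) -> tuple[VoxelDataset, NarrowbandDataset]:
    """Independent voxel permutation at every time sample, shared by the pair.

    Each column of the output is a permutation of the same column of the
    input (column-wise moments are preserved exactly); the same per-timepoint
    permutation is applied to the broadband and narrowband matrices so the
    two stay aligned.
    """
    _check_pair(broad, narrow)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    broad_data = broad.data.copy()
    narrow_data = narrow.data.copy()
    pointwise_permute_rows([broad_data, narrow_data], rng)
    return replace(broad, data=broad_data), replace(narrow, data=narrow_data)
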