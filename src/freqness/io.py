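"""Container formats: HDF5/TSV voxel matrices, landscape files, NIfTI patterns.

HDF5 layout for voxel datasets: ``/data`` (n_voxels x n_samples), optional
``/coords`` (n_voxels x 3, MNI mm), root attributes ``sampling_rate``,
``subject_id``, ``condition`` and optional ``grid_spacing_mm``.  TSV matrices
are tab-delimited with no header; the sampling rate must then be supplied by
the caller.  Landscape tables export as tidy TSV with header
(subject, condition, frequency_hz, component, eigenvalue_pct).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import Landscape, VoxelDataset
from .errors import ConfigurationError, DataError, UnsupportedOperationError

__all__ = [
    "read_voxel_dataset",
    "write_voxel_dataset",
    "write_landscape",
    "read_landscape",
    "landscape_to_tsv",
    "export_pattern_volume",
]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ConfigurationError(f"cannot infer format from suffix {suffix!r}; pass format=")


def write_voxel_dataset(dataset: VoxelDataset, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as handle:
            handle.create_dataset("data", data=dataset.data)
            if dataset.coordinates is not None:
                handle.create_dataset("coords", data=dataset.coordinates)
            handle.attrs["sampling_rate"] = dataset.sampling_rate
            handle.attrs["subject_id"] = dataset.subject_id
            handle.attrs["condition"] = dataset.condition
            if dataset.grid_spacing_mm is not None:
                handle.attrs["grid_spacing_mm"] = dataset.grid_spacing_mm
    elif fmt == "tsv":
        np.savetxt(path, dataset.data, delimiter="\t")
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    return path


def read_voxel_dataset(
    path,
    format: str | None = None,
    sampling_rate: float | None = None,
    subject_id: str | None = None,
    condition: str | None = None,
) -> VoxelDataset:
    """Read a voxel dataset from HDF5 or TSV.

    For TSV (and HDF5 files lacking the attribute) ``sampling_rate`` must be
    supplied.  Non-finite or non-numeric entries raise a data error naming the
    first offending index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    coords = None
    spacing = None
    if fmt == "hdf5":
        with h5py.File(path, "r") as handle:
            data = np.asarray(handle["data"], dtype=float)
            if "coords" in handle:
                coords = np.asarray(handle["coords"], dtype=float)
            sampling_rate = sampling_rate or handle.attrs.get("sampling_rate")
            subject_id = subject_id or handle.attrs.get("subject_id", "s01")
            condition = condition or handle.attrs.get("condition", "RS")
            spacing = handle.attrs.get("grid_spacing_mm")
    elif fmt == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", header=None, dtype=float)
        except ValueError as exc:
            raise DataError(f"non-numeric cell in {path}: {exc}") from exc
        data = frame.to_numpy()
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    if sampling_rate is None:
        raise ConfigurationError(f"{path} carries no sampling_rate; pass sampling_rate=")
    return VoxelDataset(
        data=data,
        sampling_rate=float(sampling_rate),
        subject_id=str(subject_id or "s01"),
        condition=str(condition or "RS"),
        coordinates=coords,
        grid_spacing_mm=float(spacing) if spacing is not None else None,
    )


def write_landscape(landscape: Landscape, path) -> Path:
    """Write a landscape (eigenvalue table + pattern/filter stores) to HDF5."""
    landscape.validate()
    frame = landscape.eigenvalues
    path = Path(path)
    with h5py.File(path, "w") as handle:
        grp = handle.create_group("eigenvalues")
        grp.create_dataset("subject", data=frame["subject"].astype(str).to_numpy(dtype="S"))
        grp.create_dataset("condition", data=frame["condition"].astype(str).to_numpy(dtype="S"))
        grp.create_dataset("frequency_hz", data=frame["frequency_hz"].to_numpy())
        grp.create_dataset("component", data=frame["component"].to_numpy())
        grp.create_dataset("eigenvalue_pct", data=frame["eigenvalue_pct"].to_numpy())
        for name, store in (("patterns", landscape.patterns), ("filters", landscape.filters)):
            grp = handle.create_group(name)
            for i, (key, vec) in enumerate(store.items()):
                ds = grp.create_dataset(str(i), data=vec)
                ds.attrs["subject"] = key[0]
                ds.attrs["condition"] = key[1]
                ds.attrs["frequency_hz"] = key[2]
                ds.attrs["component"] = key[3]
    return path


def read_landscape(path) -> Landscape:
    path = Path(path)
    landscape = Landscape()
    with h5py.File(path, "r") as handle:
        grp = handle["eigenvalues"]
        subjects = [s.decode() for s in grp["subject"][()]]
        conditions = [c.decode() for c in grp["condition"][()]]
        freqs = grp["frequency_hz"][()]
        comps = grp["component"][()]
        vals = grp["eigenvalue_pct"][()]
        for s, c, f, k, v in zip(subjects, conditions, freqs, comps, vals):
            landscape.add(s, c, float(f), int(k), float(v))
        for name, store in (("patterns", landscape.patterns), ("filters", landscape.filters)):
            if name in handle:
                for ds in handle[name].values():
                    key = (
                        str(ds.attrs["subject"]),
                        str(ds.attrs["condition"]),
                        float(ds.attrs["frequency_hz"]),
                        int(ds.attrs["component"]),
                    )
                    store[key] = ds[()]
    landscape.validate()
    return landscape


def landscape_to_tsv(landscape: Landscape, path) -> Path:
    landscape.validate()
    path = Path(path)
    landscape.eigenvalues.to_csv(path, sep="\t", index=False)
    return path


def export_pattern_volume(
    pattern: np.ndarray,
    coordinates: np.ndarray | None,
    grid_spacing_mm: float,
    path,
) -> Path:
    """Write a spatial pattern as a NIfTI-1 volume on its source lattice.

    Each voxel center nearest a coordinate receives that pattern value;
    off-grid voxels are zero.  The affine maps voxel indices back to the MNI
    mm coordinates.
    """
    import nibabel as nib

    if coordinates is None:
        raise UnsupportedOperationError("dataset has no coordinates; cannot export a volume")
    pattern = np.asarray(pattern, dtype=float).ravel()
    coordinates = np.asarray(coordinates, dtype=float)
    if len(pattern) != len(coordinates):
        raise DataError("pattern and coordinates length mismatch")
    origin = coordinates.min(axis=0)
    idx = (coordinates - origin) / grid_spacing_mm
    idx_int = np.round(idx).astype(int)
    if np.abs(idx - idx_int).max() > 1e-6:
        raise DataError("coordinates do not lie on a lattice with the given spacing")
    shape = idx_int.max(axis=0) + 1
    volume = np.zeros(shape, dtype=float)
    volume[tuple(idx_int.T)] = pattern
    affine = np.eye(4)
    affine[:3, :3] *= grid_spacing_mm
    affine[:3, 3] = origin
    img = nib.Nifti1Image(volume, affine)
    path = Path(path)
    nib.save(img, str(path))
    return path
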