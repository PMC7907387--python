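"""Readers and writers: imzML 1.1 (.imzML/.ibd pairs) and an HDF5 store.

The HDF5 layout is our own (there is no community standard for MSI in HDF5):

    /<dataset_id>/
        mz           float64 (d,)
        coords       int64   (n, 2)   1-based (i, j)
        intensities  float32 (n, d)
    attrs: width, height, schema_version

Several datasets can share one store file, keyed by ``dataset_id``.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .datamodel import MSIDataset

SCHEMA_VERSION = 1

__all__ = [
    "read_imzml",
    "write_imzml",
    "save_store",
    "load_store",
    "list_store",
]


def _merge_axis(values: np.ndarray, tol: float) -> np.ndarray:
    """Greedy left-to-right merge of sorted unique m/z values within tol."""
    if tol <= 0:
        return values
    merged = []
    group = [values[0]]
    for v in values[1:]:
        if v - group[0] <= tol:
            group.append(v)
        else:
            merged.append(float(np.mean(group)))
            group = [v]
    merged.append(float(np.mean(group)))
    return np.asarray(merged)


def read_imzml(path: str | os.PathLike, mz_tol: float = 0.0) -> MSIDataset:
    """Read an imzML/.ibd pair into an :class:`MSIDataset`.

    Continuous-mode files map directly onto the common axis. Processed-mode
    files (per-pixel m/z lists) are unified onto the union of all observed
    m/z values; values closer than ``mz_tol`` are merged into one channel
    (default 0 = exact union). Absent channels are zero-filled.
    """
    path = os.fspath(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not os.path.exists(ibd):
        raise FileNotFoundError(
            f"imzML file {path!r} has no companion binary file {ibd!r}"
        )
    parser = ImzMLParser(path)
    n = len(parser.coordinates)
    if n == 0:
        raise ValueError("imzML file contains no spectra")

    spectra = [parser.getspectrum(idx) for idx in range(n)]
    first_mz = np.asarray(spectra[0][0], dtype=np.float64)
    continuous = all(
        len(s[0]) == first_mz.size and np.array_equal(np.asarray(s[0]), first_mz)
        for s in spectra[1:]
    )

    coords = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=np.int64)
    width = int(coords[:, 0].max())
    height = int(coords[:, 1].max())

    if continuous:
        mz = first_mz
        inten = np.vstack([np.asarray(s[1], dtype=np.float32) for s in spectra])
    else:
        pooled = np.unique(np.concatenate([np.asarray(s[0], dtype=np.float64) for s in spectra]))
        mz = _merge_axis(pooled, mz_tol)
        inten = np.zeros((n, mz.size), dtype=np.float32)
        for row, (mzs, ints) in enumerate(spectra):
            idx = np.clip(np.searchsorted(mz, mzs), 0, mz.size - 1)
            # snap to the nearer of the two bracketing common channels
            left = np.clip(idx - 1, 0, mz.size - 1)
            nearer = np.where(
                np.abs(mz[left] - mzs) < np.abs(mz[idx] - mzs), left, idx
            )
            np.add.at(inten[row], nearer, np.asarray(ints, dtype=np.float32))

    return MSIDataset(
        width=width,
        height=height,
        mz=mz,
        coords=coords,
        intensities=inten,
        dataset_id=os.path.splitext(os.path.basename(path))[0],
    )


def write_imzml(ds: MSIDataset, path: str | os.PathLike) -> None:
    """Write a continuous-mode imzML/.ibd pair (m/z float64, intensity float32)."""
    if ds.n_pixels == 0:
        raise ValueError("no spectral pixels")
    path = os.fspath(path)
    with ImzMLWriter(path, mode="continuous", intensity_dtype=np.float32) as writer:
        for row, (i, j) in enumerate(ds.coords):
            writer.addSpectrum(ds.mz, ds.intensities[row], (int(i), int(j), 1))


def save_store(ds: MSIDataset, path: str | os.PathLike) -> None:
    """Append/overwrite one dataset in the HDF5 store, keyed by dataset_id."""
    with h5py.File(path, "a") as f:
        if ds.dataset_id in f:
            del f[ds.dataset_id]
        g = f.create_group(ds.dataset_id)
        g.attrs["width"] = ds.width
        g.attrs["height"] = ds.height
        g.attrs["schema_version"] = SCHEMA_VERSION
        g.create_dataset("mz", data=ds.mz.astype(np.float64))
        g.create_dataset("coords", data=ds.coords.astype(np.int64))
        g.create_dataset(
            "intensities", data=ds.intensities.astype(np.float32), compression="gzip"
        )


def load_store(path: str | os.PathLike, dataset_id: str | None = None) -> MSIDataset:
    """Load one dataset from the store (the only one, if id not given)."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable HDF5 store: {path}") from exc
    with f:
        keys = list(f.keys())
        if dataset_id is None:
            if len(keys) != 1:
                raise ValueError(
                    f"store holds {len(keys)} datasets {keys}; pass dataset_id"
                )
            dataset_id = keys[0]
        if dataset_id not in f:
            raise KeyError(f"dataset {dataset_id!r} not in store {keys}")
        g = f[dataset_id]
        version = g.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"store schema version {version} != supported {SCHEMA_VERSION}"
            )
        missing = {"mz", "coords", "intensities"} - set(g.keys())
        if missing:
            raise ValueError(f"store group {dataset_id!r} lacks {sorted(missing)}")
        return MSIDataset(
            width=int(g.attrs["width"]),
            height=int(g.attrs["height"]),
            mz=g["mz"][()],
            coords=g["coords"][()],
            intensities=g["intensities"][()],
            dataset_id=dataset_id,
        )


def list_store(path: str | os.PathLike) -> list[str]:
    """Dataset ids present in a store file."""
    with h5py.File(path, "r") as f:
        return sorted(f.keys())
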