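"""Core containers for multivariate MSI images.

An MSI data set is a ``w`` x ``h`` pixel grid in which a subset of pixels --
the *spectral pixels* -- carry a mass spectrum of ``d`` intensity values on a
shared m/z axis. Pixels without a measurement are implicitly all-zero.
Coordinates are 1-based throughout the public API: ``i`` is the column index
(1..w) and ``j`` the row index (1..h), matching the imzML convention.
Channel indices ``k`` are likewise 1-based (1..d).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MSIDataset",
    "IntensityImage",
    "MeanSpectrum",
    "mean_spectrum",
    "channel_image",
    "crop_mz",
]


@dataclass
class MSIDataset:
    """Pixel grid plus spectral-pixel intensity table and m/z vector.

    Attributes
    ----------
    width, height
        Grid dimensions (columns, rows).
    mz
        Strictly increasing vector of ``d`` mass-to-charge values in Da.
    coords
        ``(n, 2)`` integer array of 1-based ``(i, j)`` positions of the
        spectral pixels; rows are unique.
    intensities
        ``(n, d)`` non-negative float32 matrix, one spectrum per row, row
        order matching ``coords``.
    dataset_id
        Free-form identifier used as the group key in the HDF5 store.
    """

    width: int
    height: int
    mz: np.ndarray
    coords: np.ndarray
    intensities: np.ndarray
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.mz.size == 0:
            raise ValueError("m/z vector is empty")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z vector must be strictly increasing")
        n, d = self.intensities.shape
        if d != self.mz.size:
            raise ValueError(
                f"intensity table has {d} channels but m/z vector has {self.mz.size}"
            )
        if self.coords.shape[0] != n:
            raise ValueError(
                f"{self.coords.shape[0]} coordinates for {n} spectra"
            )
        if n == 0:
            raise ValueError("dataset has no spectral pixels")
        i, j = self.coords[:, 0], self.coords[:, 1]
        if i.min() < 1 or i.max() > self.width or j.min() < 1 or j.max() > self.height:
            raise ValueError("coordinates outside the pixel grid")
        uniq = {(int(a), int(b)) for a, b in self.coords}
        if len(uniq) != n:
            raise ValueError("duplicate spectral-pixel coordinates")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")

    # -- basic accessors -------------------------------------------------
    @property
    def n_pixels(self) -> int:
        """Number of spectral pixels |p+|."""
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        """Number of mass channels d."""
        return self.intensities.shape[1]

    def pixel_index(self, i: int, j: int) -> int:
        """Row index of spectral pixel ``(i, j)``; raises KeyError if absent."""
        hits = np.flatnonzero((self.coords[:, 0] == i) & (self.coords[:, 1] == j))
        if hits.size == 0:
            raise KeyError(f"({i}, {j}) is not a spectral pixel")
        return int(hits[0])

    def is_spectral(self, i: int, j: int) -> bool:
        try:
            self.pixel_index(i, j)
            return True
        except KeyError:
            return False

    def with_intensities(self, intensities: np.ndarray) -> "MSIDataset":
        """Copy with a new intensity table of the same shape."""
        return replace(self, intensities=np.asarray(intensities, dtype=np.float32))

    def to_grid(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-spectral-pixel vector onto the ``(h, w)`` grid."""
        values = np.asarray(values)
        grid = np.full((self.height, self.width), fill, dtype=np.float64)
        grid[self.coords[:, 1] - 1, self.coords[:, 0] - 1] = values
        return grid


@dataclass
class IntensityImage:
    """Single mass-channel image: the grid of one channel's intensities."""

    width: int
    height: int
    values: np.ndarray  # (h, w)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.height, self.width):
            raise ValueError("image shape does not match grid dimensions")


@dataclass
class MeanSpectrum:
    """Per-channel arithmetic mean over the spectral pixels."""

    mz: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64).ravel()
        self.mu = np.asarray(self.mu, dtype=np.float64).ravel()
        if self.mz.shape != self.mu.shape:
            raise ValueError("mz and mu differ in length")


def mean_spectrum(ds: MSIDataset) -> MeanSpectrum:
    """Mean spectrum over spectral pixels only (non-spectral pixels excluded)."""
    mu = ds.intensities.astype(np.float64).mean(axis=0)
    return MeanSpectrum(mz=ds.mz.copy(), mu=mu)


def channel_image(ds: MSIDataset, k: int) -> IntensityImage:
    """Image of the k-th mass channel (k is 1-based); zero off-sample."""
    if not 1 <= k <= ds.n_channels:
        raise IndexError(f"channel {k} out of range 1..{ds.n_channels}")
    grid = ds.to_grid(ds.intensities[:, k - 1])
    return IntensityImage(width=ds.width, height=ds.height, values=grid)


def crop_mz(ds: MSIDataset, lo: float, hi: float) -> MSIDataset:
    """Restrict the m/z axis to the closed interval [lo, hi].

    Raises ValueError if no channel survives or if ``lo >= hi``.
    """
    if lo >= hi:
        raise ValueError("lower cutoff must be below upper cutoff")
    keep = (ds.mz >= lo) & (ds.mz <= hi)
    if not np.any(keep):
        raise ValueError(f"no mass channels in [{lo}, {hi}]")
    return replace(ds, mz=ds.mz[keep], intensities=ds.intensities[:, keep])
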