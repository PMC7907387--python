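"""Spectrum alignment to a common m/z vector and intensity normalization.

Per-spectrum intensity variation is an inherent property of MALDI imaging
data, so an intra-sample normalization (one scaling factor per spectrum) is
applied before any embedding or similarity analysis; for comparative studies
an inter-sample normalization (one factor per data set) can follow. Both
support three factor estimators: ``mean`` and ``median`` of the nonzero
intensities, and ``mfc`` (median fold change against a median reference
spectrum, the default). Nonzero-only statistics are used because MSI spectra
are sparse and zeros would dominate the plain mean/median.

The common-axis construction is a deliberately simple kernel-density
approach: all observed channel m/z values are pooled, smoothed with a
Gaussian kernel of a user-chosen bandwidth, and the local maxima of the
density define the common vector. This is a simplification of kernel-based
clustering aligners and is documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datamodel import MSIDataset, mean_spectrum

log = logging.getLogger(__name__)

METHODS = ("mean", "median", "mfc")

__all__ = [
    "NormalizationReport",
    "build_common_mz",
    "align",
    "intra_normalize",
    "inter_normalize",
]


@dataclass
class NormalizationReport:
    """Scaling factors applied by a normalization step."""

    method: str
    scale_factors: np.ndarray  # one per spectrum (intra) or per dataset (inter)
    reference: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"scale_factor": self.scale_factors}).to_csv(
            path, index_label="index"
        )


def build_common_mz(
    ds_list: list[MSIDataset], kernel_bandwidth: float, grid_step: float | None = None
) -> np.ndarray:
    """Common m/z vector from pooled channel positions via KDE maxima.

    All channel m/z values of all datasets are pooled, a Gaussian kernel
    density with standard deviation ``kernel_bandwidth`` (Da) is evaluated on
    a fine grid, and the grid positions of the density's local maxima are
    returned sorted ascending.
    """
    if not ds_list:
        raise ValueError("need at least one dataset")
    if kernel_bandwidth <= 0:
        raise ValueError("kernel bandwidth must be positive")
    pooled = np.concatenate([ds.mz for ds in ds_list])
    step = grid_step if grid_step is not None else kernel_bandwidth / 10.0
    lo = pooled.min() - 4 * kernel_bandwidth
    hi = pooled.max() + 4 * kernel_bandwidth
    edges = np.arange(lo, hi + step, step)
    hist, edges = np.histogram(pooled, bins=edges)
    density = gaussian_filter1d(hist.astype(np.float64), kernel_bandwidth / step)
    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    return np.sort(centers[interior])


def align(ds: MSIDataset, common_mz: np.ndarray, tol: float) -> MSIDataset:
    """Snap every channel to its nearest common channel within ``tol`` Da.

    Intensities of channels mapping to the same common channel are summed;
    channels farther than ``tol`` from every common channel are dropped.
    """
    common_mz = np.asarray(common_mz, dtype=np.float64)
    idx = np.clip(np.searchsorted(common_mz, ds.mz), 0, common_mz.size - 1)
    left = np.clip(idx - 1, 0, common_mz.size - 1)
    nearer = np.where(
        np.abs(common_mz[left] - ds.mz) <= np.abs(common_mz[idx] - ds.mz), left, idx
    )
    dist = np.abs(common_mz[nearer] - ds.mz)
    keep = dist <= tol
    out = np.zeros((ds.n_pixels, common_mz.size), dtype=np.float64)
    np.add.at(out.T, nearer[keep], ds.intensities[:, keep].T.astype(np.float64))
    return MSIDataset(
        width=ds.width,
        height=ds.height,
        mz=common_mz,
        coords=ds.coords.copy(),
        intensities=out,
        dataset_id=ds.dataset_id,
    )


def _nonzero_stat(spectrum: np.ndarray, method: str) -> float:
    nz = spectrum[spectrum > 0]
    if nz.size == 0:
        return np.nan
    return float(np.mean(nz) if method == "mean" else np.median(nz))


def _mfc_factor(spectrum: np.ndarray, reference: np.ndarray) -> float:
    both = (spectrum > 0) & (reference > 0)
    if not np.any(both):
        return np.nan
    return float(np.median(spectrum[both] / reference[both]))


def intra_normalize(
    ds: MSIDataset, method: str = "mfc"
) -> tuple[MSIDataset, NormalizationReport]:
    """Divide every spectrum by its own scaling factor.

    ``mean``/``median``: statistic of the spectrum's nonzero intensities.
    ``mfc``: median, over channels nonzero in both, of the fold change
    against the dataset's per-channel median spectrum.

    All-zero spectra (or spectra without usable channels) are left unchanged
    with factor 1 and a logged warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    X = ds.intensities.astype(np.float64)
    reference = np.median(X, axis=0) if method == "mfc" else np.array([])
    factors = np.empty(ds.n_pixels)
    for row in range(ds.n_pixels):
        if method == "mfc":
            factors[row] = _mfc_factor(X[row], reference)
        else:
            factors[row] = _nonzero_stat(X[row], method)
    bad = ~np.isfinite(factors) | (factors <= 0)
    if np.any(bad):
        log.warning(
            "%d spectra have no usable intensities; left unnormalized", bad.sum()
        )
        factors[bad] = 1.0
    out = ds.with_intensities(X / factors[:, None])
    return out, NormalizationReport(method=method, scale_factors=factors, reference=reference)


def inter_normalize(
    ds_list: list[MSIDataset], method: str = "mfc"
) -> tuple[list[MSIDataset], NormalizationReport]:
    """Divide every spectrum of each dataset by one dataset-level factor.

    Factors are computed from each dataset's mean spectrum against the
    cross-dataset reference (per-channel median of the mean spectra for
    ``mfc``; ratio of nonzero mean/median statistics otherwise).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if len(ds_list) < 2:
        raise ValueError("inter-sample normalization needs at least 2 datasets")
    means = np.vstack([mean_spectrum(ds).mu for ds in ds_list])
    reference = np.median(means, axis=0)
    factors = np.empty(len(ds_list))
    for d, mu in enumerate(means):
        if method == "mfc":
            factors[d] = _mfc_factor(mu, reference)
        else:
            stat = _nonzero_stat(mu, method)
            ref_stat = _nonzero_stat(reference, method)
            factors[d] = stat / ref_stat if ref_stat else np.nan
    bad = ~np.isfinite(factors) | (factors <= 0)
    if np.any(bad):
        log.warning("%d datasets have no usable signal; factors set to 1", bad.sum())
        factors[bad] = 1.0
    out = [
        ds.with_intensities(ds.intensities.astype(np.float64) / f)
        for ds, f in zip(ds_list, factors)
    ]
    return out, NormalizationReport(method=method, scale_factors=factors, reference=reference)
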