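"""Peak picking and deisotoping on the mean spectrum.

Peaks are picked on the dataset mean spectrum only, never on individual
pixel spectra. A peak is a local maximum of the mean spectrum whose apex
height exceeds a threshold ``z_t``; its extent ``[l, r]`` is the contiguous
run of channels at or above 50% of the apex height (an FWHM-style reading),
and its representative channel ``v`` is the integer median of ``{l..r}``
(lower middle for even runs). Per-pixel peak intensity is the sum over the
extent. An optional upper-limit winsorization caps the mean spectrum at its
``z_w``-th highest value to make threshold selection easier in the presence
of towering outlier peaks. Deisotoping greedily removes lower peaks at
multiples of the C13-C12 mass difference above a kept peak, assuming singly
charged ions (the MALDI norm).

Channel indices in :class:`Peak` are 1-based, consistent with the rest of
the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MSIDataset, MeanSpectrum

ISOTOPE_SPACING_DA = 1.00335  # C13 - C12 mass difference, charge 1

__all__ = [
    "Peak",
    "PeakSet",
    "winsorize_mean",
    "detect_peaks",
    "peak_extent",
    "peak_intensity",
    "reduce_to_peaks",
    "deisotope",
    "scale_to_unit_max",
    "ISOTOPE_SPACING_DA",
]


@dataclass(frozen=True)
class Peak:
    """One picked peak on the mean spectrum (channel indices 1-based)."""

    l: int
    r: int
    v: int        # integer median of {l..r}
    apex: int     # channel of the local maximum
    mz_v: float   # m/z at v, Da
    height: float # mean-spectrum value at the apex

    def __post_init__(self) -> None:
        if not (self.l <= self.v <= self.r and self.l <= self.apex <= self.r):
            raise ValueError("peak indices must satisfy l <= v, apex <= r")


@dataclass
class PeakSet:
    """Picked peaks sorted by m/z, with the thresholds that produced them."""

    peaks: list[Peak]
    z_t: float
    z_w: int | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz_v)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.l <= a.r:
                raise ValueError(f"overlapping peak extents [{a.l},{a.r}] / [{b.l},{b.r}]")

    def __len__(self) -> int:
        return len(self.peaks)

    def apex_channels(self) -> list[int]:
        return [p.apex for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.mz_v, p.l, p.r, p.v, p.apex, p.height) for p in self.peaks],
            columns=["mz_v", "l", "r", "v", "apex", "height"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scale_to_unit_max(mu: MeanSpectrum) -> MeanSpectrum:
    """Mean spectrum rescaled to maximum 1 (identity if all-zero).

    Thresholds like ``z_t`` are conventionally quoted on this [0, 1] scale.
    """
    peak = mu.mu.max()
    return MeanSpectrum(mz=mu.mz.copy(), mu=mu.mu / peak if peak > 0 else mu.mu.copy())


def winsorize_mean(mu: MeanSpectrum, z_w: int) -> MeanSpectrum:
    """Cap the mean spectrum at its z_w-th highest value (upper winsorizing)."""
    d = mu.mu.size
    if not 1 <= z_w <= d:
        raise ValueError(f"z_w must be in 1..{d}")
    omega = np.sort(mu.mu)[::-1][z_w - 1]
    return MeanSpectrum(mz=mu.mz.copy(), mu=np.minimum(mu.mu, omega))


def _apex_runs(x: np.ndarray) -> list[int]:
    """Leftmost channels (0-based) of local-maximum runs of ``x``.

    A run of equal values is a local maximum when both flanking values are
    strictly lower (one-sided at the array ends); the run's leftmost channel
    is taken as the apex for determinism.
    """
    d = x.size
    apexes = []
    i = 0
    while i < d:
        j = i
        while j + 1 < d and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = j == d - 1 or x[j + 1] < x[i]
        if left_ok and right_ok:
            apexes.append(i)
        i = j + 1
    return apexes


def peak_extent(mu: MeanSpectrum, apex: int) -> tuple[int, int, int]:
    """Extent (l, v, r) of the peak at ``apex`` (1-based channel index).

    l and r bound the contiguous run of channels with intensity at or above
    50% of the apex height; v is the integer median of {l..r} (lower middle
    for even-length runs).
    """
    x = mu.mu
    a = apex - 1
    if not 0 <= a < x.size:
        raise IndexError(f"apex {apex} out of range 1..{x.size}")
    half = 0.5 * x[a]
    l = a
    while l - 1 >= 0 and x[l - 1] >= half:
        l -= 1
    r = a
    while r + 1 < x.size and x[r + 1] >= half:
        r += 1
    v = l + (r - l) // 2
    return l + 1, v + 1, r + 1


def detect_peaks(mu: MeanSpectrum, z_t: float, z_w: int | None = None) -> PeakSet:
    """Local-maximum peak detection with minimum apex height ``z_t``.

    Extents of adjacent peaks that would overlap are truncated at the valley
    minimum between their apexes (leftmost minimum on ties) so that peak
    intervals never overlap.
    """
    if z_t < 0:
        raise ValueError("z_t must be non-negative")
    x = mu.mu
    apexes = [a for a in _apex_runs(x) if x[a] > z_t]
    bounds = [list(peak_extent(mu, a + 1)) for a in apexes]  # [l, v, r] 1-based
    # valley truncation between adjacent apexes
    for idx in range(len(apexes) - 1):
        a1, a2 = apexes[idx], apexes[idx + 1]
        if bounds[idx][2] >= bounds[idx + 1][0]:
            valley = a1 + 1 + int(np.argmin(x[a1 + 1 : a2]))  # 0-based channel
            bounds[idx][2] = min(bounds[idx][2], valley + 1)
            bounds[idx + 1][0] = max(bounds[idx + 1][0], valley + 2)
    peaks = []
    for a, (l, _, r) in zip(apexes, bounds):
        v = l + (r - l) // 2
        peaks.append(
            Peak(l=l, r=r, v=v, apex=a + 1, mz_v=float(mu.mz[v - 1]), height=float(x[a]))
        )
    return PeakSet(peaks=peaks, z_t=z_t, z_w=z_w)


def peak_intensity(spectrum: np.ndarray, peak: Peak) -> float:
    """Sum of a spectrum over the peak's extent l..r inclusive."""
    spectrum = np.asarray(spectrum, dtype=np.float64).ravel()
    return float(spectrum[peak.l - 1 : peak.r].sum())


def reduce_to_peaks(ds: MSIDataset, ps: PeakSet) -> MSIDataset:
    """Collapse the channel axis to one summed intensity per picked peak."""
    if len(ps) == 0:
        raise ValueError("empty peak set")
    X = ds.intensities.astype(np.float64)
    out = np.column_stack([X[:, p.l - 1 : p.r].sum(axis=1) for p in ps.peaks])
    mz = np.array([p.mz_v for p in ps.peaks])
    return MSIDataset(
        width=ds.width,
        height=ds.height,
        mz=mz,
        coords=ds.coords.copy(),
        intensities=out,
        dataset_id=ds.dataset_id,
    )


def deisotope(
    ps: PeakSet,
    tol: float,
    max_iso: int = 3,
    spacing: float = ISOTOPE_SPACING_DA,
) -> PeakSet:
    """Greedy removal of isotope satellites.

    Peaks are visited in order of descending height (ascending m/z on ties,
    so the monoisotopic peak of an equal-height pair wins). Each kept peak
    at mass m suppresses any not-yet-kept peak within ``tol`` of
    ``m + n * spacing`` for n = 1..max_iso.
    """
    peaks = ps.peaks
    order = sorted(range(len(peaks)), key=lambda k: (-peaks[k].height, peaks[k].mz_v))
    removed = [False] * len(peaks)
    kept = [False] * len(peaks)
    for k in order:
        if removed[k]:
            continue
        kept[k] = True
        m = peaks[k].mz_v
        for n in range(1, max_iso + 1):
            target = m + n * spacing
            for other in range(len(peaks)):
                if kept[other] or removed[other]:
                    continue
                if abs(peaks[other].mz_v - target) <= tol:
                    removed[other] = True
    return PeakSet(
        peaks=[p for p, keep in zip(peaks, kept) if keep], z_t=ps.z_t, z_w=ps.z_w
    )
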