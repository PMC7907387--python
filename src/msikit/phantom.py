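"""Synthetic MSI phantoms with ground truth.

A phantom is a fully spectral rectangular grid containing:

* a **matrix background**: every pixel outside the sample regions carries
  the matrix signature (Gaussian peaks at dedicated channels) and that
  signature is also added to every sample pixel, emulating a MALDI matrix
  (e.g. DHB) sprayed over the whole slide; a guaranteed matrix-only border
  frame surrounds the sample;
* **sample regions**: rectangles with region-specific peak sets;
* **artifact hotspots**: spatially isolated pixels whose spectra carry an
  additional shared set of peaks boosted by a large multiplier;
* **isotope satellites**: each planted peak gets satellites at multiples of
  1.00335 Da with geometrically decaying height ratio;
* **per-spectrum intensity variation**: a log-normal multiplicative factor
  per pixel, the inherent MSI variability that intra-sample normalization
  is meant to remove;
* **additive noise**: Gaussian, clipped at zero.

The generator is deterministic for a fixed seed. Randomness is split into
two streams: the *geometry* stream (planted channel sets, artifact
positions), driven by ``geometry_seed``, and the *noise* stream (per-pixel
scaling and additive noise), driven by ``seed``. Varying ``seed`` therefore
resamples the noise while keeping the ground-truth layout identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MSIDataset
from .peakpick import ISOTOPE_SPACING_DA

__all__ = ["RegionSpec", "PhantomSpec", "PhantomTruth", "make_phantom"]


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular sample region, inclusive 1-based bounds."""

    i_min: int
    i_max: int
    j_min: int
    j_max: int
    n_peaks: int = 6
    peak_height: float = 10.0

    def contains(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return (
            (i >= self.i_min) & (i <= self.i_max) & (j >= self.j_min) & (j <= self.j_max)
        )


def _default_regions() -> list[RegionSpec]:
    # two rectangles filling most of the interior of the default 64x64 grid
    return [
        RegionSpec(i_min=7, i_max=30, j_min=7, j_max=58),
        RegionSpec(i_min=35, i_max=58, j_min=7, j_max=58),
    ]


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic phantom.

    Defaults describe a 64 x 64 grid with 500 channels at 0.2 Da spacing
    (m/z 100-199.8), two sample regions of 6 peaks each (height 10), a
    dominant 8-peak matrix signature (height 50) everywhere, a 4-pixel
    matrix-only border, 40 isolated artifact pixels boosted 5-fold over the
    matrix height at 5 shared channels, two isotope satellites per peak at
    ratio 0.5, log-normal per-spectrum scale sigma 0.25 and additive noise
    sigma 0.05.
    """

    width: int = 64
    height: int = 64
    n_channels: int = 500
    mz_start: float = 100.0
    mz_step: float = 0.2
    regions: list[RegionSpec] = field(default_factory=_default_regions)
    matrix_border: int = 4
    n_matrix_peaks: int = 8
    matrix_height: float = 50.0
    n_artifacts: int = 40
    artifact_multiplier: float = 5.0
    n_artifact_peaks: int = 5
    isotope_satellites: int = 2
    isotope_ratio: float = 0.5
    peak_width_channels: float = 1.0
    sigma_scale: float = 0.25
    sigma_noise: float = 0.05
    seed: int = 0
    geometry_seed: int = 1234


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom dataset."""

    labels: np.ndarray            # (n,) in {sample, matrix, artifact}
    region_id: np.ndarray         # (n,) region index, -1 off-sample
    region_peak_channels: list[list[int]]  # planted monoisotopic channels, 1-based
    matrix_peak_channels: list[int]
    artifact_peak_channels: list[int]
    matrix_mean_spectrum: np.ndarray       # noiseless matrix signature
    planted_channels: list[int]            # all monoisotopic + satellite apexes


def _signature(
    channels: list[int], height: float, spec: PhantomSpec
) -> tuple[np.ndarray, list[int]]:
    """Noiseless spectrum with Gaussian peaks + isotope satellites.

    Returns the signature and the list of all apex channels (1-based).
    """
    d = spec.n_channels
    grid = np.arange(d, dtype=np.float64)
    sig = np.zeros(d)
    iso_step = max(1, int(round(ISOTOPE_SPACING_DA / spec.mz_step)))
    apexes = []
    for c in channels:
        for n in range(spec.isotope_satellites + 1):
            center = (c - 1) + n * iso_step
            if center >= d:
                break
            h = height * spec.isotope_ratio**n
            sig += h * np.exp(-0.5 * ((grid - center) / spec.peak_width_channels) ** 2)
            apexes.append(center + 1)
    return sig, apexes


def _draw_channel_groups(
    rng: np.random.Generator, counts: list[int], spec: PhantomSpec
) -> list[list[int]]:
    """Draw monoisotopic channels for several peak groups at once.

    Channels are placed on a jittered lattice so that any two planted peaks
    (including their isotope satellites) are separated by at least the
    satellite footprint; group membership is then assigned at random.
    """
    iso_step = max(1, int(round(ISOTOPE_SPACING_DA / spec.mz_step)))
    span = spec.isotope_satellites * iso_step + 4  # channels kept clear past a peak
    total = sum(counts)
    lo, hi = 5, spec.n_channels - span
    slot = (hi - lo) / max(total, 1)
    if total and slot <= span:
        raise ValueError(
            f"{total} peaks do not fit {spec.n_channels} channels without collisions"
        )
    base = lo + slot * np.arange(total)
    jitter = rng.uniform(0.0, slot - span, size=total)
    channels = np.unique((base + jitter).astype(int) + 1)  # 1-based
    if channels.size < total:
        raise ValueError("peak channel collision; increase n_channels")
    order = rng.permutation(total)
    groups: list[list[int]] = []
    start = 0
    for c in counts:
        groups.append(sorted(int(channels[k]) for k in order[start : start + c]))
        start += c
    return groups


def make_phantom(spec: PhantomSpec) -> tuple[MSIDataset, PhantomTruth]:
    """Generate the phantom dataset and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    rng_geom = np.random.default_rng(spec.geometry_seed)
    w, h, d = spec.width, spec.height, spec.n_channels

    # geometry checks: regions must stay off the matrix border frame
    b = spec.matrix_border
    for reg in spec.regions:
        if (
            reg.i_min <= b
            or reg.i_max > w - b
            or reg.j_min <= b
            or reg.j_max > h - b
        ):
            raise ValueError(f"region {reg} overlaps the matrix border frame")

    ii, jj = np.meshgrid(np.arange(1, w + 1), np.arange(1, h + 1), indexing="xy")
    coords = np.column_stack([ii.ravel(), jj.ravel()])
    n = coords.shape[0]

    region_id = np.full(n, -1, dtype=np.int64)
    for k, reg in enumerate(spec.regions):
        inside = reg.contains(coords[:, 0], coords[:, 1])
        region_id[inside] = k

    # planted channel sets, mutually separated
    counts = (
        [spec.n_matrix_peaks]
        + [reg.n_peaks for reg in spec.regions]
        + [spec.n_artifact_peaks]
    )
    groups = _draw_channel_groups(rng_geom, counts, spec)
    matrix_channels = groups[0]
    region_channels = groups[1 : 1 + len(spec.regions)]
    artifact_channels = groups[-1]

    matrix_sig, matrix_apexes = _signature(matrix_channels, spec.matrix_height, spec)
    region_sigs = []
    planted = list(matrix_apexes)
    for reg, chans in zip(spec.regions, region_channels):
        sig, apexes = _signature(chans, reg.peak_height, spec)
        region_sigs.append(sig)
        planted.extend(apexes)
    artifact_sig, artifact_apexes = _signature(
        artifact_channels, spec.artifact_multiplier * spec.matrix_height, spec
    )

    # base spectra: matrix signature everywhere, region signature on top
    X = np.tile(matrix_sig, (n, 1))
    for k in range(len(spec.regions)):
        X[region_id == k] += region_sigs[k]

    # isolated artifact pixels (min Chebyshev separation 3, off the outermost ring)
    labels = np.full(n, "matrix", dtype="<U8")
    labels[region_id >= 0] = "sample"
    artifact_rows: list[int] = []
    if spec.n_artifacts > 0:
        placed: list[tuple[int, int]] = []
        order = rng_geom.permutation(n)
        for row in order:
            i, j = int(coords[row, 0]), int(coords[row, 1])
            if i < 2 or i > w - 1 or j < 2 or j > h - 1:
                continue
            if all(max(abs(i - pi), abs(j - pj)) >= 3 for pi, pj in placed):
                placed.append((i, j))
                artifact_rows.append(int(row))
            if len(placed) == spec.n_artifacts:
                break
        if len(placed) < spec.n_artifacts:
            raise ValueError("grid too small to place isolated artifacts")
        X[artifact_rows] += artifact_sig
        labels[artifact_rows] = "artifact"
        region_id[artifact_rows] = -1

    # per-spectrum multiplicative variation, then additive noise, clamped
    if spec.sigma_scale > 0:
        X *= np.exp(rng.normal(0.0, spec.sigma_scale, size=n))[:, None]
    if spec.sigma_noise > 0:
        X = np.clip(X + rng.normal(0.0, spec.sigma_noise, size=(n, d)), 0.0, None)

    ds = MSIDataset(
        width=w,
        height=h,
        mz=spec.mz_start + spec.mz_step * np.arange(d),
        coords=coords,
        intensities=X,
        dataset_id=f"phantom-seed{spec.seed}",
    )
    truth = PhantomTruth(
        labels=labels,
        region_id=region_id,
        region_peak_channels=region_channels,
        matrix_peak_channels=matrix_channels,
        artifact_peak_channels=artifact_channels,
        matrix_mean_spectrum=matrix_sig,
        planted_channels=sorted(planted),
    )
    return ds, truth
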