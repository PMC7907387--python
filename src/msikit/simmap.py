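"""Headless spectral-similarity pseudocoloring engine.

Renders a scalar field over the pixel grid from the 8-bit byte
representation of the spectra, in one of three modes:

* **similarity** -- inverse angular distance between every pixel spectrum
  and a chosen reference pixel: ``c' = [255 * (1 - (2/pi) * arccos(cos))]``
  where ``cos`` is the cosine of the two byte spectra. The angular metric is
  invariant to per-spectrum scale, so it compares peak *profiles*, not
  magnitudes.
* **browsing** -- the byte value of one mass channel per pixel.
* **grouping** -- the mean byte value over a set of channels per pixel
  (reduces exactly to browsing for a single channel).

The raw field ``c'`` is min-max normalized over the spectral pixels to
``c''`` on [0, 255], then mapped through a colour lookup table ("fire" by
default, black-red-yellow-white) to an RGB image, accompanied by a 256-bin
histogram of ``c''`` that doubles as the colour-scale legend.

Rounding is half-away-from-zero everywhere for deterministic, language-
independent byte values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .datamodel import MSIDataset

__all__ = [
    "ByteDataset",
    "RenderedMap",
    "to_bytes",
    "similarity_field",
    "angular_similarity",
    "browsing_field",
    "grouping_field",
    "normalize_field",
    "apply_colormap",
    "render",
    "reference_spectrum",
    "COLOR_SCALES",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (inputs here are non-negative)."""
    return np.floor(np.asarray(x) + 0.5)


@dataclass
class ByteDataset:
    """8-bit per-spectrum representation of an MSI dataset.

    Each spectrum is scaled by 255 over its own maximum and rounded, so a
    spectrum carries at most 256 distinct values. All-zero spectra stay zero.
    """

    width: int
    height: int
    mz: np.ndarray
    coords: np.ndarray
    bytes: np.ndarray  # (n, d) uint8
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.bytes = np.asarray(self.bytes)
        if self.bytes.dtype != np.uint8:
            if self.bytes.min() < 0 or self.bytes.max() > 255:
                raise ValueError("byte values outside 0..255")
            self.bytes = self.bytes.astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return self.bytes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.bytes.shape[1]

    def pixel_index(self, i: int, j: int) -> int:
        hits = np.flatnonzero((self.coords[:, 0] == i) & (self.coords[:, 1] == j))
        if hits.size == 0:
            raise KeyError(f"({i}, {j}) is not a spectral pixel")
        return int(hits[0])

    def to_grid(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        grid = np.full((self.height, self.width), fill, dtype=np.float64)
        grid[self.coords[:, 1] - 1, self.coords[:, 0] - 1] = values
        return grid


@dataclass
class RenderedMap:
    """One rendered pseudocolor map with its intermediate fields."""

    raw: np.ndarray         # (h, w) c' field, 0 off-sample
    normalized: np.ndarray  # (h, w) c'' field, 0 off-sample
    image: np.ndarray       # (h, w, 3) uint8
    histogram: np.ndarray   # (256,) counts of c'' over spectral pixels
    mode: str
    reference: object       # (q, r), channel k, or channel set M


def to_bytes(ds: MSIDataset) -> ByteDataset:
    """Per-spectrum 8-bit transform: ``round(255 * s / max(s))``."""
    X = ds.intensities.astype(np.float64)
    maxima = X.max(axis=1)
    scale = np.where(maxima > 0, maxima, 1.0)
    b = _round_half_away(255.0 * X / scale[:, None]).astype(np.uint8)
    return ByteDataset(
        width=ds.width,
        height=ds.height,
        mz=ds.mz.copy(),
        coords=ds.coords.copy(),
        bytes=b,
        dataset_id=ds.dataset_id,
    )


def angular_similarity(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Unrounded inverse angular distance ``255 * (1 - (2/pi) * angle)``.

    Works on any non-negative spectra (float or byte); rows with zero norm
    map to 0 (maximally dissimilar), matching the black background.
    """
    X = np.asarray(X, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64).ravel()
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference spectrum has zero norm")
    norms = np.linalg.norm(X, axis=1)
    out = np.zeros(X.shape[0])
    ok = norms > 0
    cos = np.clip(X[ok] @ ref / (norms[ok] * ref_norm), -1.0, 1.0)
    out[ok] = 255.0 * (1.0 - (2.0 / np.pi) * np.arccos(cos))
    return out


def similarity_field(bds: ByteDataset, q: int, r: int) -> np.ndarray:
    """Similarity-mode raw field c' against reference pixel (q, r).

    Returns one rounded value in [0, 255] per spectral pixel, aligned with
    ``bds.coords``. The reference must be a spectral pixel with nonzero
    byte spectrum.
    """
    ref = bds.bytes[bds.pixel_index(q, r)]
    if not np.any(ref):
        raise ValueError(f"reference pixel ({q}, {r}) has an all-zero byte spectrum")
    return _round_half_away(angular_similarity(bds.bytes, ref))


def browsing_field(bds: ByteDataset, k: int) -> np.ndarray:
    """Browsing-mode raw field: byte value of channel k (1-based) per pixel."""
    if not 1 <= k <= bds.n_channels:
        raise IndexError(f"channel {k} out of range 1..{bds.n_channels}")
    return bds.bytes[:, k - 1].astype(np.float64)


def grouping_field(bds: ByteDataset, M) -> np.ndarray:
    """Grouping-mode raw field: rounded mean byte value over channels M.

    The 0-255 byte values are treated as 255 times a unit-normalized
    intensity, so the mean stays on the byte scale and a single-channel set
    reduces exactly to browsing mode.
    """
    M = sorted(set(int(k) for k in np.atleast_1d(np.asarray(M, dtype=int)).ravel()))
    if not M:
        raise ValueError("empty channel set")
    for k in M:
        if not 1 <= k <= bds.n_channels:
            raise IndexError(f"channel {k} out of range 1..{bds.n_channels}")
    cols = [k - 1 for k in M]
    return _round_half_away(bds.bytes[:, cols].astype(np.float64).mean(axis=1))


def normalize_field(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize a raw field over the spectral pixels to [0, 255].

    Constant fields map to all zeros.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return 255.0 * (raw - lo) / (hi - lo)


def _fire_lut() -> np.ndarray:
    """Black-red-yellow-white LUT, linear in RGB between the control points."""
    stops = np.array([0, 96, 192, 255], dtype=np.float64)
    colors = np.array(
        [[0, 0, 0], [255, 0, 0], [255, 255, 0], [255, 255, 255]], dtype=np.float64
    )
    x = np.arange(256, dtype=np.float64)
    lut = np.column_stack(
        [np.interp(x, stops, colors[:, c]) for c in range(3)]
    )
    return _round_half_away(lut).astype(np.uint8)


def _gray_lut() -> np.ndarray:
    x = np.arange(256, dtype=np.uint8)
    return np.column_stack([x, x, x])


COLOR_SCALES = {"fire": _fire_lut(), "gray": _gray_lut()}


def apply_colormap(normalized: np.ndarray, scale_name: str = "fire") -> np.ndarray:
    """Map values in [0, 255] through a colour LUT to RGB (uint8)."""
    if scale_name not in COLOR_SCALES:
        raise ValueError(
            f"unknown color scale {scale_name!r}; choose from {sorted(COLOR_SCALES)}"
        )
    values = np.asarray(normalized, dtype=np.float64)
    if values.min() < 0 or values.max() > 255:
        raise ValueError("values outside [0, 255]")
    idx = _round_half_away(values).astype(np.intp)
    return COLOR_SCALES[scale_name][idx]


def reference_spectrum(bds: ByteDataset, q: int, r: int) -> np.ndarray:
    """Byte spectrum at (q, r); the byte mean spectrum if not spectral."""
    try:
        return bds.bytes[bds.pixel_index(q, r)].copy()
    except KeyError:
        return _round_half_away(bds.bytes.astype(np.float64).mean(axis=0)).astype(
            np.uint8
        )


def render(
    bds: ByteDataset,
    mode: str,
    out_path: str | os.PathLike | None = None,
    scale_name: str = "fire",
    ref: tuple[int, int] | None = None,
    channel: int | None = None,
    channels=None,
) -> RenderedMap:
    """Compute a full rendered map and optionally write PNG + CSV artifacts.

    ``mode`` selects the field: "similarity" (needs ``ref=(q, r)``),
    "browsing" (needs ``channel``), or "grouping" (needs ``channels``).
    With ``out_path`` given (a path without suffix), writes
    ``<out>.png`` (RGB image), ``<out>_field.csv`` (the c'' grid) and
    ``<out>_hist.csv`` (the 256-bin histogram). Deterministic.
    """
    if mode == "similarity":
        if ref is None:
            raise ValueError("similarity mode needs a reference pixel (q, r)")
        raw = similarity_field(bds, *ref)
        reference = tuple(ref)
    elif mode == "browsing":
        if channel is None:
            raise ValueError("browsing mode needs a channel")
        raw = browsing_field(bds, channel)
        reference = int(channel)
    elif mode == "grouping":
        if channels is None:
            raise ValueError("grouping mode needs a channel set")
        raw = grouping_field(bds, channels)
        reference = sorted(set(int(k) for k in np.ravel(channels)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    normalized = normalize_field(raw)
    hist = np.bincount(
        _round_half_away(normalized).astype(np.intp), minlength=256
    )[:256]
    raw_grid = bds.to_grid(raw)
    norm_grid = bds.to_grid(normalized)
    image = apply_colormap(norm_grid, scale_name)
    result = RenderedMap(
        raw=raw_grid,
        normalized=norm_grid,
        image=image,
        histogram=hist,
        mode=mode,
        reference=reference,
    )
    if out_path is not None:
        base = os.fspath(out_path)
        Image.fromarray(image, mode="RGB").save(base + ".png")
        pd.DataFrame(norm_grid).to_csv(base + "_field.csv", index=False)
        pd.DataFrame({"bin": np.arange(256), "count": hist}).to_csv(
            base + "_hist.csv", index=False
        )
    return result
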