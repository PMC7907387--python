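"""Embedding-based detection and subtraction of matrix and artifact signals.

Spectral pixels fall into three categories: *sample* (tissue), *matrix*
(ions from the applied MALDI matrix, e.g. DHB, covering the off-tissue
area), and *artifact* (isolated hotspot pixels whose spectra resemble
neither). The pixel spectra are embedded into 2-D (truncated SVD first when
the channel count exceeds 1000, then UMAP), the embedding is clustered, and
clusters are labelled by two spatial heuristics:

* artifact clusters are spatially scattered (large mean nearest-neighbour
  distance in the pixel grid) or tiny;
* the matrix cluster is the one with the largest fraction of pixels on the
  image border frame, where no tissue lies.

The mean spectrum of the matrix (or artifact) pixels can then be subtracted
channel-wise from every spectrum, clamped at zero, and/or the labelled
pixels removed outright. When strong artifacts distort the embedding, an
iterative pass removes them first and re-embeds before matrix detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.decomposition import TruncatedSVD

from .datamodel import MSIDataset

log = logging.getLogger(__name__)

SAMPLE = "sample"
MATRIX = "matrix"
ARTIFACT = "artifact"
LABELS = (SAMPLE, MATRIX, ARTIFACT)

TSVD_CHANNEL_THRESHOLD = 1000  # above this many channels, tSVD precedes UMAP

__all__ = [
    "Embedding2D",
    "PixelClassification",
    "ClassifyParams",
    "embed",
    "auto_classify",
    "classify_by_selection",
    "subtract_class_mean",
    "remove_pixels",
    "iterative_clean",
]


@dataclass
class Embedding2D:
    """2-D embedding of the spectral pixels, row order matching coords."""

    coords2d: np.ndarray
    method_chain: list[str]
    seed: int

    def __post_init__(self) -> None:
        self.coords2d = np.asarray(self.coords2d, dtype=np.float64)
        if self.coords2d.ndim != 2 or self.coords2d.shape[1] != 2:
            raise ValueError("embedding must be (n, 2)")
        if not np.all(np.isfinite(self.coords2d)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class PixelClassification:
    """Per-spectral-pixel label in {sample, matrix, artifact}."""

    labels: np.ndarray
    provenance: str = "auto"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U8")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside {LABELS}: {sorted(bad)}")

    def mask(self, which: str) -> np.ndarray:
        if which not in LABELS:
            raise ValueError(f"unknown label {which!r}")
        return self.labels == which

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}


@dataclass
class ClassifyParams:
    """Tunables of the automatic classification heuristics.

    min_cluster_size: DBSCAN ``min_samples`` on the 2-D embedding; clusters
        cannot be smaller than this.
    eps_frac: DBSCAN neighbourhood radius as a fraction of the embedding
        span (its largest axis range). Relative scaling makes the radius
        independent of the embedding's arbitrary units and large enough to
        bridge the local tears a nonlinear embedding introduces inside one
        homogeneous cloud.
    hotspot_dist: mean within-cluster spatial nearest-neighbour distance
        (pixels) above which a cluster counts as scattered, hence artifact.
        Contiguous tissue or matrix areas sit near 1; isolated hotspots are
        several pixels apart by definition.
    min_matrix_frac: clusters smaller than this fraction of |p+| count as
        artifact regardless of scatter.
    border_px: width of the border frame used to identify the matrix cluster.
    """

    min_cluster_size: int = 5
    eps_frac: float = 0.05
    hotspot_dist: float = 3.5
    min_matrix_frac: float = 0.001
    border_px: int = 4


def embed(ds: MSIDataset, seed: int, tsvd_components: int = 100) -> Embedding2D:
    """Embed pixel spectra into 2-D; deterministic for a fixed seed.

    With more than 1000 channels, truncated SVD reduces to
    ``tsvd_components`` dimensions before the nonlinear UMAP step, trading
    negligible embedding quality for a large runtime saving.
    """
    import umap  # deferred: numba compilation makes this import expensive

    if ds.n_pixels < 10:
        raise ValueError("need at least 10 spectral pixels to embed")
    X = ds.intensities.astype(np.float64)
    chain: list[str] = []
    if ds.n_channels > TSVD_CHANNEL_THRESHOLD:
        n_comp = min(tsvd_components, ds.n_channels - 1, ds.n_pixels - 1)
        X = TruncatedSVD(n_components=n_comp, random_state=seed).fit_transform(X)
        chain.append("tsvd")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(15, ds.n_pixels - 1),
        random_state=seed,
    )
    coords2d = reducer.fit_transform(X)
    chain.append("umap")
    return Embedding2D(coords2d=coords2d, method_chain=chain, seed=seed)


def _mean_nn_distance(points: np.ndarray) -> float:
    """Mean nearest-neighbour distance among grid points; inf for singletons."""
    if points.shape[0] < 2:
        return np.inf
    dist, _ = cKDTree(points).query(points, k=2)
    return float(dist[:, 1].mean())


def _border_fraction(coords: np.ndarray, w: int, h: int, border_px: int) -> float:
    i, j = coords[:, 0], coords[:, 1]
    on_border = (
        (i <= border_px) | (i > w - border_px) | (j <= border_px) | (j > h - border_px)
    )
    return float(on_border.mean())


def auto_classify(
    ds: MSIDataset, emb: Embedding2D, params: ClassifyParams | None = None
) -> PixelClassification:
    """Density-cluster the embedding and label clusters by spatial heuristics.

    Noise points of the clusterer are attached to the nearest cluster
    centroid before the rules apply. If clustering finds no structure (zero
    or one cluster), everything is labelled sample and a warning is logged.
    """
    params = params or ClassifyParams()
    if emb.coords2d.shape[0] != ds.n_pixels:
        raise ValueError("embedding does not match dataset")
    n = ds.n_pixels
    span = float(np.max(emb.coords2d.max(axis=0) - emb.coords2d.min(axis=0)))
    if span == 0.0:
        log.warning("degenerate embedding (all points equal); labelling all sample")
        return PixelClassification(labels=np.full(n, SAMPLE), provenance="auto")
    cluster_ids = DBSCAN(
        eps=params.eps_frac * span, min_samples=params.min_cluster_size
    ).fit_predict(emb.coords2d)
    uniq = np.unique(cluster_ids[cluster_ids >= 0])
    if uniq.size == 0:
        log.warning("no clusters found in embedding; labelling all pixels sample")
        return PixelClassification(labels=np.full(n, SAMPLE), provenance="auto")

    # attach noise points to the nearest cluster centroid
    centroids = np.vstack([emb.coords2d[cluster_ids == c].mean(axis=0) for c in uniq])
    noise = cluster_ids < 0
    if np.any(noise):
        d2 = ((emb.coords2d[noise, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        cluster_ids = cluster_ids.copy()
        cluster_ids[noise] = uniq[np.argmin(d2, axis=1)]

    labels = np.full(n, SAMPLE, dtype="<U8")
    candidates = []
    for c in uniq:
        members = cluster_ids == c
        pts = ds.coords[members].astype(np.float64)
        scattered = _mean_nn_distance(pts) > params.hotspot_dist
        tiny = members.sum() < params.min_matrix_frac * n
        if scattered or tiny:
            labels[members] = ARTIFACT
        else:
            candidates.append(c)

    if len(candidates) < 2:
        log.warning(
            "fewer than two compact clusters; cannot separate matrix from sample"
        )
        return PixelClassification(labels=labels, provenance="auto")

    fracs = [
        _border_fraction(ds.coords[cluster_ids == c], ds.width, ds.height, params.border_px)
        for c in candidates
    ]
    best = int(np.argmax(fracs))
    if fracs[best] > 0:
        labels[cluster_ids == candidates[best]] = MATRIX
    else:
        log.warning("no candidate cluster touches the border; no matrix assigned")
    return PixelClassification(labels=labels, provenance="auto")


def classify_by_selection(
    ds: MSIDataset,
    emb: Embedding2D | None,
    selection,
    label: str,
    prior: PixelClassification | None = None,
) -> PixelClassification:
    """Label pixels selected by an embedding-space polygon or coordinate list.

    ``selection`` is either an ``(m, 2)`` float polygon in embedding space
    (even-odd containment; requires ``emb``) or an iterable of 1-based
    ``(i, j)`` pixel coordinates. Unselected pixels keep their prior label
    (default sample). This is the scriptable replacement for interactive
    lasso selection.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    labels = (
        prior.labels.copy() if prior is not None else np.full(ds.n_pixels, SAMPLE, dtype="<U8")
    )
    if np.issubdtype(selection.dtype, np.floating):
        if emb is None:
            raise ValueError("polygon selection requires an embedding")
        if selection.ndim != 2 or selection.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        inside = MplPath(selection).contains_points(emb.coords2d)
        labels[inside] = label
    else:
        for i, j in selection.reshape(-1, 2):
            labels[ds.pixel_index(int(i), int(j))] = label
    return PixelClassification(labels=labels, provenance="manual")


def subtract_class_mean(
    ds: MSIDataset, cls: PixelClassification, which: str = MATRIX
) -> MSIDataset:
    """Subtract the labelled pixels' mean spectrum from every spectrum.

    Negative results are clamped to zero so intensities stay physical.
    """
    mask = cls.mask(which)
    if not np.any(mask):
        raise ValueError(f"no pixels labelled {which!r}")
    class_mean = ds.intensities[mask].astype(np.float64).mean(axis=0)
    cleaned = np.clip(ds.intensities.astype(np.float64) - class_mean, 0.0, None)
    return ds.with_intensities(cleaned)


def remove_pixels(
    ds: MSIDataset, cls: PixelClassification, which: str
) -> MSIDataset:
    """Drop labelled pixels from the spectral set; grid dimensions stay."""
    drop = cls.mask(which)
    if np.all(drop):
        raise ValueError(f"removing all {which!r} pixels would empty the dataset")
    keep = ~drop
    return replace(
        ds, coords=ds.coords[keep].copy(), intensities=ds.intensities[keep].copy()
    )


def iterative_clean(
    ds: MSIDataset, seed: int, params: ClassifyParams | None = None,
    tsvd_components: int = 100,
) -> tuple[MSIDataset, PixelClassification, Embedding2D]:
    """Artifact-first two-pass cleaning.

    Pass 1 embeds, classifies, and removes artifact pixels, whose large
    high-dimensional distances can compress the rest of the embedding.
    Pass 2 re-embeds the remaining pixels, detects the matrix cluster on the
    cleaner embedding, and subtracts its mean spectrum. Returns the cleaned
    dataset with the final classification and embedding (both over the
    remaining pixels).
    """
    params = params or ClassifyParams()
    emb1 = embed(ds, seed, tsvd_components=tsvd_components)
    cls1 = auto_classify(ds, emb1, params)
    if np.any(cls1.mask(ARTIFACT)):
        ds1 = remove_pixels(ds, cls1, ARTIFACT)
        emb2 = embed(ds1, seed, tsvd_components=tsvd_components)
    else:
        ds1, emb2 = ds, emb1
    cls2 = auto_classify(ds1, emb2, params)
    if np.any(cls2.mask(MATRIX)):
        ds2 = subtract_class_mean(ds1, cls2, MATRIX)
    else:
        log.warning("no matrix cluster found in second pass; nothing subtracted")
        ds2 = ds1
    return ds2, cls2, emb2
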