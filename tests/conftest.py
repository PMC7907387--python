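"""Shared fixtures.

The UMAP-based embeddings are the expensive part of the suite, so phantom
datasets and their embeddings are built once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from msikit.datamodel import MSIDataset
from msikit.matrix_clean import embed
from msikit.phantom import PhantomSpec, RegionSpec, make_phantom
from msikit.preprocess import intra_normalize


def make_dataset(intensities, mz=None, width=None, height=None, coords=None, **kw):
    """Small hand-rolled dataset helper for unit tests."""
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n, d = intensities.shape
    if mz is None:
        mz = 100.0 + np.arange(d)
    if coords is None:
        width = width or n
        height = height or 1
        coords = [(k % width + 1, k // width + 1) for k in range(n)]
    else:
        width = width or max(c[0] for c in coords)
        height = height or max(c[1] for c in coords)
    return MSIDataset(
        width=width, height=height, mz=mz, coords=np.asarray(coords),
        intensities=intensities, **kw,
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 32x32, 160-channel phantom small enough for per-test embeddings."""
    kw = dict(
        width=32,
        height=32,
        n_channels=160,
        regions=[
            RegionSpec(i_min=5, i_max=14, j_min=5, j_max=28, n_peaks=3),
            RegionSpec(i_min=18, i_max=27, j_min=5, j_max=28, n_peaks=3),
        ],
        matrix_border=3,
        n_matrix_peaks=4,
        # enough hotspots that they outnumber the embedding's neighbourhood
        # size and can form their own cluster
        n_artifacts=16,
        n_artifact_peaks=3,
        isotope_satellites=1,
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def normalized_phantom(default_phantom):
    ds, truth = default_phantom
    out, _ = intra_normalize(ds, "mfc")
    return out, truth


@pytest.fixture(scope="session")
def phantom_embedding(normalized_phantom):
    ds, _ = normalized_phantom
    return embed(ds, seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def small_normalized(small_phantom):
    ds, truth = small_phantom
    out, _ = intra_normalize(ds, "mfc")
    return out, truth


@pytest.fixture(scope="session")
def small_embedding(small_normalized):
    ds, _ = small_normalized
    return embed(ds, seed=0)
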