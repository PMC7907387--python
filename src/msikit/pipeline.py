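"""End-to-end pipeline: convert -> normalize -> clean -> pick -> render.

A :class:`RunConfig` (JSON-serializable, strictly validated: unknown keys
are rejected by name) describes every stage; :func:`run_pipeline` executes
the enabled stages in order on either an imzML input or a generated
phantom, writes all artifacts under the output directory, and records a
manifest with the resolved configuration, the seed, and SHA-256 hashes of
every output file, so that identical configurations yield byte-identical,
verifiable runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from . import io as msio
from .datamodel import MSIDataset, crop_mz, mean_spectrum
from .matrix_clean import (
    ARTIFACT,
    MATRIX,
    ClassifyParams,
    auto_classify,
    embed,
    iterative_clean,
    remove_pixels,
    subtract_class_mean,
)
from .peakpick import deisotope, detect_peaks, reduce_to_peaks, scale_to_unit_max, winsorize_mean
from .phantom import PhantomSpec, make_phantom
from .preprocess import intra_normalize
from .simmap import render, to_bytes

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConvertConfig(_Strict):
    enabled: bool = True
    mz_lo: float | None = None
    mz_hi: float | None = None


class NormalizeConfig(_Strict):
    enabled: bool = True
    method: str = "mfc"


class CleanConfig(_Strict):
    enabled: bool = True
    iterative: bool = True
    subtract: list[str] = [MATRIX]
    remove: list[str] = [ARTIFACT]
    tsvd_components: int = 100
    min_cluster_size: int = 5
    eps_frac: float = 0.05
    hotspot_dist: float = 3.5
    min_matrix_frac: float = 0.001
    border_px: int = 4

    def params(self) -> ClassifyParams:
        return ClassifyParams(
            min_cluster_size=self.min_cluster_size,
            eps_frac=self.eps_frac,
            hotspot_dist=self.hotspot_dist,
            min_matrix_frac=self.min_matrix_frac,
            border_px=self.border_px,
        )


class PickConfig(_Strict):
    enabled: bool = True
    z_t: float = 0.019
    z_w: int | None = None
    relative: bool = True  # threshold on the unit-max scaled mean spectrum
    deisotope: bool = False
    tol: float = 0.01
    max_iso: int = 3


class RenderConfig(_Strict):
    enabled: bool = True
    mode: str = "similarity"
    ref: tuple[int, int] | None = None  # default: grid center
    channel: int | None = None
    channels: list[int] | None = None
    colormap: str = "fire"


class RunConfig(_Strict):
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    input: str | None = None  # imzML path; None generates the default phantom
    output_dir: str = "."
    dataset_id: str | None = None
    convert: ConvertConfig = ConvertConfig()
    normalize: NormalizeConfig = NormalizeConfig()
    clean: CleanConfig = CleanConfig()
    pick: PickConfig = PickConfig()
    render: RenderConfig = RenderConfig()


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse and validate a JSON config; unknown keys raise by name."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory). A stage failure propagates after logging the stage
    name.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    stages: list[str] = []
    outputs: list[str] = []

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception:
            log.error("pipeline stage %r failed", name)
            raise
        stages.append(name)
        return result

    # ---- input -------------------------------------------------------
    if config.input is None:
        ds, _truth = make_phantom(PhantomSpec(seed=config.seed))
    else:
        ds = msio.read_imzml(config.input)
    if config.dataset_id:
        ds.dataset_id = config.dataset_id

    # ---- convert: m/z crop + store -----------------------------------
    if config.convert.enabled:
        def _convert():
            nonlocal ds
            lo = config.convert.mz_lo if config.convert.mz_lo is not None else ds.mz[0]
            hi = config.convert.mz_hi if config.convert.mz_hi is not None else ds.mz[-1]
            ds = crop_mz(ds, lo, hi)
            store = os.path.join(out, "dataset.h5")
            msio.save_store(ds, store)
            outputs.append(store)
        run_stage("convert", _convert)

    # ---- normalize ---------------------------------------------------
    if config.normalize.enabled:
        def _normalize():
            nonlocal ds
            ds, report = intra_normalize(ds, config.normalize.method)
            path = os.path.join(out, "scale_factors.csv")
            report.to_csv(path)
            outputs.append(path)
        run_stage("normalize", _normalize)

    # ---- clean -------------------------------------------------------
    if config.clean.enabled:
        def _clean():
            nonlocal ds
            params = config.clean.params()
            if config.clean.iterative:
                ds2, cls, emb2 = iterative_clean(
                    ds, config.seed, params, tsvd_components=config.clean.tsvd_components
                )
                if ARTIFACT not in config.clean.remove:
                    log.warning("iterative cleaning always removes artifact pixels")
                ds = ds2
            else:
                emb2 = embed(ds, config.seed, tsvd_components=config.clean.tsvd_components)
                cls = auto_classify(ds, emb2, params)
                for which in config.clean.subtract:
                    if np.any(cls.mask(which)):
                        ds = subtract_class_mean(ds, cls, which)
                for which in config.clean.remove:
                    if np.any(cls.mask(which)):
                        ds = remove_pixels(ds, cls, which)
                        cls.labels = cls.labels[~cls.mask(which)]
            labels_path = os.path.join(out, "labels.csv")
            with open(labels_path, "w") as fh:
                fh.write("i,j,label\n")
                for (i, j), lab in zip(ds.coords, cls.labels):
                    fh.write(f"{i},{j},{lab}\n")
            emb_path = os.path.join(out, "embedding.csv")
            np.savetxt(
                emb_path, emb2.coords2d, delimiter=",", header="x,y", comments=""
            )
            outputs.extend([labels_path, emb_path])
        run_stage("clean", _clean)

    # ---- pick --------------------------------------------------------
    if config.pick.enabled:
        def _pick():
            nonlocal ds
            mu = mean_spectrum(ds)
            if config.pick.relative:
                mu = scale_to_unit_max(mu)
            if config.pick.z_w is not None:
                mu = winsorize_mean(mu, config.pick.z_w)
            ps = detect_peaks(mu, config.pick.z_t, z_w=config.pick.z_w)
            if config.pick.deisotope:
                ps = deisotope(ps, config.pick.tol, max_iso=config.pick.max_iso)
            if len(ps) == 0:
                raise ValueError(f"no peaks above threshold {config.pick.z_t}")
            ds = reduce_to_peaks(ds, ps)
            path = os.path.join(out, "peaks.csv")
            ps.to_csv(path)
            outputs.append(path)
        run_stage("pick", _pick)

    # ---- render ------------------------------------------------------
    if config.render.enabled:
        def _render():
            bds = to_bytes(ds)
            ref = config.render.ref
            if config.render.mode == "similarity" and ref is None:
                center = ds.coords[
                    np.argmin(
                        (ds.coords[:, 0] - ds.width / 2) ** 2
                        + (ds.coords[:, 1] - ds.height / 2) ** 2
                    )
                ]
                ref = (int(center[0]), int(center[1]))
            base = os.path.join(out, "render")
            render(
                bds,
                config.render.mode,
                out_path=base,
                scale_name=config.render.colormap,
                ref=ref,
                channel=config.render.channel,
                channels=config.render.channels,
            )
            outputs.extend([base + ".png", base + "_field.csv", base + "_hist.csv"])
        run_stage("render", _render)

    # ---- manifest ----------------------------------------------------
    manifest = {
        "stages": stages,
        "seed": config.seed,
        "config": config.model_dump(),
        "dataset_id": ds.dataset_id,
        "n_pixels": ds.n_pixels,
        "n_channels": ds.n_channels,
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
    }
    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
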