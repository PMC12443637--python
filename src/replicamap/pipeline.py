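"""End-to-end orchestration: preprocess chain, run configs, provenance.

`standard_preprocess` applies the canonical chain (lockmass → quantize →
TIC → segment → background-correct) to one dataset. `run` executes a
schema-validated YAML config end to end, writing stage outputs with
checksums, a resolved-config copy, a log, and derived per-stage seeds so
stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from . import __version__
from .core import CommonRepresentation, MSIDataset, TissueMask
from .errors import ParameterError
from .preprocess import (
    BackgroundStats,
    BinAxis,
    LockmassReport,
    SegmentationChannels,
    background_correct,
    lockmass_align,
    quantize,
    segment_tissue,
    tic_normalize,
)

__all__ = ["PreprocessResult", "standard_preprocess", "RunConfig", "run", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable, < 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PreprocessResult:
    """All artefacts of the standard preprocessing chain for one sample."""

    tic: CommonRepresentation  # TIC-normalized (correlation/volcano scale)
    corrected: CommonRepresentation  # background z-scored (clustering/classification)
    mask: TissueMask
    background: BackgroundStats
    lockmass: LockmassReport


def standard_preprocess(
    dataset: MSIDataset,
    axis: BinAxis | None = None,
    channels: SegmentationChannels | None = None,
    lockmass_mz: float | None = None,
    lockmass_tol: float = 0.1,
    filter_size: int = 3,
) -> PreprocessResult:
    """lockmass → quantize → TIC normalize → segment → background correct.

    Pass ``lockmass_mz=None`` to skip alignment (already-calibrated or
    drift-free data).
    """
    report = LockmassReport()
    if lockmass_mz is not None:
        dataset, report = lockmass_align(dataset, lockmass_mz, lockmass_tol)
    binned = quantize(dataset, axis)
    tic = tic_normalize(binned)
    mask = segment_tissue(tic, channels, filter_size=filter_size)
    corrected, stats = background_correct(tic, mask)
    return PreprocessResult(
        tic=tic, corrected=corrected, mask=mask, background=stats, lockmass=report
    )


# ---------------------------------------------------------------------------
# run configs


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mz_start: float = 600.0
    mz_end: float = 900.0
    bin_width: float = 0.5
    lockmass_mz: float | None = None
    lockmass_tol: float = 0.1
    channels: tuple[float, float, float] = (794.55, 834.53, 886.60)
    filter_size: int = 3


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "section"  # section | cohort | longitudinal
    grid: tuple[int, int] = (32, 32)
    pixel_size: float = 100.0
    noise_sigma: float = 0.4


class RegionsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 3


class RunConfig(BaseModel):
    """Schema-validated configuration for an end-to-end run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "runs/demo"
    input_imzml: str | None = None  # when unset, a phantom is simulated
    simulate: SimulateConfig = SimulateConfig()
    preprocessing: PreprocessConfig = PreprocessConfig()
    regions: RegionsConfig = RegionsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        try:
            return cls.model_validate(raw)
        except PydanticValidationError as exc:
            raise ParameterError(f"invalid run config: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, resume: bool = True) -> Path:
    """Execute an end-to-end run; returns the run directory.

    The run directory receives the resolved config, a log, stage outputs
    (CSV/JSON) and a checksum manifest. With ``resume=True`` a run
    directory whose manifest matches the config hash is returned as-is.
    """
    from .io import read_imzml
    from .regions import hca_regions, name_clusters, region_areas
    from .simulate import PhantomSpec, generate_section

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = config.model_dump_json(indent=2)
    config_hash = hashlib.sha256(config_json.encode()).hexdigest()
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("config_hash") == config_hash:
                logger.info("run already complete; resuming from %s", out)
                return out
        except json.JSONDecodeError:
            pass

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("replicamap")
    root.addHandler(handler)
    try:
        (out / "config.resolved.json").write_text(config_json)
        if config.input_imzml:
            dataset = read_imzml(config.input_imzml)
        else:
            spec = PhantomSpec(
                grid=tuple(config.simulate.grid),
                pixel_size=config.simulate.pixel_size,
                noise_sigma=config.simulate.noise_sigma,
                seed=derive_seed(config.seed, "simulate"),
            )
            dataset, _truth = generate_section(spec)
        pp = config.preprocessing
        result = standard_preprocess(
            dataset,
            axis=BinAxis(pp.mz_start, pp.mz_end, pp.bin_width),
            channels=SegmentationChannels(tuple(pp.channels)),
            lockmass_mz=pp.lockmass_mz,
            lockmass_tol=pp.lockmass_tol,
            filter_size=pp.filter_size,
        )
        labels = hca_regions(
            result.corrected,
            result.mask,
            k=config.regions.k,
            subsample_seed=derive_seed(config.seed, "hca"),
        )
        labels = name_clusters(labels, result.tic)
        areas = region_areas(labels)
        areas.to_csv(out / "region_areas.csv", index=False)
        cluster_means = labels.cluster_means.T
        cluster_means.index.name = "mz"
        cluster_means.to_csv(out / "cluster_mean_spectra.csv")
        pd.DataFrame(
            {
                "x": result.tic.coords[:, 0],
                "y": result.tic.coords[:, 1],
                "tissue": result.mask.pixel_flags(result.tic.coords),
                "cluster": labels.labels,
            }
        ).to_csv(out / "pixel_labels.csv", index=False)
        summary = {
            "version": __version__,
            "config_hash": config_hash,
            "seed": config.seed,
            "stage_seeds": {
                s: derive_seed(config.seed, s) for s in ("simulate", "hca")
            },
            "n_pixels": int(len(dataset)),
            "n_tissue": int(result.mask.n_tissue),
            "n_background": int(result.background.n_background),
            "regions": {
                row["region"]: row["area_mm2"] for _, row in areas.iterrows()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        outputs = [
            "config.resolved.json",
            "summary.json",
            "region_areas.csv",
            "cluster_mean_spectra.csv",
            "pixel_labels.csv",
        ]
        manifest = {
            "version": __version__,
            "config_hash": config_hash,
            "checksums": {name: _sha256(out / name) for name in outputs},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
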