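"""End-to-end orchestration: synth -> fuse -> link -> quantify -> gate ->
profile (-> model), with a provenance manifest.

Every stage parameter is echoed into ``manifest.json`` in the run
directory together with SHA-256 checksums of all outputs, so a run can be
audited and reproduced exactly from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import ColonySpec, generate_colony, degrade_segmentation, write_colony
from .linking import LinkParams, fuse_segmentations, link_stack, nuclei_table
from .quant import measure_nuclei, transform_table
from .gating import (
    fit_thresholds,
    rescale_to_threshold,
    gate_populations,
    population_fractions,
    save_thresholds,
)
from .profiles import radial_positive_fraction

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "analyse_colonies"]

STAGES = ("synth", "link", "quantify", "gate", "profile", "model")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict[str, str]:
        return {"stage": self.stage, "error": type(self.cause).__name__, "message": str(self.cause)}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    colony: ColonySpec = dc_field(default_factory=ColonySpec)
    n_colonies: int = 4
    stages: Sequence[str] = STAGES[:5]
    miss_rate: float = 0.05
    merge_rate: float = 0.05
    link_params: LinkParams | None = None
    gate_markers: Sequence[str] | None = None
    profile_gate: str = "PGCLC_broad"
    bandwidth: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.colony.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_link_params(spec: ColonySpec) -> LinkParams:
    return LinkParams.from_geometry(
        nucleus_diameter_um=2.0 * spec.nucleus_radius,
        z_spacing_um=spec.z_spacing,
        pixel_size_um=spec.pixel_size,
    )


def analyse_colonies(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Run synth -> link -> quantify -> gate in memory for all colonies.

    Returns (gated cell table over all colonies, thresholds, population
    fraction table).  Seeds for colony generation and degradation derive
    deterministically from ``config.seed``.
    """
    spec = config.colony
    lp = config.link_params or _default_link_params(spec)
    tables = []
    for c in range(config.n_colonies):
        cspec = ColonySpec(**{**_spec_kwargs(spec), "seed": (config.seed * 1009 + c) % (2**31 - 1)})
        image, truth = generate_colony(cspec)
        primary, fallback = degrade_segmentation(
            truth, config.miss_rate, config.merge_rate, seed=cspec.seed + 1
        )
        fused = fuse_segmentations(primary, fallback)
        nuclei = link_stack(fused, lp, pixel_size=cspec.pixel_size, z_spacing=cspec.z_spacing)
        table = measure_nuclei(image, nuclei, cspec.channels, colony_id=c)
        tables.append(transform_table(table))
    cells = pd.concat(tables, ignore_index=True)

    markers = list(config.gate_markers or spec.markers)
    thresholds = fit_thresholds(cells, markers, seed=config.seed)
    cells = rescale_to_threshold(cells, thresholds)
    gated = gate_populations(cells, thresholds)
    fractions = population_fractions(gated)
    return gated, thresholds, fractions


def _spec_kwargs(spec: ColonySpec) -> dict[str, Any]:
    import dataclasses

    return {f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages and write outputs + manifest.

    Any stage failure aborts the run; the manifest then contains a
    machine-readable error record naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "pgcolony",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages_requested": list(config.stages),
        "stages_completed": [],
        "parameters": {
            "colony": _jsonable(_spec_kwargs(config.colony)),
            "n_colonies": config.n_colonies,
            "miss_rate": config.miss_rate,
            "merge_rate": config.merge_rate,
            "link_params": asdict(config.link_params or _default_link_params(config.colony)),
            "profile_gate": config.profile_gate,
            "bandwidth": config.bandwidth,
        },
        "outputs": {},
    }

    def done(stage: str, files: dict[str, str]) -> None:
        manifest["stages_completed"].append(stage)
        for key, p in files.items():
            manifest["outputs"][f"{stage}/{key}"] = {"path": str(p), "sha256": _sha256(Path(p))}

    try:
        stage = "synth"
        spec = config.colony
        lp = config.link_params or _default_link_params(spec)
        colonies = []
        for c in range(config.n_colonies):
            cspec = ColonySpec(**{**_spec_kwargs(spec), "seed": (config.seed * 1009 + c) % (2**31 - 1)})
            image, truth = generate_colony(cspec)
            colonies.append((cspec, image, truth))
        if "synth" in config.stages:
            paths = write_colony(out, *colonies[0][1:], prefix="colony0")
            done("synth", paths)

        stage = "link"
        all_tables = []
        for c, (cspec, image, truth) in enumerate(colonies):
            primary, fallback = degrade_segmentation(
                truth, config.miss_rate, config.merge_rate, seed=cspec.seed + 1
            )
            fused = fuse_segmentations(primary, fallback)
            nuclei = link_stack(fused, lp, pixel_size=cspec.pixel_size, z_spacing=cspec.z_spacing)
            if c == 0 and "link" in config.stages:
                ntab_path = out / "nuclei_colony0.csv"
                nuclei_table(nuclei, colony_id=0).to_csv(ntab_path, index=False)
                done("link", {"nuclei": str(ntab_path)})
            stage = "quantify"
            table = measure_nuclei(image, nuclei, cspec.channels, colony_id=c)
            all_tables.append(transform_table(table))
            stage = "link"
        stage = "quantify"
        cells = pd.concat(all_tables, ignore_index=True)
        if "quantify" in config.stages:
            cells_path = out / "cells.csv"
            cells.to_csv(cells_path, index=False)
            done("quantify", {"cells": str(cells_path)})

        stage = "gate"
        markers = list(config.gate_markers or spec.markers)
        thresholds = fit_thresholds(cells, markers, seed=config.seed)
        cells = rescale_to_threshold(cells, thresholds)
        gated = gate_populations(cells, thresholds)
        fractions = population_fractions(gated)
        if "gate" in config.stages:
            gated_path = out / "gated.csv"
            gated.to_csv(gated_path, index=False)
            th_path = out / "thresholds.json"
            save_thresholds(thresholds, th_path)
            frac_path = out / "population_fractions.csv"
            fractions.to_csv(frac_path, index=False)
            done("gate", {"gated": str(gated_path), "thresholds": str(th_path), "fractions": str(frac_path)})

        stage = "profile"
        if "profile" in config.stages:
            profile = radial_positive_fraction(
                gated, config.profile_gate, bandwidth=config.bandwidth,
                colony_radius=spec.radius,
            )
            prof_path = out / f"profile_{config.profile_gate}.csv"
            profile.to_csv(prof_path)
            done("profile", {"profile": str(prof_path)})

        stage = "model"
        if "model" in config.stages:
            from .fatemodel import Condition, simulate_fates, edge_band_summary

            cond = Condition("WT", radius=spec.radius)
            fld = simulate_fates(cond)
            band = edge_band_summary(fld)
            model_path = out / "model_wt_edge_band.json"
            model_path.write_text(json.dumps(band, indent=2))
            done("model", {"edge_band": str(model_path)})
    except Exception as exc:  # noqa: BLE001 - abort with a stage-tagged record
        err = PipelineError(stage, exc)
        manifest["error"] = err.record()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise err from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
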