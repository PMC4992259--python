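"""End-to-end orchestration: cohort -> normalize -> probabilities -> sweep.

A :class:`RunConfig` (constructible from YAML) names either an expression
table on disk or a synthetic-generator configuration, plus the estimator and
sweep knobs and a master seed.  :func:`run` executes the full workflow and
writes all tabular outputs as UTF-8 comma-separated CSV together with a
manifest recording the configuration hash, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classification import SweepConfig, SweepResult, sweep
from .expression import Cohort, minmax_normalize, read_cohort
from .labor_probability import BasinGridSpec, probability_surface
from .ode_model import LaborBasinError
from .synthetic_data import GeneratorConfig, default_config, generate_cohort

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run", "load_run_config"]

logger = logging.getLogger("laborbasin")
if not logger.handlers:
    _handler = logging.StreamHandler()
    _handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.addHandler(_handler)
logger.setLevel(logging.INFO)


class PipelineError(LaborBasinError):
    """A pipeline stage failed; the message names the stage."""


def _package_version() -> str:
    import laborbasin

    return laborbasin.__version__


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs.

    Exactly one of ``input_path`` (a cohort CSV/TSV) or ``generator`` is the
    data source; with neither set, the default synthetic cohort is generated
    with the master seed.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    master_seed: int = 0
    ci_method: str = "bootstrap-median"
    n_boot: int = 10_000
    basin_resolution: int = 101
    subsample: int | None = None
    pooled_normalization: bool = False
    surface: bool = False
    surface_n: int = 21
    out_dir: str = "results"

    def sweep_config(self) -> SweepConfig:
        return SweepConfig(
            ci_method=self.ci_method,
            n_boot=self.n_boot,
            master_seed=self.master_seed,
            grid=BasinGridSpec(resolution=self.basin_resolution),
            subsample=self.subsample,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognized keys mirror the RunConfig fields; a ``generator`` mapping may
    override ``seed``, ``effect_size``, ``null_mode`` and
    ``exclude_one_term_il`` of the default synthetic configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_cfg = None
    if "generator" in raw and raw["generator"] is not None:
        allowed = {"seed", "effect_size", "null_mode", "exclude_one_term_il"}
        unknown = set(raw["generator"]) - allowed
        if unknown:
            raise PipelineError(f"unknown generator key(s): {sorted(unknown)}")
        gen_cfg = default_config(**raw["generator"])
    field_names = {f.name for f in dataclasses.fields(RunConfig)} - {"generator"}
    kwargs = {k: v for k, v in raw.items() if k in field_names}
    unknown = set(raw) - field_names - {"generator"}
    if unknown:
        raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(generator=gen_cfg, **kwargs)


def _config_hash(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    canonical = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Frames produced by one run, plus where they were written."""

    cohort: Cohort
    normalized: Cohort
    result: SweepResult
    surface: pd.DataFrame | None
    manifest: dict
    paths: dict


def run(config: RunConfig | None = None) -> ReportBundle:
    """Execute the full workflow and write the report bundle to disk.

    Outputs (under ``config.out_dir``): normalized_cohort.csv,
    probabilities.csv (sample x 6 predictors), model_summary.csv,
    null_summary.csv, outcomes.csv, optional surface.csv, manifest.json.
    Stage failures are re-raised as :class:`PipelineError` naming the stage;
    outputs written before the failure are left in place.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name: str):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        stage("load")
        if config.input_path is not None:
            cohort = read_cohort(config.input_path)
        else:
            gen = config.generator or default_config(seed=config.master_seed)
            cohort = generate_cohort(gen)
            raw_path = out / "raw_cohort.csv"
            cohort.data.to_csv(raw_path, index=False)
            paths["raw_cohort"] = str(raw_path)
        done("load")
    except LaborBasinError as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    try:
        stage("normalize")
        normalized = minmax_normalize(cohort, pooled=config.pooled_normalization)
        norm_path = out / "normalized_cohort.csv"
        normalized.data.to_csv(norm_path, index=False)
        paths["normalized_cohort"] = str(norm_path)
        done("normalize")
    except LaborBasinError as exc:
        raise PipelineError(f"stage normalize: {exc}") from exc

    try:
        stage("sweep")
        result = sweep(normalized, config.sweep_config())
        prob_path = out / "probabilities.csv"
        result.probabilities.rename_axis("sample_id").to_csv(prob_path)
        paths["probabilities"] = str(prob_path)
        for name, frame in (
            ("model_summary", result.model_summary),
            ("null_summary", result.null_summary),
            ("outcomes", result.outcomes),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = str(p)
        done("sweep")
    except LaborBasinError as exc:
        raise PipelineError(f"stage sweep: {exc}") from exc

    surface = None
    if config.surface:
        try:
            stage("surface")
            import numpy as np

            grid = np.linspace(0.0, 1.0, config.surface_n)
            surface = probability_surface(
                grid, grid, k=1.0, spec=BasinGridSpec(resolution=config.basin_resolution)
            )
            surf_path = out / "surface.csv"
            surface.rename_axis("b").to_csv(surf_path)
            paths["surface"] = str(surf_path)
            done("surface")
        except LaborBasinError as exc:
            raise PipelineError(f"stage surface: {exc}") from exc

    manifest = {
        "package_version": _package_version(),
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "n_samples": len(cohort.sample_ids),
        "n_partitions": result.n_partitions,
        "n_outcomes": int(len(result.outcomes)),
        "timings_s": timings,
        "outputs": paths,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    logger.info("run complete: %d outcomes over %d partitions",
                manifest["n_outcomes"], manifest["n_partitions"])

    return ReportBundle(
        cohort=cohort,
        normalized=normalized,
        result=result,
        surface=surface,
        manifest=manifest,
        paths=paths,
    )
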