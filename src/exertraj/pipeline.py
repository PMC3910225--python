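"""End-to-end pipeline: filter, individual fits, summaries, RMSE-difference
analysis, optional mixed-effects fits, clustering, and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .clustering import cluster_trajectories, describe_clusters, represent_trajectories
from .fitting import (
    FitConfig,
    compare_families,
    fits_to_frame,
    rmse_difference_analysis,
    summarize_fits,
)
from .io import cohort_to_frame, read_cohort_csv, write_json
from .mixed import McmcConfig, fit_mixed
from .simulate import CohortConfig, filter_min_points, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Exactly one of ``input_csv`` / ``generator`` selects the cohort source."""

    output_dir: str = "exertraj-results"
    input_csv: Optional[str] = None
    generator: Optional[CohortConfig] = None
    min_points: int = 6
    fit: FitConfig = field(default_factory=FitConfig)
    mcmc: Optional[McmcConfig] = None          # None skips the mixed stage
    mixed_variants: tuple[str, ...] = ("MQD", "MQDV")
    cluster_k: "int | str" = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_csv / generator must be provided"
            )


def _config_hash(config: PipelineConfig) -> str:
    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    blob = json.dumps(encode(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages, persisting each stage's output.

    Returns the manifest dict (also written to ``manifest.json``).  On a
    stage failure the partial manifest is persisted and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        if config.input_csv is not None:
            cohort = read_cohort_csv(config.input_csv)
        else:
            cohort = generate_cohort(config.generator).trajectories
        cohort_to_frame(cohort).to_csv(outdir / "cohort.csv", index=False)
        manifest["stages"][stage] = {
            "n_subjects": len(cohort), "seconds": round(time.time() - t0, 3),
        }

        stage = "filter"
        t0 = time.time()
        cohort, report = filter_min_points(cohort, config.min_points)
        write_json(
            {"n_input": report.n_input, "n_retained": report.n_retained,
             "excluded": report.excluded},
            outdir / "filter_report.json",
        )
        manifest["stages"][stage] = {
            "n_retained": report.n_retained, "seconds": round(time.time() - t0, 3),
        }

        stage = "fit"
        t0 = time.time()
        comparisons = {
            t.subject_id: compare_families(t, config.fit) for t in cohort
        }
        all_fits = [f for comp in comparisons.values()
                    for f in comp.fits.values()]
        fits_to_frame(all_fits).to_csv(outdir / "individual_fits.csv", index=False)
        manifest["stages"][stage] = {
            "n_fits": len(all_fits), "seconds": round(time.time() - t0, 3),
        }

        stage = "summaries"
        t0 = time.time()
        summarize_fits(all_fits, cohort).to_csv(
            outdir / "fit_summaries.csv", index=False)
        trajmap = {t.subject_id: t for t in cohort}
        diff = rmse_difference_analysis(comparisons, trajmap)
        pd.concat(
            [frame.assign(pair=f"{a}-{b}") for (a, b), frame in diff.items()],
            ignore_index=True,
        ).to_csv(outdir / "rmse_differences.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

        if config.mcmc is not None:
            stage = "mixed"
            t0 = time.time()
            mixed_info = {}
            for variant in config.mixed_variants:
                result = fit_mixed(cohort, variant, config.mcmc)
                result.samples.to_csv(
                    outdir / f"mixed_{variant}_draws.csv", index=False)
                result.posterior_summary.to_csv(
                    outdir / f"mixed_{variant}_summary.csv", index=False)
                mixed_info[variant] = {
                    "dic": result.dic, "p_dic": result.p_dic,
                    "max_psrf": result.max_psrf, "converged": result.converged,
                    "acceptance_rates": result.acceptance_rates,
                }
            write_json(mixed_info, outdir / "mixed_diagnostics.json")
            manifest["stages"][stage] = {
                "variants": list(config.mixed_variants),
                "seconds": round(time.time() - t0, 3),
            }

        stage = "cluster"
        t0 = time.time()
        coefs, ids, basis = represent_trajectories(cohort)
        model, assignment = cluster_trajectories(
            coefs, ids, basis, k=config.cluster_k, seed=config.seed)
        pd.DataFrame(
            [{"subject_id": sid, "cluster": lab}
             for sid, lab in assignment.labels.items()]
        ).to_csv(outdir / "cluster_assignments.csv", index=False)
        model.mean_curves().to_csv(outdir / "cluster_mean_curves.csv", index=False)
        covmap = {t.subject_id: dict(t.covariates) for t in cohort}
        describe_clusters(assignment, covmap).to_csv(
            outdir / "cluster_composition.csv", index=False)
        manifest["stages"][stage] = {
            "n_clusters": model.n_clusters,
            "seconds": round(time.time() - t0, 3),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_json(manifest, outdir / "manifest.json")
        raise PipelineError(stage, exc) from exc

    write_json(manifest, outdir / "manifest.json")
    return manifest
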