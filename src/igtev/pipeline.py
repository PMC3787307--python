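"""End-to-end orchestration: generate -> fit -> metrics -> analysis.

A run is driven by one :class:`RunConfig` (JSON-serializable). The global
seed fans out to stage-specific seeds through a stable hash of the stage
name, so any stage can be rerun independently yet reproducibly. All
tables are written as UTF-8 delimited text with headers; nested results as
JSON. Given a fixed config the run is byte-identical except for
``timings.json``, which records wall-clock bookkeeping only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import analysis as an
from .cohort import Cohort, CohortConfig, generate_cohort
from .metrics import block_net_scores, metrics_table
from .model import FitSettings, fit_subject
from .task import build_standard_decks, decks_to_json, read_sessions_csv, write_sessions_csv

log = logging.getLogger("igtev")

read_sessions = read_sessions_csv  # session ingestion entry point

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    fit: FitSettings = Field(default_factory=FitSettings)
    blocks: tuple[tuple[int, int], ...] = ((1, 40), (41, 100))
    seed: int = 0
    out_dir: str = "igtev_run"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    """Bookkeeping of one run: per-stage record counts, convergence and
    headline analysis numbers."""

    record_counts: dict[str, int] = field(default_factory=dict)
    n_converged: int = 0
    mean_bic: float = float("nan")
    share_bic_positive: float = float("nan")
    tests: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    elapsed: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "record_counts": self.record_counts,
            "n_converged": self.n_converged,
            "mean_bic": self.mean_bic,
            "share_bic_positive": self.share_bic_positive,
            "tests": self.tests,
            "warnings": self.warnings,
        }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def fit_sessions(sessions, settings: FitSettings) -> pd.DataFrame:
    """Fit every session; one row per subject in the fit-table schema."""
    rows = []
    for s in sessions:
        fit = fit_subject(s, settings)
        rows.append(
            {
                "subject_id": s.subject_id,
                "w": fit.params.w,
                "phi": fit.params.phi,
                "c": fit.params.c,
                "loglik_model": fit.loglik_model,
                "loglik_baseline": fit.loglik_baseline,
                "bic_stat": fit.bic_stat,
                "converged": int(fit.converged),
            }
        )
    return pd.DataFrame(rows)


def _analysis_stage(
    subjects: pd.DataFrame, fits: pd.DataFrame, metrics: pd.DataFrame,
    blocks, report: RunReport,
) -> tuple[dict, pd.DataFrame]:
    tests: dict = {}

    def tr(result) -> dict:
        return {"statistic": result.statistic, "df": result.df, "p_value": result.p_value}

    # 2x2 wave-1 by wave-2 smoking status
    tab = pd.crosstab(subjects["smoker_t1"], subjects["smoker_t2"]).reindex(
        index=[0, 1], columns=[0, 1], fill_value=0
    )
    try:
        tests["chi2_smoker_t1_by_t2"] = tr(an.pearson_chi2_2x2(tab.to_numpy()))
    except an.DegenerateTableError as exc:
        report.warnings.append(f"chi2_smoker_t1_by_t2 degenerate: {exc}")

    # Wave-1 group comparisons on behavioral and model measures
    merged = subjects.merge(fits, on="subject_id").merge(metrics, on="subject_id")
    if len(merged) != len(subjects):
        raise PipelineError("analysis: join lost records")
    g1 = merged[merged["smoker_t1"] == 1]
    g0 = merged[merged["smoker_t1"] == 0]
    for var in ("net_total", "w", "phi", "c", "wm_score", "sap"):
        try:
            tests[f"ttest_t1_{var}"] = tr(an.independent_t_test(g0[var], g1[var]))
        except (ValueError, an.DegenerateInputError) as exc:
            report.warnings.append(f"ttest_t1_{var} degenerate: {exc}")

    # Group x block split-plot contrast for wave-2 status
    b1 = f"net_{blocks[0][0]}_{blocks[0][1]}"
    b2 = f"net_{blocks[1][0]}_{blocks[1][1]}"
    if merged["smoker_t2"].nunique() == 2:
        try:
            anc = an.block_group_interaction(
                merged[[b1, b2]].to_numpy(),
                merged["smoker_t2"].to_numpy(),
                merged[["age", "male", "vocational"]],
            )
            tests["block_group_interaction_t2"] = tr(anc.interaction)
            tests["block_group_main_t2"] = tr(anc.group)
        except ValueError as exc:
            report.warnings.append(f"block_group_interaction_t2 degenerate: {exc}")
    else:
        report.warnings.append("block_group_interaction_t2 skipped: one outcome class")

    # Prediction battery
    try:
        suite = an.run_prediction_suite(subjects, fits, metrics)
        suite_frame = an.suite_to_frame(suite)
        for (model, focal), summ in suite.items():
            if summ.separated:
                report.warnings.append(f"{model}/{focal}: separation flagged")
    except ValueError as exc:
        report.warnings.append(f"prediction suite skipped: {exc}")
        suite_frame = pd.DataFrame()
    return tests, suite_frame


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all tables under ``out_dir``.

    Stages: deck program -> cohort generation -> per-subject ML fitting ->
    behavioral metrics -> statistical analysis -> report. Any stage failure
    aborts with a stage-tagged :class:`PipelineError`.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    cohort_cfg = config.cohort.model_copy(update={"seed": stage_seed(config.seed, "cohort")})
    fit_cfg = config.fit.model_copy(update={"seed": stage_seed(config.seed, "fit")})

    def timed(stage: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                report.elapsed[stage] = time.perf_counter() - self.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

        return _T()

    with timed("decks"):
        decks = build_standard_decks()
        decks_to_json(decks, out / "decks.json")

    with timed("cohort"):
        cohort: Cohort = generate_cohort(cohort_cfg)
        subjects = cohort.to_frame()
        subjects.to_csv(out / "subjects.csv", index=False, float_format=FLOAT_FORMAT)
        write_sessions_csv(cohort.sessions, out / "sessions.csv")
        report.record_counts["subjects"] = len(subjects)
        report.record_counts["sessions"] = len(cohort.sessions)
        log.info("cohort: %d subjects", len(subjects))

    with timed("fit"):
        fits = fit_sessions(cohort.sessions, fit_cfg)
        fits.to_csv(out / "fits.csv", index=False, float_format=FLOAT_FORMAT)
        report.record_counts["fits"] = len(fits)
        report.n_converged = int(fits["converged"].sum())
        report.mean_bic = float(fits["bic_stat"].mean())
        report.share_bic_positive = float((fits["bic_stat"] > 0).mean())
        log.info("fit: mean BIC %.2f, %d/%d converged", report.mean_bic, report.n_converged, len(fits))

    with timed("metrics"):
        metrics = metrics_table(cohort.sessions, config.blocks)
        metrics.to_csv(out / "metrics.csv", index=False, float_format=FLOAT_FORMAT)
        report.record_counts["metrics"] = len(metrics)

    with timed("analysis"):
        tests, suite_frame = _analysis_stage(subjects, fits, metrics, config.blocks, report)
        report.tests = tests
        _write_json(tests, out / "analysis.json")
        suite_frame.to_csv(out / "models.csv", index=False, float_format=FLOAT_FORMAT)
        report.record_counts["model_summaries"] = (
            suite_frame[["model", "focal"]].drop_duplicates().shape[0] if len(suite_frame) else 0
        )

    _write_json(report.to_dict(), out / "report.json")
    _write_json({k: round(v, 3) for k, v in report.elapsed.items()}, out / "timings.json")
    return report
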