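"""Cohort-level statistical stage.

Implements the study-style analysis battery: Pearson chi-square tests on
2x2 contingency tables (no continuity correction), independent t-tests
(pooled variance by default), a between-within ANCOVA for the group-by-block
contrast on the two IGT blocks, and the two prediction models — a logistic
regression for wave-2 smoking status and a linear regression (with
standardized betas) for wave-2 smoking level — each run once per focal
predictor with a fixed covariate adjustment set.

The numerical work is delegated to scipy.stats and statsmodels; this module
owns the contracts (error signalling for degenerate tables, separation and
rank deficiency) and the summary shapes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(ValueError):
    """A contingency-table margin is zero; the chi-square test is undefined."""


class DegenerateInputError(ValueError):
    """Samples carry no variance to test."""


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (complete or quasi-separation)."""


class DesignError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float


@dataclass(frozen=True)
class AncovaResult:
    """Between-within ANCOVA on two blocks: interaction and group effects."""

    interaction: TestResult
    group: TestResult


@dataclass
class ModelSummary:
    """Per-term regression output in the study's reporting shape.

    ``table`` is indexed by term with columns ``B`` (raw coefficient),
    ``SE``, ``effect`` (exp(B) for logistic models, standardized beta for
    linear models), ``ci_low``/``ci_high`` (95%; on the exp(B) scale for
    logistic, on B for linear) and ``p_value``.
    """

    outcome: str
    kind: str  # "logistic" | "linear"
    n: int
    table: pd.DataFrame
    focal: str = ""
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def separated(self) -> bool:
        return "separation" in self.flags


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def pearson_chi2_2x2(table: Sequence[Sequence[float]] | np.ndarray) -> TestResult:
    """Pearson chi-square on a 2x2 table, one degree of freedom, no Yates
    continuity correction (the convention that reproduces the printed
    statistics of the reference tables exactly)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if arr.sum() < 1:
        raise DegenerateTableError("table total must be >= 1")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("every row and column margin must be nonzero")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), df=float(dof), p_value=float(p))


def independent_t_test(x, y, pooled: bool = True) -> TestResult:
    """Two-sample t-test; Student (pooled variance) by default, Welch optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        raise DegenerateInputError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return TestResult(statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def block_group_interaction(
    block_scores: np.ndarray | Sequence[Sequence[float]],
    group: Sequence[int],
    covariates: pd.DataFrame | None = None,
) -> AncovaResult:
    """Group-by-block contrast of a two-block split-plot design with covariates.

    With exactly two blocks the interaction test reduces to an ANCOVA on the
    within-subject difference scores (block2 - block1) regressed on group
    plus covariates; the group main effect is the same ANCOVA on the
    subject means. Returns F statistics with (1, n - p) degrees of freedom.
    """
    scores = np.asarray(block_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("block_scores must be n_subjects x 2")
    g = np.asarray(group, dtype=float)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if cov.isna().any().any():
            raise ValueError("missing covariate values")
        X = pd.concat([pd.Series(g, name="group"), cov], axis=1)
    else:
        X = pd.DataFrame({"group": g})
    X = sm.add_constant(X.astype(float), has_constant="add")

    def group_f(y: np.ndarray) -> TestResult:
        full = sm.OLS(y, X).fit()
        if full.df_resid < 1:
            raise ValueError("not enough subjects for the covariate-adjusted F test")
        restricted = sm.OLS(y, X.drop(columns="group")).fit()
        df_resid = float(full.df_resid)
        sse_full, sse_restr = float(full.ssr), float(restricted.ssr)
        # zero residual variance: no evidence against (nor for) a group effect
        tiny = 1e-12 * max(1.0, float(np.sum(y**2)))
        if sse_full <= tiny:
            fstat = 0.0 if sse_restr - sse_full <= tiny else math.inf
        else:
            fstat = max(sse_restr - sse_full, 0.0) / (sse_full / df_resid)
        p = float(stats.f.sf(fstat, 1, df_resid))
        return TestResult(statistic=fstat, df=(1.0, df_resid), p_value=p)

    diff = scores[:, 1] - scores[:, 0]
    means = scores.mean(axis=1)
    return AncovaResult(interaction=group_f(diff), group=group_f(means))


# ---------------------------------------------------------------------------
# Prediction models
# ---------------------------------------------------------------------------

def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    X = design.astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return Xc


def fit_logistic(outcome, design: pd.DataFrame, outcome_name: str = "outcome") -> ModelSummary:
    """Maximum-likelihood logistic regression with Wald 95% CIs on exp(B).

    Complete or quasi-complete separation raises :class:`SeparationError`
    rather than returning silently diverged estimates.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = _check_design(design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from None
    if not res.mle_retvals.get("converged", True) or np.abs(res.params.drop("const")).max() > 30:
        raise SeparationError("logistic fit did not converge; likely separation")
    b = res.params
    se = res.bse
    table = pd.DataFrame(
        {
            "B": b,
            "SE": se,
            "effect": np.exp(b),
            "ci_low": np.exp(b - Z_95 * se),
            "ci_high": np.exp(b + Z_95 * se),
            "p_value": res.pvalues,
        }
    ).drop(index="const")
    return ModelSummary(outcome=outcome_name, kind="logistic", n=len(y), table=table)


def fit_linear_standardized(outcome, design: pd.DataFrame, outcome_name: str = "outcome") -> ModelSummary:
    """Ordinary least squares with standardized betas alongside raw B.

    The standardized beta for term j is ``B_j * sd(x_j) / sd(y)``,
    identical to refitting on z-scored variables; confidence intervals are
    reported on the raw coefficient (B +/- 1.96 SE).
    """
    y = np.asarray(outcome, dtype=float)
    X = _check_design(design)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than model terms")
    res = sm.OLS(y, X).fit()
    b = res.params
    se = res.bse
    sd_y = float(np.std(y, ddof=1))
    sd_x = X.std(ddof=1)
    beta = b * sd_x / sd_y if sd_y > 0 else b * 0.0
    table = pd.DataFrame(
        {
            "B": b,
            "SE": se,
            "effect": beta,
            "ci_low": b - Z_95 * se,
            "ci_high": b + Z_95 * se,
            "p_value": res.pvalues,
        }
    ).drop(index="const")
    return ModelSummary(outcome=outcome_name, kind="linear", n=len(y), table=table)


ADJUSTMENT_COVARIATES = ["age", "male", "vocational", "wm_score", "sap"]
FOCAL_PREDICTORS = ["net_total", "w", "phi", "c"]


def run_prediction_suite(
    subjects: pd.DataFrame,
    fits: pd.DataFrame,
    metrics: pd.DataFrame,
) -> dict[tuple[str, str], ModelSummary]:
    """Run the full battery: for each focal predictor (overall net score and
    the three rEV parameters), a logistic model of wave-2 smoking status
    ("model_I") and a standardized linear model of wave-2 smoking level
    ("model_II"), each adjusted for age, gender, school type, working
    memory, academic performance and the wave-1 value of the outcome.
    Focal predictors enter one at a time, never jointly.

    The three tables join on ``subject_id``; any loss of records in a join
    raises a data error. A logistic model hitting separation is returned
    flagged rather than aborting the battery.
    """
    n = len(subjects)
    merged = subjects.merge(fits[["subject_id", "w", "phi", "c"]], on="subject_id")
    merged = merged.merge(metrics[["subject_id", "net_total"]], on="subject_id")
    if len(merged) != n:
        raise ValueError(
            f"join lost records: {n} subjects vs {len(merged)} joined rows"
        )
    out: dict[tuple[str, str], ModelSummary] = {}
    for focal in FOCAL_PREDICTORS:
        design_i = merged[ADJUSTMENT_COVARIATES + ["smoker_t1", focal]]
        try:
            out[("model_I", focal)] = fit_logistic(
                merged["smoker_t2"], design_i, outcome_name="smoker_t2"
            )
        except SeparationError:
            out[("model_I", focal)] = ModelSummary(
                outcome="smoker_t2", kind="logistic", n=len(merged),
                table=pd.DataFrame(), flags=["separation"],
            )
        design_ii = merged[ADJUSTMENT_COVARIATES + ["level_t1", focal]]
        out[("model_II", focal)] = fit_linear_standardized(
            merged["level_t2"], design_ii, outcome_name="level_t2"
        )
    for key, summary in out.items():
        summary.focal = key[1]
    return out


def suite_to_frame(suite: Mapping[tuple[str, str], ModelSummary]) -> pd.DataFrame:
    """Flatten a prediction-suite result into one long table."""
    rows = []
    for (model, focal), summ in suite.items():
        if summ.separated:
            rows.append({"model": model, "focal": focal, "term": "", "flag": "separation"})
            continue
        for term, row in summ.table.iterrows():
            rows.append(
                {
                    "model": model,
                    "focal": focal,
                    "term": term,
                    "B": row["B"],
                    "SE": row["SE"],
                    "effect": row["effect"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p_value": row["p_value"],
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)
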