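"""Synthetic two-wave adolescent cohort generator.

No subject-level data from the reference cohort is available, so this
module generates a cohort with the same statistical structure: covariate
margins (age, gender, school type, working memory, academic performance),
baseline smoking prevalence with the published gender and school-type
contrasts, rEV parameters drawn per baseline smoking group, an IGT session
simulated from each subject's true parameters, and a wave-2 smoking
outcome generated by a logistic model whose structural coefficients are
the published ones: a large positive effect of baseline smoking and a
negative effect of the attention weight ``w`` (loss-insensitive
adolescents are more likely to smoke a year later).

Intercepts are calibrated numerically so the marginal prevalences hit the
published 9.4% (wave 1) and 12.2% (wave 2). The generator is a pure
function of (config, seed); the wave-2 outcome conditions on the *true*
``w``, keeping generator truth separate from estimation noise.

The module also houses the parameter-recovery experiment that validates
the maximum-likelihood fitter against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from . import datasets
from .model import EVParameters, FitSettings, fit_subject, simulate_session
from .task import IGTSession


class SmokingLevelError(ValueError):
    """Unknown smoking-level questionnaire response."""


# Seven-option past-30-day smoking item; index = ordinal level 0..6.
SMOKING_LEVEL_OPTIONS = (
    "I did not smoke cigarettes during the past 30 days",
    "Less than 1 cigarette per day",
    "1 cigarette per day",
    "2-5 cigarettes per day",
    "6-10 cigarettes per day",
    "11-20 cigarettes per day",
    "More than 20 cigarettes per day",
)


def code_smoking_level(response: str) -> int:
    """Map a questionnaire response to its ordinal level 0-6.

    Level 0 means no past-30-day smoking (non-current smoker); any level
    above zero classifies the respondent as a current smoker. En-dash and
    hyphen range spellings are both accepted.
    """
    normalized = response.strip().replace("–", "-")
    for level, option in enumerate(SMOKING_LEVEL_OPTIONS):
        if normalized.lower() == option.lower():
            return level
    raise SmokingLevelError(f"unknown smoking-level response: {response!r}")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _truncnorm_dist(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def _truncnorm_ppf(u: float, mean: float, sd: float, lo: float, hi: float) -> float:
    """Inverse CDF of a truncated normal via the normal CDF directly; much
    cheaper than constructing a frozen scipy distribution per draw."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    fa, fb = ndtr(a), ndtr(b)
    return float(mean + sd * ndtri(fa + u * (fb - fa)))


class CohortConfig(BaseModel):
    """Generator configuration, calibrated to the published cohort margins.

    The gender and school coefficients on baseline smoking are the log
    odds ratios implied by the published composition tables (male OR 8.68,
    vocational OR 4.47); intercepts are solved at construction so the
    marginal prevalences match their targets.
    """

    n_subjects: int = Field(default=181, ge=1)
    seed: int = 0
    n_trials: int = Field(default=100, ge=1)
    theta_variant: str = "pow3"

    age_mean: float = datasets.AGE_MEAN
    age_sd: float = Field(default=datasets.AGE_SD, ge=0)
    p_male: float = Field(default=0.5, ge=0, le=1)
    p_vocational: float = Field(default=82 / 181, ge=0, le=1)
    wm_mean: float = datasets.WM_MEAN
    wm_sd: float = Field(default=datasets.WM_SD, ge=0)
    sap_probs: tuple[float, float, float, float, float] = (0.05, 0.10, 0.30, 0.35, 0.20)

    # Baseline smoking model: logit P = b0 + b_male*male + b_vocational*voc
    target_prevalence_t1: float = Field(default=datasets.PREVALENCE_T1, ge=0, le=1)
    b_male: float = math.log((15 / 76) / (2 / 88))
    b_vocational: float = math.log((13 / 69) / (4 / 95))

    # rEV parameter distributions (parent normal mean/sd, truncated to box).
    w_mean_nonsmoker: float = datasets.W_NONSMOKER[0]
    w_mean_smoker_t1: float = datasets.W_SMOKER_T1[0]
    w_sd: float = Field(default=datasets.W_NONSMOKER[1], ge=0)
    phi_mean: float = datasets.PHI_OVERALL[0]
    phi_sd: float = Field(default=datasets.PHI_OVERALL[1], ge=0)
    c_mean: float = datasets.C_OVERALL[0]
    c_sd: float = Field(default=datasets.C_OVERALL[1], ge=0)
    c_max: float = Field(default=5.0, gt=0)

    # Wave-2 outcome model: logit P = b0 + b_smoker_t1*s1 + b_w*w
    target_prevalence_t2: float = Field(default=datasets.PREVALENCE_T2, ge=0, le=1)
    b_smoker_t1: float = datasets.B_SMOKER_T1
    b_w: float = datasets.B_WEIGHT_W

    # Smoking-level (1..6) distributions conditional on being a smoker.
    level_probs_t1: tuple[float, ...] = tuple(np.array(datasets.LEVEL_COUNTS_T1) / 17)
    level_probs_t2: tuple[float, ...] = tuple(np.array(datasets.LEVEL_COUNTS_T2) / 22)

    @model_validator(mode="after")
    def _check_probs(self) -> "CohortConfig":
        for name in ("sap_probs", "level_probs_t1", "level_probs_t2"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
        return self

    # -- calibrated intercepts ---------------------------------------------

    def intercept_t1(self) -> float:
        """Solve the baseline-smoking intercept so the marginal prevalence
        over the gender x school cells equals the target."""
        cells = [
            (m, v, (self.p_male if m else 1 - self.p_male) * (self.p_vocational if v else 1 - self.p_vocational))
            for m in (0, 1)
            for v in (0, 1)
        ]

        def marginal(b0: float) -> float:
            return sum(
                p * _sigmoid(b0 + self.b_male * m + self.b_vocational * v)
                for m, v, p in cells
            ) - self.target_prevalence_t1

        return brentq(marginal, -30.0, 30.0, xtol=1e-12)

    def intercept_t2(self, n_quad: int = 512) -> float:
        """Solve the wave-2 intercept so the marginal prevalence matches the
        target, integrating over baseline status and the truncated-normal
        attention-weight distribution of each baseline group."""
        q = (np.arange(n_quad) + 0.5) / n_quad
        groups = [
            (0, 1 - self.target_prevalence_t1, _truncnorm_dist(self.w_mean_nonsmoker, self.w_sd, 0, 1).ppf(q)),
            (1, self.target_prevalence_t1, _truncnorm_dist(self.w_mean_smoker_t1, self.w_sd, 0, 1).ppf(q)),
        ]

        def marginal(b0: float) -> float:
            total = 0.0
            for s1, p_g, w_grid in groups:
                z = b0 + self.b_smoker_t1 * s1 + self.b_w * w_grid
                total += p_g * float(np.mean(1.0 / (1.0 + np.exp(-z))))
            return total - self.target_prevalence_t2

        return brentq(marginal, -30.0, 30.0, xtol=1e-12)


@dataclass
class SubjectRecord:
    """One synthetic subject: covariates, two-wave smoking outcomes, the
    generator's true rEV parameters and (optionally) a simulated session."""

    subject_id: str
    age: float
    gender: str  # "male" | "female"
    school_type: str  # "academic" | "vocational"
    wm_score: int
    sap: int
    smoker_t1: bool
    level_t1: int
    true_params: EVParameters
    smoker_t2: bool | None = None
    level_t2: int | None = None
    session: IGTSession | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.wm_score <= 72:
            raise ValueError("wm_score must lie in [0, 72]")
        if not 1 <= self.sap <= 5:
            raise ValueError("sap must lie in 1..5")
        if (self.level_t1 > 0) != self.smoker_t1:
            raise ValueError("level_t1 > 0 must hold exactly for wave-1 smokers")
        if self.smoker_t2 is not None and (self.level_t2 > 0) != self.smoker_t2:
            raise ValueError("level_t2 > 0 must hold exactly for wave-2 smokers")


@dataclass
class Cohort:
    """A generated cohort plus its configuration."""

    subjects: list[SubjectRecord]
    config: CohortConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age": s.age,
                    "gender": s.gender,
                    "male": int(s.gender == "male"),
                    "school_type": s.school_type,
                    "vocational": int(s.school_type == "vocational"),
                    "wm_score": s.wm_score,
                    "sap": s.sap,
                    "smoker_t1": int(s.smoker_t1),
                    "level_t1": s.level_t1,
                    "smoker_t2": int(s.smoker_t2) if s.smoker_t2 is not None else np.nan,
                    "level_t2": s.level_t2 if s.level_t2 is not None else np.nan,
                    "true_w": s.true_params.w,
                    "true_phi": s.true_params.phi,
                    "true_c": s.true_params.c,
                }
            )
        return pd.DataFrame(rows)

    def true_params_frame(self) -> pd.DataFrame:
        """True parameters shaped like a fit table (for oracle analyses)."""
        df = self.to_frame()[["subject_id", "true_w", "true_phi", "true_c"]]
        return df.rename(columns={"true_w": "w", "true_phi": "phi", "true_c": "c"})

    @property
    def sessions(self) -> list[IGTSession]:
        return [s.session for s in self.subjects if s.session is not None]


def sample_subject(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = "s1", b0_t1: float | None = None
) -> SubjectRecord:
    """Draw one subject's covariates, baseline smoking and true parameters.

    With all SDs at zero every subject sits exactly at the configured means
    (degenerate but valid). Draw order is fixed, so the subject stream is a
    pure function of the generator state.
    """
    if b0_t1 is None:
        b0_t1 = config.intercept_t1()
    age = config.age_mean + config.age_sd * rng.standard_normal()
    male = rng.random() < config.p_male
    vocational = rng.random() < config.p_vocational
    if config.wm_sd > 0:
        wm = _truncnorm_ppf(rng.random(), config.wm_mean, config.wm_sd, 0, 72)
    else:
        wm = config.wm_mean
    sap = 1 + int(rng.choice(5, p=np.asarray(config.sap_probs)))
    p_smoke = _sigmoid(b0_t1 + config.b_male * male + config.b_vocational * vocational)
    smoker_t1 = rng.random() < p_smoke
    level_t1 = 1 + int(rng.choice(6, p=np.asarray(config.level_probs_t1))) if smoker_t1 else 0

    w_mean = config.w_mean_smoker_t1 if smoker_t1 else config.w_mean_nonsmoker
    def draw(mean: float, sd: float, lo: float, hi: float) -> float:
        if sd == 0:
            return float(np.clip(mean, lo, hi))
        return _truncnorm_ppf(rng.random(), mean, sd, lo, hi)

    params = EVParameters(
        w=draw(w_mean, config.w_sd, 0, 1),
        phi=draw(config.phi_mean, config.phi_sd, 0, 1),
        c=draw(config.c_mean, config.c_sd, 0, config.c_max),
    )
    return SubjectRecord(
        subject_id=subject_id,
        age=float(age),
        gender="male" if male else "female",
        school_type="vocational" if vocational else "academic",
        wm_score=int(round(np.clip(wm, 0, 72))),
        sap=sap,
        smoker_t1=bool(smoker_t1),
        level_t1=level_t1,
        true_params=params,
    )


def assign_t2_smoking(
    record: SubjectRecord,
    config: CohortConfig,
    rng: np.random.Generator,
    b0_t2: float | None = None,
) -> SubjectRecord:
    """Draw the wave-2 outcome from the logistic model on baseline smoking
    and the subject's true attention weight, then a smoking level from the
    wave-2 level distribution if the subject smokes."""
    if b0_t2 is None:
        b0_t2 = config.intercept_t2()
    z = b0_t2 + config.b_smoker_t1 * record.smoker_t1 + config.b_w * record.true_params.w
    smoker_t2 = bool(rng.random() < _sigmoid(z))
    level_t2 = 1 + int(rng.choice(6, p=np.asarray(config.level_probs_t2))) if smoker_t2 else 0
    record.smoker_t2 = smoker_t2
    record.level_t2 = level_t2
    return record


def generate_cohort(config: CohortConfig, with_sessions: bool = True) -> Cohort:
    """Generate the full cohort; reproducible byte-for-byte from the seed.

    Subject covariates/outcomes and session simulation use independent
    spawned RNG streams, so disabling sessions (for analyses that only
    need true parameters) leaves the subject stream unchanged.
    """
    ss = np.random.SeedSequence(config.seed)
    subj_seq, sess_seq = ss.spawn(2)
    rng_subj = np.random.default_rng(subj_seq)
    rng_sess = np.random.default_rng(sess_seq)
    b0_t1 = config.intercept_t1()
    b0_t2 = config.intercept_t2()
    width = len(str(config.n_subjects))
    subjects = []
    for i in range(config.n_subjects):
        rec = sample_subject(config, rng_subj, subject_id=f"S{i + 1:0{width}d}", b0_t1=b0_t1)
        rec = assign_t2_smoking(rec, config, rng_subj, b0_t2=b0_t2)
        if with_sessions:
            rec.session = simulate_session(
                rec.true_params,
                n_trials=config.n_trials,
                seed=rng_sess,
                theta_variant=config.theta_variant,
                subject_id=rec.subject_id,
            )
        subjects.append(rec)
    return Cohort(subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """True-versus-recovered parameters over simulated agents."""

    true: pd.DataFrame
    estimated: pd.DataFrame
    n_trials: int

    def metrics(self) -> pd.DataFrame:
        """Pearson and rank correlation, bias and RMSE per parameter."""
        rows = []
        for p in ("w", "phi", "c"):
            t = self.true[p].to_numpy()
            e = self.estimated[p].to_numpy()
            pearson = float(np.corrcoef(t, e)[0, 1]) if np.std(e) > 0 else 0.0
            rank = float(pd.Series(t).corr(pd.Series(e), method="spearman")) if np.std(e) > 0 else 0.0
            rows.append(
                {
                    "parameter": p,
                    "pearson_r": pearson,
                    "spearman_rho": rank,
                    "bias": float(np.mean(e - t)),
                    "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def recovery_experiment(
    n_agents: int,
    n_trials: int = 100,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> RecoveryReport:
    """Simulate agents with parameters drawn uniformly over the box,
    refit each session by maximum likelihood, and report recovery quality."""
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    settings = settings or FitSettings()
    # separate streams: the agent population is identical across horizons
    # for a given seed, so recovery-vs-T comparisons hold agents fixed
    par_seq, sess_seq = np.random.SeedSequence(seed).spawn(2)
    rng_par = np.random.default_rng(par_seq)
    rng_sess = np.random.default_rng(sess_seq)
    true_rows, est_rows = [], []
    for i in range(n_agents):
        params = EVParameters(
            w=float(rng_par.random()),
            phi=float(rng_par.random()),
            c=float(rng_par.random() * settings.c_max),
        )
        session = simulate_session(
            params, n_trials=n_trials, seed=rng_sess,
            theta_variant=settings.theta_variant, subject_id=f"agent{i}",
        )
        fit = fit_subject(session, settings)
        true_rows.append({"subject_id": session.subject_id, "w": params.w, "phi": params.phi, "c": params.c})
        est_rows.append(
            {"subject_id": session.subject_id, "w": fit.params.w, "phi": fit.params.phi, "c": fit.params.c}
        )
    return RecoveryReport(
        true=pd.DataFrame(true_rows), estimated=pd.DataFrame(est_rows), n_trials=n_trials
    )
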