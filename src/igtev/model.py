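"""The revised expectancy-valence (rEV) model of IGT choice behavior.

The model decomposes trial-by-trial deck choices into three psychological
components, each an estimated parameter:

* ``w`` — attention weight to gains versus losses. The subjective value
  (valence) of a card is ``v(t) = w*win(t) - (1-w)*loss(t)`` with
  ``0 <= w <= 1``; low ``w`` means losses dominate the evaluation.
* ``phi`` — recency (learning rate). Each deck carries an expectancy
  ``E_j(t)`` updated after choosing it: ``E_j(t) = E_j(t-1) +
  phi*[v(t) - E_j(t-1)]``; high ``phi`` makes recent outcomes dominate.
* ``c`` — choice consistency. Choice probabilities follow the softmax /
  Luce strength-ratio rule ``p_j = exp(theta*E_j) / sum_k exp(theta*E_k)``
  where the sensitivity ``theta`` grows with ``c`` (``theta = 3**c - 1`` by
  default; a trial-dependent variant ``theta(t) = (t/10)**c`` is
  selectable). ``c = 0`` gives uniform random choice.

Model adequacy is judged against a static baseline that predicts every
choice from the subject's overall choice proportions, via a BIC statistic
on the log-likelihood difference; positive values favor the learning model.

The user-facing entry point follows the statsmodels convention: build
:class:`ExpectancyValenceModel` from a session, call :meth:`~ExpectancyValenceModel.fit`,
inspect the returned :class:`EVFit` (and its ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import minimize

from . import _likelihood as _lk
from .task import (
    DECK_LABELS,
    CardOutcome,
    DeckSchedule,
    IGTSession,
    Trial,
    build_standard_decks,
)

THETA_VARIANTS = {"pow3": _lk.THETA_POW3, "trial_pow": _lk.THETA_TRIAL_POW}


class InvalidParameterError(ValueError):
    """A model parameter lies outside its admissible range."""


class ThetaVariantError(ValueError):
    """Unknown sensitivity-formula selector."""


@dataclass(frozen=True)
class EVParameters:
    """The rEV parameter triple (w, phi, c)."""

    w: float
    phi: float
    c: float

    def validate(self, c_max: float = 5.0) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise InvalidParameterError(f"w must be in [0, 1], got {self.w}")
        if not 0.0 <= self.phi <= 1.0:
            raise InvalidParameterError(f"phi must be in [0, 1], got {self.phi}")
        if not 0.0 <= self.c <= c_max:
            raise InvalidParameterError(f"c must be in [0, {c_max}], got {self.c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.phi, self.c])


@dataclass
class ExpectancyState:
    """Per-deck expectancy scores after processing trials 1..t."""

    E: dict[str, float]
    t: int = 0

    def __post_init__(self) -> None:
        if set(self.E) != set(DECK_LABELS):
            raise ValueError(f"expectancy state needs exactly the decks {DECK_LABELS}")
        if not all(math.isfinite(v) for v in self.E.values()):
            raise ValueError("expectancies must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.E[d] for d in DECK_LABELS])


class FitSettings(BaseModel):
    """Controls for maximum-likelihood fitting.

    ``n_grid`` starts per parameter define an ``n_grid**3`` lattice of
    starting points; the ``n_refine`` most promising are refined by bounded
    derivative-free local search. ``prob_floor`` bounds probabilities away
    from zero inside logs so the likelihood surface stays finite for
    extreme sensitivities.
    """

    n_grid: int = Field(default=4, ge=1)
    n_refine: int = Field(default=6, ge=1)
    tol: float = Field(default=1e-6, gt=0)
    prob_floor: float = Field(default=1e-10, gt=0)
    theta_variant: str = "pow3"
    c_max: float = Field(default=5.0, gt=0, le=10.0)
    seed: int = 0

    def variant_code(self) -> int:
        try:
            return THETA_VARIANTS[self.theta_variant]
        except KeyError:
            raise ThetaVariantError(
                f"unknown theta_variant {self.theta_variant!r}; choose from {sorted(THETA_VARIANTS)}"
            ) from None


@dataclass
class EVFit:
    """Result of fitting the rEV model to one session.

    Carries the maximum-likelihood parameters, the model and baseline
    log-likelihoods, and the BIC statistic of their comparison (positive
    means the learning model beats the static baseline).
    """

    params: EVParameters
    loglik_model: float
    loglik_baseline: float
    bic_stat: float
    n_starts: int
    converged: bool
    subject_id: str = ""

    def summary(self) -> str:
        lines = [
            "Expectancy-Valence Model Fit" + (f" — subject {self.subject_id}" if self.subject_id else ""),
            "=" * 46,
            f"{'attention weight w':<28}{self.params.w:>12.4f}",
            f"{'recency phi':<28}{self.params.phi:>12.4f}",
            f"{'consistency c':<28}{self.params.c:>12.4f}",
            "-" * 46,
            f"{'log-likelihood (model)':<28}{self.loglik_model:>12.3f}",
            f"{'log-likelihood (baseline)':<28}{self.loglik_baseline:>12.3f}",
            f"{'BIC statistic':<28}{self.bic_stat:>12.3f}",
            f"{'optimizer starts':<28}{self.n_starts:>12d}",
            f"{'converged':<28}{str(self.converged):>12}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model primitives
# ---------------------------------------------------------------------------

def valence(outcome: CardOutcome, w: float) -> float:
    """Subjective value of a card: ``w*win - (1-w)*loss`` (loss a magnitude)."""
    if not 0.0 <= w <= 1.0:
        raise InvalidParameterError(f"w must be in [0, 1], got {w}")
    return w * outcome.win - (1.0 - w) * outcome.loss


def update_expectancy(e_prev: float, v: float, phi: float) -> float:
    """Delta-rule update toward the new valence: convex combination of the two."""
    if not 0.0 <= phi <= 1.0:
        raise InvalidParameterError(f"phi must be in [0, 1], got {phi}")
    return e_prev + phi * (v - e_prev)


def sensitivity_theta(c: float, t: int = 1, variant: str = "pow3") -> float:
    """Sensitivity of the choice rule as a function of consistency ``c``.

    ``pow3`` (default): ``theta = 3**c - 1``, independent of trial.
    ``trial_pow``: ``theta(t) = (t/10)**c``, growing over the session.
    Both are nondecreasing in ``c`` and give uniform choice at ``c = 0``
    (for ``trial_pow``, sensitivity 1 at every trial scales expectancies
    directly).
    """
    if c < 0:
        raise InvalidParameterError(f"c must be non-negative, got {c}")
    if variant not in THETA_VARIANTS:
        raise ThetaVariantError(
            f"unknown theta_variant {variant!r}; choose from {sorted(THETA_VARIANTS)}"
        )
    return _lk._theta(c, t, THETA_VARIANTS[variant])


def choice_probabilities(state: ExpectancyState | np.ndarray, theta: float) -> np.ndarray:
    """Luce / softmax choice probabilities over the four decks.

    Computed with max-subtraction so extreme ``theta * E`` never overflows;
    the result always sums to one.
    """
    if theta < 0:
        raise InvalidParameterError(f"theta must be non-negative, got {theta}")
    E = state.as_array() if isinstance(state, ExpectancyState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("expectancies must be finite")
    z = theta * E
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def session_log_likelihood(
    session: IGTSession,
    params: EVParameters,
    settings: FitSettings | None = None,
) -> float:
    """One-step-ahead log-likelihood of a session under the rEV model.

    All expectancies start at zero, so the first choice is uniform (log 1/4).
    Each trial contributes the log-probability of the chosen deck given the
    history, then the chosen deck's expectancy absorbs the trial valence.
    """
    settings = settings or FitSettings()
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    params.validate(c_max=max(settings.c_max, params.c))
    chosen, win, loss = session.to_arrays()
    return -_lk.negative_log_likelihood(
        params.w, params.phi, params.c, chosen, win, loss,
        settings.variant_code(), settings.prob_floor,
    )


def baseline_log_likelihood(session: IGTSession) -> float:
    """Log-likelihood of the static baseline predicting mean choice proportions.

    With per-deck counts ``n_j`` over ``T`` trials the maximized value is
    ``sum_j n_j * log(n_j / T)``; decks never chosen contribute nothing.
    """
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    chosen, _, _ = session.to_arrays()
    counts = np.bincount(chosen, minlength=4).astype(float)
    T = counts.sum()
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log(counts[nz] / T)))


def bic_statistic(
    loglik_model: float,
    loglik_baseline: float,
    k_model: int = 3,
    k_baseline: int = 3,
    n: int = 100,
) -> float:
    """BIC statistic for the model-vs-baseline comparison.

    ``2*(ll_model - ll_baseline) - (k_model - k_baseline)*ln(n)``; with the
    default equal parameter counts (three free proportions in the baseline)
    the penalty cancels and the statistic is twice the log-likelihood
    difference. Positive values favor the learning model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * (loglik_model - loglik_baseline) - (k_model - k_baseline) * math.log(n)


# ---------------------------------------------------------------------------
# Fitting and simulation
# ---------------------------------------------------------------------------

def _start_lattice(settings: FitSettings) -> np.ndarray:
    """Interior lattice of starting points over the parameter box, with a
    small seed-controlled jitter so restarts from different seeds probe
    slightly different basins while remaining deterministic."""
    g = settings.n_grid
    frac = (np.arange(g) + 0.5) / g
    rng = np.random.default_rng(settings.seed)
    starts = []
    for fw in frac:
        for fp in frac:
            for fc in frac:
                starts.append((fw, fp * 1.0, fc * settings.c_max))
    starts = np.array(starts)
    jitter = rng.uniform(-0.25, 0.25, size=starts.shape) / g
    jitter[:, 2] *= settings.c_max
    starts += jitter
    starts[:, 0] = np.clip(starts[:, 0], 0.0, 1.0)
    starts[:, 1] = np.clip(starts[:, 1], 0.0, 1.0)
    starts[:, 2] = np.clip(starts[:, 2], 0.0, settings.c_max)
    return starts


def fit_subject(session: IGTSession, settings: FitSettings | None = None) -> EVFit:
    """Maximum-likelihood rEV fit for one session by screened multi-start.

    Every lattice point is scored; bounded Nelder-Mead search refines the
    ``n_refine`` best. Ties within ``tol`` break toward lexicographically
    smaller (w, phi, c). Deterministic given ``settings.seed``.
    """
    settings = settings or FitSettings()
    if session.n_trials < 10:
        raise ValueError("fitting requires at least 10 trials")
    chosen, win, loss = session.to_arrays()
    variant = settings.variant_code()
    floor = settings.prob_floor

    def nll(x: np.ndarray) -> float:
        return _lk.negative_log_likelihood(
            x[0], x[1], x[2], chosen, win, loss, variant, floor
        )

    starts = _start_lattice(settings)
    scores = np.array([nll(s) for s in starts])
    order = np.argsort(scores, kind="stable")
    refine = starts[order[: settings.n_refine]]

    bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, settings.c_max)]
    candidates = []
    any_converged = False
    for x0 in refine:
        res = minimize(
            nll, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": settings.tol, "fatol": settings.tol, "maxiter": 400},
        )
        x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        candidates.append((float(nll(x)), tuple(x)))
        any_converged = any_converged or bool(res.success)

    best_fun = min(f for f, _ in candidates)
    in_tol = [x for f, x in candidates if f <= best_fun + settings.tol]
    w, phi, c = min(in_tol)
    ll_model = -nll(np.array([w, phi, c]))
    ll_base = baseline_log_likelihood(session)
    return EVFit(
        params=EVParameters(w=w, phi=phi, c=c),
        loglik_model=ll_model,
        loglik_baseline=ll_base,
        bic_stat=bic_statistic(ll_model, ll_base, n=session.n_trials),
        n_starts=len(starts),
        converged=any_converged,
        subject_id=session.subject_id,
    )


def simulate_session(
    params: EVParameters,
    decks: Mapping[str, DeckSchedule] | None = None,
    n_trials: int = 100,
    seed: int | np.random.Generator = 0,
    theta_variant: str = "pow3",
    subject_id: str = "sim",
) -> IGTSession:
    """Generate a session from the rEV model acting on the deck schedules.

    Each choice is sampled from the current choice probabilities; the card
    outcome comes from the chosen deck's schedule at that deck's next draw
    position. Reproducible given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params.validate(c_max=max(5.0, params.c))
    if decks is None:
        decks = build_standard_decks()
    if theta_variant not in THETA_VARIANTS:
        raise ThetaVariantError(f"unknown theta_variant {theta_variant!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gains = np.array([decks[d].gain_per_card for d in DECK_LABELS])
    cycles = np.array([decks[d].loss_cycle for d in DECK_LABELS])
    uniforms = rng.random(n_trials)
    chosen, win, loss = _lk.simulate_choices(
        params.w, params.phi, params.c, n_trials, gains, cycles, uniforms,
        THETA_VARIANTS[theta_variant],
    )
    trials = [
        Trial(t=t + 1, deck=DECK_LABELS[chosen[t]], outcome=CardOutcome(win=win[t], loss=loss[t]))
        for t in range(n_trials)
    ]
    return IGTSession(subject_id=subject_id, trials=trials)


class ExpectancyValenceModel:
    """statsmodels-style wrapper: a model bound to one subject's session.

    Examples
    --------
    >>> from igtev.model import ExpectancyValenceModel, EVParameters, simulate_session
    >>> session = simulate_session(EVParameters(w=0.3, phi=0.2, c=2.0), seed=7)
    >>> fit = ExpectancyValenceModel(session).fit()
    >>> print(fit.summary())           # doctest: +SKIP
    """

    def __init__(self, session: IGTSession, settings: FitSettings | None = None):
        self.session = session
        self.settings = settings or FitSettings()

    def loglike(self, params: EVParameters) -> float:
        return session_log_likelihood(self.session, params, self.settings)

    def baseline_loglike(self) -> float:
        return baseline_log_likelihood(self.session)

    def fit(self) -> EVFit:
        return fit_subject(self.session, self.settings)

    @staticmethod
    def simulate(
        params: EVParameters,
        decks: Mapping[str, DeckSchedule] | None = None,
        n_trials: int = 100,
        seed: int | np.random.Generator = 0,
        theta_variant: str = "pow3",
        subject_id: str = "sim",
    ) -> IGTSession:
        return simulate_session(params, decks, n_trials, seed, theta_variant, subject_id)
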