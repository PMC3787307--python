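"""Shared fixtures and the independent brute-force likelihood oracle."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings as hyp_settings

from igtev.task import (
    CardOutcome,
    IGTSession,
    Trial,
    build_standard_decks,
    session_from_deck_sequence,
)

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def decks():
    return build_standard_decks()


@pytest.fixture
def constant_session():
    """Factory: a session of n draws from one deck, outcomes from the payoff engine."""

    def make(deck: str, n: int, subject_id: str = "const") -> IGTSession:
        return session_from_deck_sequence(subject_id, [deck] * n)

    return make


@pytest.fixture
def sequence_session():
    """Factory: a session replaying an arbitrary deck-label sequence."""

    def make(seq, subject_id: str = "seq") -> IGTSession:
        return session_from_deck_sequence(subject_id, list(seq))

    return make


def oracle_log_likelihood(
    session: IGTSession,
    w: float,
    phi: float,
    c: float,
    variant: str = "pow3",
    prob_floor: float = 1e-10,
) -> float:
    """Straight-line per-trial enumeration of the rEV likelihood.

    Written directly from the three defining equations, independently of
    the package's vectorized kernel: the valence is a weighted average of
    win and loss, the chosen deck's expectancy moves a fraction ``phi``
    toward the valence, and each choice probability is the Luce strength
    ratio 1 / sum_k exp(theta * (E_k - E_chosen)). Probabilities are
    floored before taking logs, exactly as the likelihood is defined.
    """
    E = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0}
    total = 0.0
    for trial in session.trials:
        theta = (3.0**c - 1.0) if variant == "pow3" else (trial.t / 10.0) ** c
        denom = 0.0
        for deck in E:
            try:
                denom += math.exp(theta * (E[deck] - E[trial.deck]))
            except OverflowError:
                denom = math.inf
        p = 0.0 if math.isinf(denom) else 1.0 / denom
        total += math.log(max(p, prob_floor))
        v = w * trial.outcome.win - (1.0 - w) * trial.outcome.loss
        E[trial.deck] = E[trial.deck] + phi * (v - E[trial.deck])
    return total


@pytest.fixture
def make_trial():
    def make(t: int, deck: str, win: float, loss: float) -> Trial:
        return Trial(t=t, deck=deck, outcome=CardOutcome(win=win, loss=loss))

    return make
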