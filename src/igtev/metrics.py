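"""Descriptive IGT performance measures.

The net score over a trial range is (choices from C + D) minus (choices
from A + B): positive values mean advantageous choosing. The session is
conventionally split at trial 40 — early trials probe decision-making
under ambiguity (contingencies unknown), later trials decision-making
under risk (contingencies learned) — so the default blocks are 1-40 and
41-100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .task import DECK_LABELS, IGTSession

DEFAULT_BLOCKS: tuple[tuple[int, int], ...] = ((1, 40), (41, 100))

ADVANTAGEOUS = ("C", "D")
DISADVANTAGEOUS = ("A", "B")


@dataclass(frozen=True)
class DeckCounts:
    """Per-deck selection counts over a trial range."""

    counts: dict[str, int]
    trial_range: tuple[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BlockScores:
    """Net scores for a list of trial ranges partitioning the session."""

    ranges: tuple[tuple[int, int], ...]
    net: tuple[int, ...]


def _check_range(session: IGTSession, trial_range: tuple[int, int] | None) -> tuple[int, int]:
    lo, hi = trial_range if trial_range is not None else (1, session.n_trials)
    if lo > hi:
        raise ValueError(f"empty trial range ({lo}, {hi})")
    if lo < 1 or hi > session.n_trials:
        raise ValueError(f"range ({lo}, {hi}) outside trials 1..{session.n_trials}")
    return lo, hi


def deck_counts(session: IGTSession, trial_range: tuple[int, int] | None = None) -> DeckCounts:
    """Exact selection counts per deck within a (1-based, inclusive) range."""
    lo, hi = _check_range(session, trial_range)
    counts = {d: 0 for d in DECK_LABELS}
    for tr in session.trials[lo - 1 : hi]:
        counts[tr.deck] += 1
    return DeckCounts(counts=counts, trial_range=(lo, hi))


def net_score(session: IGTSession, trial_range: tuple[int, int] | None = None) -> int:
    """(n_C + n_D) - (n_A + n_B) over the range; positive = advantageous."""
    dc = deck_counts(session, trial_range).counts
    return sum(dc[d] for d in ADVANTAGEOUS) - sum(dc[d] for d in DISADVANTAGEOUS)


def block_net_scores(
    session: IGTSession, blocks: Sequence[tuple[int, int]] = DEFAULT_BLOCKS
) -> BlockScores:
    """Net score per block; the blocks must partition 1..T without overlap."""
    covered: set[int] = set()
    for lo, hi in blocks:
        rng = set(range(lo, hi + 1))
        if covered & rng:
            raise ValueError(f"block ({lo}, {hi}) overlaps a previous block")
        covered |= rng
    if covered != set(range(1, session.n_trials + 1)):
        raise ValueError("blocks must partition trials 1..n_trials")
    return BlockScores(
        ranges=tuple(tuple(b) for b in blocks),
        net=tuple(net_score(session, b) for b in blocks),
    )


def default_blocks(n_trials: int) -> tuple[tuple[int, int], ...]:
    """Ambiguity/risk split at 40% of the session (trial 40 of 100)."""
    if n_trials < 2:
        return ((1, n_trials),)
    cut = max(1, min(n_trials - 1, round(0.4 * n_trials)))
    return ((1, cut), (cut + 1, n_trials))


def metrics_table(
    sessions: Sequence[IGTSession], blocks: Sequence[tuple[int, int]] | None = None
) -> pd.DataFrame:
    """One row per subject: deck counts, overall net score, per-block net
    scores. With ``blocks=None`` each session is split at 40% of its length."""
    rows = []
    for s in sessions:
        dc = deck_counts(s).counts
        bs = block_net_scores(s, blocks if blocks is not None else default_blocks(s.n_trials))
        row = {"subject_id": s.subject_id}
        row.update({f"n_{d}": dc[d] for d in DECK_LABELS})
        row["net_total"] = net_score(s)
        for (lo, hi), v in zip(bs.ranges, bs.net):
            row[f"net_{lo}_{hi}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
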