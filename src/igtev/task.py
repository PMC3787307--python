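"""Iowa Gambling Task payoff engine.

The IGT presents four decks of cards (A, B, C, D). Every card from a deck
pays a fixed immediate gain ($100 for A and B, $50 for C and D) and,
depending on the draw position within the deck, an unpredictable loss.
Losses follow a fixed 10-card cycle: decks A and B lose $1250 per 10 cards
(net -$250, disadvantageous) while C and D lose $250 per 10 cards
(net +$250, advantageous). A and C spread their losses over five smaller
punishments per cycle; B and D concentrate them in a single large one.

This module is fully deterministic: given a deck and a draw position it
returns the exact card outcome. All money amounts are task dollars; losses
are stored as positive magnitudes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DECK_LABELS = ("A", "B", "C", "D")
DECK_INDEX = {label: i for i, label in enumerate(DECK_LABELS)}

CYCLE_LENGTH = 10
DEFAULT_STARTING_CASH = 2000.0


class InvalidPositionError(ValueError):
    """Raised when a draw position is not a positive integer."""


class SessionFormatError(ValueError):
    """Raised when serialized session data violates the session schema."""


@dataclass(frozen=True)
class DeckSchedule:
    """Payoff program of one deck: fixed gain per card, cyclic loss schedule.

    Parameters
    ----------
    label : str
        Deck identifier, one of ``A, B, C, D``.
    gain_per_card : float
        Immediate reward paid by every card of this deck (>= 0).
    loss_cycle : tuple of float
        Length-10 sequence of loss magnitudes (>= 0) applied cyclically by
        within-deck draw position.
    """

    label: str
    gain_per_card: float
    loss_cycle: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in DECK_LABELS:
            raise ValueError(f"deck label must be one of {DECK_LABELS}, got {self.label!r}")
        if self.gain_per_card < 0:
            raise ValueError("gain_per_card must be non-negative")
        if len(self.loss_cycle) != CYCLE_LENGTH:
            raise ValueError(f"loss_cycle must have exactly {CYCLE_LENGTH} entries")
        if any(x < 0 for x in self.loss_cycle):
            raise ValueError("loss magnitudes must be non-negative")

    @property
    def total_loss_per_cycle(self) -> float:
        return float(sum(self.loss_cycle))

    @property
    def net_per_cycle(self) -> float:
        """Net outcome of one full 10-card cycle: -250 for A/B, +250 for C/D."""
        return CYCLE_LENGTH * self.gain_per_card - self.total_loss_per_cycle


@dataclass(frozen=True)
class CardOutcome:
    """Monetary result of turning one card: a win and a loss magnitude."""

    win: float
    loss: float

    def __post_init__(self) -> None:
        if self.win < 0 or self.loss < 0:
            raise ValueError("win and loss must be non-negative magnitudes")

    @property
    def net(self) -> float:
        return self.win - self.loss


@dataclass(frozen=True)
class Trial:
    """One choice in a session: 1-based trial index, deck, and card outcome."""

    t: int
    deck: str
    outcome: CardOutcome


@dataclass
class IGTSession:
    """One subject's ordered sequence of IGT trials.

    Trial indices must run 1..n without gaps and every deck must be one of
    A/B/C/D; both are validated on construction.
    """

    subject_id: str
    trials: list[Trial] = field(default_factory=list)
    starting_cash: float = DEFAULT_STARTING_CASH

    def __post_init__(self) -> None:
        for i, trial in enumerate(self.trials, start=1):
            if trial.t != i:
                raise SessionFormatError(
                    f"subject {self.subject_id}: trial indices must be 1..n "
                    f"without gaps (expected {i}, got {trial.t})"
                )
            if trial.deck not in DECK_LABELS:
                raise SessionFormatError(
                    f"subject {self.subject_id}, trial {trial.t}: unknown deck "
                    f"{trial.deck!r}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_arrays(self):
        """Return (chosen deck indices, wins, losses) as float/int arrays."""
        import numpy as np

        chosen = np.array([DECK_INDEX[tr.deck] for tr in self.trials], dtype=np.int64)
        win = np.array([tr.outcome.win for tr in self.trials], dtype=np.float64)
        loss = np.array([tr.outcome.loss for tr in self.trials], dtype=np.float64)
        return chosen, win, loss


# Canonical ABCD loss program. Positions are 1-based within each 10-card
# cycle; magnitudes satisfy the published sums (1250 for A/B, 250 for C/D)
# and frequencies (5 punishments per cycle for A/C, 1 for B/D).
_STANDARD_PROGRAM: dict[str, tuple[float, dict[int, float]]] = {
    "A": (100.0, {3: 150.0, 5: 300.0, 7: 200.0, 9: 250.0, 10: 350.0}),
    "B": (100.0, {9: 1250.0}),
    "C": (50.0, {3: 50.0, 5: 50.0, 7: 50.0, 9: 50.0, 10: 50.0}),
    "D": (50.0, {10: 250.0}),
}


def build_standard_decks() -> dict[str, DeckSchedule]:
    """Construct the four standard deck schedules.

    Deterministic: every call returns the same program. Decks A/B pay $100
    per card and lose $1250 per 10-card cycle; C/D pay $50 and lose $250.
    """
    decks = {}
    for label, (gain, losses) in _STANDARD_PROGRAM.items():
        cycle = tuple(losses.get(pos, 0.0) for pos in range(1, CYCLE_LENGTH + 1))
        decks[label] = DeckSchedule(label=label, gain_per_card=gain, loss_cycle=cycle)
    return decks


def card_outcome(schedule: DeckSchedule, draw_position: int) -> CardOutcome:
    """Outcome of drawing the card at a 1-based position from a deck.

    ``draw_position`` counts prior draws from this deck plus one; the loss
    schedule repeats every 10 draws.
    """
    if draw_position < 1 or int(draw_position) != draw_position:
        raise InvalidPositionError(f"draw_position must be a positive integer, got {draw_position}")
    loss = schedule.loss_cycle[(int(draw_position) - 1) % CYCLE_LENGTH]
    return CardOutcome(win=schedule.gain_per_card, loss=loss)


def session_net_cash(session: IGTSession) -> float:
    """Final account balance: starting cash plus the sum of net outcomes."""
    return session.starting_cash + sum(tr.outcome.net for tr in session.trials)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def decks_to_json(decks: Mapping[str, DeckSchedule], path: str | Path) -> None:
    """Write deck programs as JSON: {label: {gain: .., losses: [10 values]}}."""
    payload = {
        label: {"gain": d.gain_per_card, "losses": list(d.loss_cycle)}
        for label, d in sorted(decks.items())
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def decks_from_json(path: str | Path) -> dict[str, DeckSchedule]:
    """Load deck programs from JSON; any program meeting the invariants loads."""
    payload = json.loads(Path(path).read_text())
    return {
        label: DeckSchedule(
            label=label,
            gain_per_card=float(entry["gain"]),
            loss_cycle=tuple(float(x) for x in entry["losses"]),
        )
        for label, entry in payload.items()
    }


SESSION_CSV_COLUMNS = ["subject_id", "trial", "deck", "win", "loss"]


def write_sessions_csv(sessions: Iterable[IGTSession], path: str | Path) -> None:
    """Write sessions as delimited text with one row per trial."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_CSV_COLUMNS)
        for session in sessions:
            for tr in session.trials:
                writer.writerow(
                    [session.subject_id, tr.t, tr.deck, f"{tr.outcome.win:g}", f"{tr.outcome.loss:g}"]
                )


def read_sessions_csv(path: str | Path) -> list[IGTSession]:
    """Read and validate sessions from the CSV schema.

    Rows for a subject must be contiguous with strictly consecutive trial
    indices starting at 1. Malformed rows raise :class:`SessionFormatError`
    naming the offending line.
    """
    sessions: list[IGTSession] = []
    current_id: str | None = None
    trials: list[Trial] = []

    def flush() -> None:
        nonlocal trials, current_id
        if current_id is not None:
            sessions.append(IGTSession(subject_id=current_id, trials=trials))
        trials = []

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SESSION_CSV_COLUMNS:
            raise SessionFormatError(
                f"{path}: line 1: expected header {SESSION_CSV_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise SessionFormatError(f"{path}: line {lineno}: expected 5 columns, got {len(row)}")
            sid, t_raw, deck, win_raw, loss_raw = row
            try:
                t = int(t_raw)
                win = float(win_raw)
                loss = float(loss_raw)
            except ValueError as exc:
                raise SessionFormatError(f"{path}: line {lineno}: {exc}") from None
            if deck not in DECK_LABELS:
                raise SessionFormatError(
                    f"{path}: line {lineno}, column 'deck': unknown deck {deck!r}"
                )
            if sid != current_id:
                if sid in {s.subject_id for s in sessions}:
                    raise SessionFormatError(
                        f"{path}: line {lineno}: rows for subject {sid!r} are not contiguous"
                    )
                flush()
                current_id = sid
            expected_t = len(trials) + 1
            if t != expected_t:
                raise SessionFormatError(
                    f"{path}: line {lineno}, column 'trial': expected trial {expected_t} "
                    f"for subject {sid!r}, got {t} (gap or reorder)"
                )
            trials.append(Trial(t=t, deck=deck, outcome=CardOutcome(win=win, loss=loss)))
        flush()
    return sessions


def session_from_deck_sequence(
    subject_id: str,
    deck_sequence: Sequence[str],
    decks: Mapping[str, DeckSchedule] | None = None,
    starting_cash: float = DEFAULT_STARTING_CASH,
) -> IGTSession:
    """Build a session by replaying a deck-choice sequence through the payoff engine."""
    if decks is None:
        decks = build_standard_decks()
    positions = {label: 0 for label in DECK_LABELS}
    trials = []
    for t, deck in enumerate(deck_sequence, start=1):
        positions[deck] += 1
        trials.append(Trial(t=t, deck=deck, outcome=card_outcome(decks[deck], positions[deck])))
    return IGTSession(subject_id=subject_id, trials=trials, starting_cash=starting_cash)
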