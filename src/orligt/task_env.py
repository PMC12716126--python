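"""Iowa Gambling Task deck payoff structure.

The task presents four decks (A, B, C, D). Every draw pays a fixed gain
and, on some positions within a repeating cycle, also a loss. Decks A and
B pay large gains but lose money over a full cycle; C and D pay modest
gains but come out ahead. B and D deliver a loss on only one position in
ten (they "win" on 90% of draws), while A and C lose on five of ten.

The canonical monetary magnitudes (Bechara-style: 100/50 gains, 1250/250
cycle losses) are the default; every magnitude is configurable via
:class:`PayoffSchedule`, and schedules round-trip through a plain YAML
format (see :func:`load_schedule` / :func:`save_schedule`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

DECKS = ("A", "B", "C", "D")
#: Deck letter -> 1-based index used throughout the package.
DECK_INDEX = {"A": 1, "B": 2, "C": 3, "D": 4}
#: Decks with positive net outcome per cycle under the classic schedule.
WINNING_DECKS = frozenset({"C", "D"})


class InvalidDeckError(ValueError):
    """Raised when a deck identifier is not one of A, B, C, D (or 1..4)."""


@dataclass(frozen=True)
class DeckPayoff:
    """Payoff rule for one deck: a constant gain plus a cyclic loss list."""

    gain_per_draw: float
    loss_events: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loss_events", tuple(float(x) for x in self.loss_events))

    @property
    def cycle_length(self) -> int:
        return len(self.loss_events)

    @property
    def net_per_cycle(self) -> float:
        return self.gain_per_draw * self.cycle_length - sum(self.loss_events)

    @property
    def zero_loss_fraction(self) -> float:
        return sum(1 for x in self.loss_events if x == 0) / self.cycle_length


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-deck payoff structure of the task.

    ``decks`` maps deck letters to :class:`DeckPayoff`. Losses are delivered
    on fixed positions within each cycle (deterministic dialect); see
    :func:`shuffle_within_cycle` for the randomized-position dialect.
    """

    decks: Mapping[str, DeckPayoff] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "decks", dict(self.decks))


@dataclass(frozen=True)
class TrialOutcome:
    """One draw's monetary result; ``net`` is always ``gain - loss``."""

    gain: float
    loss: float

    @property
    def net(self) -> float:
        return self.gain - self.loss


def make_classic_schedule() -> PayoffSchedule:
    """Return the default schedule with canonical magnitudes.

    A: +100 per draw, five losses per 10-draw cycle totalling 1250 (net -250).
    B: +100 per draw, one loss of 1250 per cycle (net -250).
    C: +50 per draw, five losses totalling 250 (net +250).
    D: +50 per draw, one loss of 250 per cycle (net +250).
    """
    zero5 = [0.0] * 5
    return PayoffSchedule(
        decks={
            # loss positions follow the original card order: A spreads its
            # penalties over positions 3,5,7,9,10; B and D concentrate theirs
            # on position 9 / 10.
            "A": DeckPayoff(100.0, (0, 0, 150, 0, 300, 0, 200, 0, 250, 350)),
            "B": DeckPayoff(100.0, (0, 0, 0, 0, 0, 0, 0, 0, 1250, 0)),
            "C": DeckPayoff(50.0, (0, 0, 50, 0, 50, 0, 50, 0, 50, 50)),
            "D": DeckPayoff(50.0, (0, 0, 0, 0, 0, 0, 0, 0, 0, 250)),
        }
    )


def _resolve_deck(deck: str | int) -> str:
    if isinstance(deck, str):
        if deck.upper() in DECK_INDEX:
            return deck.upper()
        raise InvalidDeckError(f"unknown deck {deck!r}; expected one of {DECKS}")
    if deck in (1, 2, 3, 4):
        return DECKS[deck - 1]
    raise InvalidDeckError(f"unknown deck {deck!r}; expected one of {DECKS} or 1..4")


def draw_outcome(schedule: PayoffSchedule, deck: str | int, draw_index_on_deck: int) -> TrialOutcome:
    """Outcome of the ``draw_index_on_deck``-th draw (1-based) from ``deck``.

    Deterministic: the position within the loss cycle is
    ``(draw_index_on_deck - 1) mod cycle_length``.
    """
    letter = _resolve_deck(deck)
    if draw_index_on_deck < 1:
        raise ValueError("draw_index_on_deck is 1-based and must be >= 1")
    payoff = schedule.decks[letter]
    pos = (draw_index_on_deck - 1) % payoff.cycle_length
    return TrialOutcome(gain=payoff.gain_per_draw, loss=payoff.loss_events[pos])


def validate_schedule(schedule: PayoffSchedule) -> list[str]:
    """Check schedule invariants; return a list of violation messages.

    An empty list means the schedule is valid. Checks: four decks present;
    gains positive; losses non-negative; A/B net-losing and C/D net-winning
    per cycle; zero-loss fraction 0.9 for B/D and 0.5 for A/C.
    """
    violations: list[str] = []
    if set(schedule.decks) != set(DECKS):
        violations.append("must have 4 decks (A, B, C, D)")
        return violations
    for letter, payoff in schedule.decks.items():
        if payoff.gain_per_draw <= 0:
            violations.append(f"{letter}: gain must be > 0")
        if any(x < 0 for x in payoff.loss_events):
            violations.append(f"{letter}: losses must be >= 0")
        if payoff.cycle_length < 1:
            violations.append(f"{letter}: cycle must be nonempty")
    for letter in "AB":
        if schedule.decks[letter].net_per_cycle >= 0:
            violations.append(f"{letter} not disadvantageous (net per cycle >= 0)")
    for letter in "CD":
        if schedule.decks[letter].net_per_cycle <= 0:
            violations.append(f"{letter} not advantageous (net per cycle <= 0)")
    for letter, frac in (("A", 0.5), ("B", 0.9), ("C", 0.5), ("D", 0.9)):
        got = schedule.decks[letter].zero_loss_fraction
        if abs(got - frac) > 1e-12:
            violations.append(f"{letter}: zero-loss fraction {got:.3g}, expected {frac}")
    return violations


def shuffle_within_cycle(schedule: PayoffSchedule, seed: int) -> PayoffSchedule:
    """Randomized-position dialect: permute each deck's losses within its cycle.

    Gains, loss magnitudes and therefore all per-cycle aggregates are
    unchanged; only the positions at which losses land differ.
    """
    rng = np.random.default_rng(seed)
    decks = {}
    for letter in DECKS:
        payoff = schedule.decks[letter]
        losses = tuple(rng.permutation(np.asarray(payoff.loss_events)))
        decks[letter] = DeckPayoff(payoff.gain_per_draw, losses)
    return PayoffSchedule(decks=decks)


def save_schedule(schedule: PayoffSchedule, path: str | Path) -> None:
    """Serialize a schedule to a small YAML file (one block per deck)."""
    data = {
        letter: {
            "gain_per_draw": float(p.gain_per_draw),
            "loss_events": [float(x) for x in p.loss_events],
        }
        for letter, p in schedule.decks.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_schedule(path: str | Path | None = None) -> PayoffSchedule:
    """Load a schedule from YAML; with no path, load the shipped classic file."""
    if path is None:
        text = resources.files("orligt").joinpath("data/classic_schedule.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    decks = {
        str(letter).upper(): DeckPayoff(float(block["gain_per_draw"]), tuple(block["loss_events"]))
        for letter, block in data.items()
    }
    return PayoffSchedule(decks=decks)
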