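"""Iowa Gambling Task environment.

The task presents four decks of cards. Every draw from a deck pays a
constant gain and, with deck-specific probability, also incurs a loss.
Decks A and B are disadvantageous (expected net -25 RMB per draw), C and
D advantageous (+25 RMB per draw).  Loss frequencies are realized
*exactly* within each deck's cycle (10 cards for A, B, D; 8 for C), with
the position of loss cards shuffled within each cycle by a seeded RNG,
so the card order is deterministic and reproducible while honouring the
nominal probabilities.

A standard administration is 100 selections split into 5 blocks of 20,
starting from a bankroll of 2000 RMB.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DECK_LABELS = ("A", "B", "C", "D")

#: default administration length
N_TRIALS = 100
#: trials per block (100 trials / 5 blocks)
BLOCK_SIZE = 20
#: starting bankroll, RMB
PRINCIPAL = 2000.0


@dataclass(frozen=True)
class DeckSpec:
    """Payoff structure of one deck.

    ``loss_table`` lists ``(magnitude, probability)`` pairs; over one
    ``cycle_length`` run of cards each magnitude occurs exactly
    ``probability * cycle_length`` times (which must be integral).
    """

    label: str
    win: float
    loss_table: tuple[tuple[float, float], ...]
    cycle_length: int

    def __post_init__(self) -> None:
        if self.label not in DECK_LABELS:
            raise ValueError(f"unknown deck label {self.label!r}")
        total_p = sum(p for _, p in self.loss_table)
        if total_p > 1 + 1e-12:
            raise ValueError("loss probabilities must sum to <= 1")
        for mag, p in self.loss_table:
            k = p * self.cycle_length
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"deck {self.label}: probability {p} is not realizable "
                    f"in a cycle of {self.cycle_length} cards"
                )

    def loss_multiset(self) -> list[float]:
        """The exact multiset of losses within one cycle (zeros included)."""
        losses: list[float] = []
        for mag, p in self.loss_table:
            losses.extend([mag] * round(p * self.cycle_length))
        losses.extend([0.0] * (self.cycle_length - len(losses)))
        return losses

    @property
    def expected_net(self) -> float:
        """Long-run expected net per draw (gain minus expected loss)."""
        return self.win - sum(m * p for m, p in self.loss_table)


#: The four canonical decks: A/B win 100 with 10% total loss mass of
#: 1250 per 10-card cycle; C/D win 50 with 200 per 8 (C) or 250 per 10 (D).
DECKS: dict[str, DeckSpec] = {
    "A": DeckSpec(
        "A",
        win=100.0,
        loss_table=((150.0, 0.1), (200.0, 0.1), (250.0, 0.1), (300.0, 0.1), (350.0, 0.1)),
        cycle_length=10,
    ),
    "B": DeckSpec("B", win=100.0, loss_table=((1250.0, 0.1),), cycle_length=10),
    "C": DeckSpec(
        "C",
        win=50.0,
        loss_table=((25.0, 0.125), (50.0, 0.25), (75.0, 0.125)),
        cycle_length=8,
    ),
    "D": DeckSpec("D", win=50.0, loss_table=((250.0, 0.1),), cycle_length=10),
}


@dataclass(frozen=True)
class PayoffSchedule:
    """Predetermined card order for each deck.

    ``card_orders[label]`` is an ordered list of ``(gain, loss)``
    outcomes; draws beyond the stored order wrap around (the stored
    order is a whole number of cycles, so wrapping preserves per-cycle
    loss frequencies).
    """

    decks: dict[str, DeckSpec]
    card_orders: dict[str, tuple[tuple[float, float], ...]]
    seed: int
    n_trials: int = N_TRIALS
    block_size: int = BLOCK_SIZE
    principal: float = PRINCIPAL

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_trials": self.n_trials,
            "block_size": self.block_size,
            "principal": self.principal,
            "card_orders": {
                label: [list(card) for card in order]
                for label, order in self.card_orders.items()
            },
        }


def build_schedule(
    seed: int,
    n_trials: int = N_TRIALS,
    block_size: int = BLOCK_SIZE,
    principal: float = PRINCIPAL,
) -> PayoffSchedule:
    """Build a deterministic payoff schedule.

    Each deck's order is a concatenation of independently shuffled
    cycles; every cycle contains exactly the loss multiset implied by
    the deck's printed probabilities.
    """
    if seed < 0 or int(seed) != seed:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    orders: dict[str, tuple[tuple[float, float], ...]] = {}
    for label in DECK_LABELS:
        deck = DECKS[label]
        n_cycles = max(1, math.ceil(n_trials / deck.cycle_length))
        cards: list[tuple[float, float]] = []
        base = deck.loss_multiset()
        for _ in range(n_cycles):
            perm = rng.permutation(len(base))
            cards.extend((deck.win, base[i]) for i in perm)
        orders[label] = tuple(cards)
    return PayoffSchedule(
        decks=dict(DECKS),
        card_orders=orders,
        seed=int(seed),
        n_trials=n_trials,
        block_size=block_size,
        principal=principal,
    )


def draw(schedule: PayoffSchedule, deck: str, position: int) -> tuple[float, float]:
    """Outcome ``(gain, loss)`` of the ``position``-th draw from ``deck``.

    ``position`` counts from 1 per deck; positions beyond the stored
    order wrap by cycle.
    """
    if deck not in schedule.card_orders:
        raise KeyError(f"unknown deck label {deck!r}")
    if position < 1:
        raise ValueError("position counts from 1")
    order = schedule.card_orders[deck]
    return order[(position - 1) % len(order)]


@dataclass(frozen=True)
class TrialRecord:
    """One choice: deck drawn, outcome, and running bankroll."""

    trial: int
    deck: str
    gain: float
    loss: float
    bankroll_after: float
    block: int

    @property
    def net(self) -> float:
        return self.gain - self.loss


@dataclass
class SubjectDataset:
    """One subject-session: ordered trials plus clinical fields."""

    subject_id: str
    group: str = "HC"
    session: str = "pre"
    trials: list[TrialRecord] = field(default_factory=list)
    craving: int | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials, start=1):
            if t.trial != i:
                raise ValueError(
                    f"subject {self.subject_id}: trials must be strictly "
                    f"ordered 1..n with no gaps (got {t.trial} at position {i})"
                )
        if self.craving is not None and not (1 <= self.craving <= 100):
            raise ValueError("craving must lie in [1, 100]")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def choices(self) -> np.ndarray:
        """Deck indices 0..3 in trial order."""
        return np.array([DECK_LABELS.index(t.deck) for t in self.trials], dtype=np.int64)

    def nets(self) -> np.ndarray:
        return np.array([t.net for t in self.trials], dtype=np.float64)

    def gains(self) -> np.ndarray:
        return np.array([t.gain for t in self.trials], dtype=np.float64)

    def losses(self) -> np.ndarray:
        return np.array([t.loss for t in self.trials], dtype=np.float64)

    def deck_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(DECK_LABELS, 0)
        for t in self.trials:
            counts[t.deck] += 1
        return counts


def make_subject(
    subject_id: str,
    choices: Sequence[int | str],
    schedule: PayoffSchedule,
    group: str = "HC",
    session: str = "pre",
    craving: int | None = None,
    covariates: dict[str, float] | None = None,
) -> SubjectDataset:
    """Assemble a :class:`SubjectDataset` by replaying ``choices``
    (deck letters or indices 0..3) against a schedule."""
    positions = dict.fromkeys(DECK_LABELS, 0)
    bankroll = schedule.principal
    trials: list[TrialRecord] = []
    for i, c in enumerate(choices, start=1):
        label = c if isinstance(c, str) else DECK_LABELS[int(c)]
        positions[label] += 1
        gain, loss = draw(schedule, label, positions[label])
        bankroll += gain - loss
        trials.append(
            TrialRecord(
                trial=i,
                deck=label,
                gain=gain,
                loss=loss,
                bankroll_after=bankroll,
                block=math.ceil(i / schedule.block_size),
            )
        )
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        session=session,
        trials=trials,
        craving=craving,
        covariates=covariates or {},
    )


def block_advantage_rates(
    subject: SubjectDataset, block_size: int = BLOCK_SIZE
) -> np.ndarray:
    """Per-block proportion of advantageous (C or D) choices."""
    n = subject.n_trials
    if n == 0 or n % block_size != 0:
        raise ValueError(
            f"subject {subject.subject_id}: {n} trials do not form complete "
            f"blocks of {block_size}"
        )
    adv = np.array([t.deck in ("C", "D") for t in subject.trials], dtype=float)
    return adv.reshape(-1, block_size).mean(axis=1)


class QCResult(NamedTuple):
    kept: list[SubjectDataset]
    excluded: list[SubjectDataset]
    reasons: dict[str, str]


def qc_filter(
    cohort: Sequence[SubjectDataset], min_fraction: float = 0.05
) -> QCResult:
    """Exclude subjects who under-sampled any deck.

    A subject is excluded iff any deck was chosen
    ``floor(min_fraction * n_trials)`` times or fewer — the "five times
    or less" rule on 100 trials.  Idempotent on the kept partition.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    kept: list[SubjectDataset] = []
    excluded: list[SubjectDataset] = []
    reasons: dict[str, str] = {}
    for subject in cohort:
        threshold = math.floor(min_fraction * subject.n_trials)
        counts = subject.deck_counts()
        bad = {label: c for label, c in counts.items() if c <= threshold}
        if bad:
            detail = ", ".join(f"{label}={c}" for label, c in sorted(bad.items()))
            reasons[f"{subject.subject_id}/{subject.session}"] = (
                f"deck selection count <= {threshold}: {detail}"
            )
            excluded.append(subject)
            logger.info(
                "QC excluded %s (%s): %s", subject.subject_id, subject.session, detail
            )
        else:
            kept.append(subject)
    return QCResult(kept, excluded, reasons)
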