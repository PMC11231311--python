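"""Readers and writers for the long-format trial CSV and schedule JSON.

The trial file convention is one row per choice with columns
``subjID, group, session, trial, choice, gain, loss``; ``choice`` may be
coded as deck letters A-D or integers 1-4 and is normalized on read.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .task import (
    DECK_LABELS,
    DECKS,
    PayoffSchedule,
    SubjectDataset,
    TrialRecord,
)

TRIAL_COLUMNS = ["subjID", "group", "session", "trial", "choice", "gain", "loss"]


def _normalize_choice(value) -> str:
    s = str(value).strip().upper()
    if s in DECK_LABELS:
        return s
    try:
        idx = int(float(s))
    except ValueError:
        raise ValueError(f"unrecognized deck coding {value!r}") from None
    if 1 <= idx <= 4:
        return DECK_LABELS[idx - 1]
    raise ValueError(f"unrecognized deck coding {value!r}")


def subjects_to_frame(subjects: Sequence[SubjectDataset]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for t in s.trials:
            rows.append(
                {
                    "subjID": s.subject_id,
                    "group": s.group,
                    "session": s.session,
                    "trial": t.trial,
                    "choice": DECK_LABELS.index(t.deck) + 1,
                    "gain": t.gain,
                    "loss": t.loss,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(subjects: Sequence[SubjectDataset], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def frame_to_subjects(
    df: pd.DataFrame,
    principal: float = 2000.0,
    block_size: int = 20,
) -> list[SubjectDataset]:
    """Reassemble subjects from a long-format trial table.

    Bankroll is reconstructed by accumulating net outcomes from the
    principal; ``group``/``session`` default to HC/pre when absent.
    """
    df = df.copy()
    missing = {"subjID", "trial", "choice", "gain", "loss"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "HC"
    if "session" not in df.columns:
        df["session"] = "pre"
    subjects = []
    for (sid, session), sub in df.groupby(["subjID", "session"], sort=False):
        sub = sub.sort_values("trial")
        bankroll = principal
        trials = []
        for _, row in sub.iterrows():
            deck = _normalize_choice(row["choice"])
            gain = float(row["gain"])
            loss = abs(float(row["loss"]))  # some dialects store losses negative
            bankroll += gain - loss
            trials.append(
                TrialRecord(
                    trial=int(row["trial"]),
                    deck=deck,
                    gain=gain,
                    loss=loss,
                    bankroll_after=bankroll,
                    block=math.ceil(int(row["trial"]) / block_size),
                )
            )
        subjects.append(
            SubjectDataset(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                session=str(session),
                trials=trials,
            )
        )
    return subjects


def read_trials(path: str | Path, **kwargs) -> list[SubjectDataset]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return frame_to_subjects(pd.read_csv(path, sep=sep), **kwargs)


def write_schedule(schedule: PayoffSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schedule.to_dict(), indent=1))


def read_schedule(path: str | Path) -> PayoffSchedule:
    d = json.loads(Path(path).read_text())
    orders = {
        label: tuple((float(g), float(l)) for g, l in cards)
        for label, cards in d["card_orders"].items()
    }
    return PayoffSchedule(
        decks=dict(DECKS),
        card_orders=orders,
        seed=int(d["seed"]),
        n_trials=int(d["n_trials"]),
        block_size=int(d["block_size"]),
        principal=float(d["principal"]),
    )
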