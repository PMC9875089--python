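"""Individual-level laterality scoring.

A side-choice record is a pair of event counts (right, left) for one animal
performing one behavior in one observation session.  From these we derive:

* the binomial Z-score ``Z = (R - N/2) / sqrt(N * p * q)`` with ``p = q = 0.5``,
  used to classify an animal as left-preferring, right-preferring or
  ambilateral at the conventional ``|Z| > 1.96`` bound;
* the laterality (handedness) index ``LI = (R - L) / N`` in [-1, 1], the
  direction of the side preference; and
* its absolute value ``|LI|`` in [0, 1], the strength of the preference
  irrespective of direction.

Records with fewer than ``min_n`` total events (default 10) carry too little
information for a stable preference estimate and are excluded before any
group-level analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "BEHAVIORS",
    "CAPPED_BEHAVIORS",
    "LEFT",
    "AMBILATERAL",
    "RIGHT",
    "Z_THRESHOLD",
    "ChoiceCount",
    "LateralityScore",
    "compute_z",
    "compute_li",
    "classify",
    "score",
    "score_table",
    "filter_min_counts",
]

#: Canonical genotype codes, in conventional order (wild type, heterozygous
#: knockout, homozygous knockout).  Slash notation is accepted on input.
GENOTYPES = ("WT", "HET", "KO")

#: The four scored behaviors: grid climbing, food-reaching test,
#: self-grooming, barrier crossing.
BEHAVIORS = ("GC", "FRT", "SG", "BC")

#: Behaviors whose event coding stops after 50 events.
CAPPED_BEHAVIORS = frozenset({"FRT", "BC"})
EVENT_CAP = 50

LEFT = "LEFT"
AMBILATERAL = "AMBILATERAL"
RIGHT = "RIGHT"

#: Two-sided 5% normal critical value used for individual classification.
Z_THRESHOLD = 1.96


class EmptyCountError(ValueError):
    """Raised when a laterality statistic is requested for N = 0 events."""


@dataclass(frozen=True)
class ChoiceCount:
    """Left/right event tallies for one animal x behavior x session."""

    animal_id: str
    genotype: str
    behavior: str
    session: int
    batch: int
    n_right: int
    n_left: int

    def __post_init__(self) -> None:
        if self.n_right < 0 or self.n_left < 0:
            raise ValueError(
                f"negative count for {self.animal_id}/{self.behavior}: "
                f"R={self.n_right}, L={self.n_left}"
            )
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session!r}")
        if self.behavior in CAPPED_BEHAVIORS and self.n_total > EVENT_CAP:
            raise ValueError(
                f"{self.behavior} coding stops at {EVENT_CAP} events; "
                f"got N={self.n_total} for animal {self.animal_id}"
            )

    @property
    def n_total(self) -> int:
        return self.n_right + self.n_left


@dataclass(frozen=True)
class LateralityScore:
    """Derived laterality statistics for one :class:`ChoiceCount`."""

    z: float
    li: float
    abs_li: float
    n_total: int
    classification: str


def compute_z(n_right: int, n_left: int) -> float:
    """Binomial Z-score ``(R - N/2) / (0.5 * sqrt(N))`` for p = q = 0.5.

    Positive iff the animal used the right side more often than the left.
    """
    n = n_right + n_left
    if n == 0:
        raise EmptyCountError("Z-score undefined for a record with zero events")
    return (n_right - n / 2.0) / (0.5 * math.sqrt(n))


def compute_li(n_right: int, n_left: int) -> float:
    """Laterality index ``(R - L) / N`` in [-1, 1]; equals ``Z / sqrt(N)``."""
    n = n_right + n_left
    if n == 0:
        raise EmptyCountError("LI undefined for a record with zero events")
    return (n_right - n_left) / n


def classify(z: float, threshold: float = Z_THRESHOLD) -> str:
    """Classify a Z-score as LEFT / AMBILATERAL / RIGHT.

    The inequalities are strict: ``z`` exactly at the threshold is
    ambilateral, matching the convention that only scores *exceeding*
    the critical value indicate a significant individual preference.
    """
    if threshold <= 0:
        raise ValueError("classification threshold must be positive")
    if z > threshold:
        return RIGHT
    if z < -threshold:
        return LEFT
    return AMBILATERAL


def score(count: ChoiceCount, threshold: float = Z_THRESHOLD) -> LateralityScore:
    """Score a single record: Z, LI, |LI| and the L/A/R classification."""
    z = compute_z(count.n_right, count.n_left)
    li = compute_li(count.n_right, count.n_left)
    return LateralityScore(
        z=z,
        li=li,
        abs_li=abs(li),
        n_total=count.n_total,
        classification=classify(z, threshold),
    )


def score_table(counts: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Vectorised :func:`score` over a tidy count table.

    Parameters
    ----------
    counts
        Tidy table with columns ``animal_id, genotype, behavior, session,
        batch, n_right, n_left`` (one row per animal x behavior x session).
    threshold
        Classification bound on the Z-score.

    Returns
    -------
    A copy of ``counts`` with appended columns ``n_total, z, li, abs_li,
    classification``.  Rows with zero events raise :class:`EmptyCountError`.
    """
    out = counts.copy()
    n = out["n_right"].to_numpy(float) + out["n_left"].to_numpy(float)
    if (n == 0).any():
        bad = out.loc[n == 0, ["animal_id", "behavior", "session"]]
        raise EmptyCountError(
            f"zero-event records cannot be scored:\n{bad.to_string(index=False)}"
        )
    z = (out["n_right"].to_numpy(float) - n / 2.0) / (0.5 * np.sqrt(n))
    li = (out["n_right"].to_numpy(float) - out["n_left"].to_numpy(float)) / n
    out["n_total"] = n.astype(int)
    out["z"] = z
    out["li"] = li
    out["abs_li"] = np.abs(li)
    out["classification"] = np.where(
        z > threshold, RIGHT, np.where(z < -threshold, LEFT, AMBILATERAL)
    )
    return out


def filter_min_counts(
    counts: pd.DataFrame,
    min_n: int = 10,
    require_both_sessions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the minimum-event inclusion rule.

    A record is retained iff its own total event count is at least ``min_n``
    (inclusive).  With ``require_both_sessions=True`` — used by the
    temporal-consistency analyses, which need a complete session pair — an
    animal x behavior combination is retained only when *both* of its
    sessions individually pass the rule.

    Returns ``(retained, exclusion_log)``; the log has one row per dropped
    record with a ``reason`` column.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    df = counts.copy()
    n = df["n_right"] + df["n_left"]
    below = n < min_n
    reasons = pd.Series(
        np.where(below, f"fewer than {min_n} events", ""), index=df.index
    )
    drop = below.copy()
    if require_both_sessions:
        bad_pairs = set(
            map(tuple, df.loc[below, ["animal_id", "behavior"]].drop_duplicates().to_numpy())
        )
        pair_key = list(map(tuple, df[["animal_id", "behavior"]].to_numpy()))
        partner = pd.Series([k in bad_pairs for k in pair_key], index=df.index) & ~below
        reasons = reasons.mask(partner, "paired session below the event minimum")
        drop |= partner
        # a pair also needs both sessions to exist at all
        n_sessions = df.groupby(["animal_id", "behavior"], observed=True)[
            "session"
        ].transform("nunique")
        lone = (n_sessions < 2) & ~drop
        reasons = reasons.mask(lone, "no paired session recorded")
        drop |= lone
    log = df.loc[drop].copy()
    log["reason"] = reasons[drop]
    return df.loc[~drop].copy(), log


def records_to_frame(records: Iterable[ChoiceCount]) -> pd.DataFrame:
    """Convert :class:`ChoiceCount` records to the tidy table layout."""
    rows = [
        (r.animal_id, r.genotype, r.behavior, r.session, r.batch, r.n_right, r.n_left)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "behavior", "session", "batch", "n_right", "n_left"],
    )
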