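"""Data model and I/O for dyadic match records and ethogram event tables.

Match tables are plain CSV (UTF-8, header row, dot decimal) with columns
``assay, cage, order, id_a, id_b, outcome, count_a, count_b`` — a dialect
chosen so that spreadsheet-annotated behavioral data round-trips without
surprises. Ethogram tables follow the shape of a BORIS export after a
simple column mapping: one CSV of events (``trial_id, subject, behavior,
start_s, stop_s``) and one of trials (``trial_id, start_s, stop_s``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from domsuite.errors import FormatError, ValidationError


class Assay(str, enum.Enum):
    """The four dominance assays."""

    AGONISTIC = "agonistic"
    URINE = "urine"
    TUBE = "tube"
    REWARD = "reward"


class Outcome(str, enum.Enum):
    A_WINS = "a"
    B_WINS = "b"
    TIE = "tie"


class Behavior(str, enum.Enum):
    """Tube-test ethogram behaviors.

    Push: moving forward, attempting to move feet forward, or darting the
    head at the opponent. Resist: holding position while pushed, without
    pushing back. Retreat-in-contact: backing up while touching the
    opponent. Passive retreat: backing up without contact.
    """

    PUSH = "push"
    RESIST = "resist"
    RETREAT_CONTACT = "retreat_contact"
    RETREAT_PASSIVE = "retreat_passive"


@dataclass(frozen=True)
class MatchRecord:
    """One dyadic contest.

    ``order`` is the chronological index within (assay, cage); outcomes
    are from the perspective of ``id_a``. ``count_a``/``count_b`` carry
    per-animal tallies where the assay has them (urine spots, rewards won).
    """

    assay: Assay
    cage: str
    order: int
    id_a: str
    id_b: str
    outcome: Outcome
    count_a: int | None = None
    count_b: int | None = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValidationError(
                f"match {self.assay.value}/{self.cage}/{self.order}: "
                f"id_a and id_b are both {self.id_a!r}"
            )
        if self.order < 0:
            raise ValidationError(f"negative order index {self.order}")
        for name, c in (("count_a", self.count_a), ("count_b", self.count_b)):
            if c is not None and c < 0:
                raise ValidationError(f"{name} is negative: {c}")


@dataclass(frozen=True)
class EthogramEvent:
    """One annotated behavior bout of one subject, in seconds from trial start."""

    subject: str
    behavior: Behavior
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.stop_s:
            raise ValidationError(
                f"event interval [{self.start_s}, {self.stop_s}] is not "
                "a forward interval with non-negative start"
            )


@dataclass(frozen=True)
class Trial:
    """A scored trial window with its ethogram events."""

    start_s: float
    stop_s: float
    events: tuple[EthogramEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stop_s <= self.start_s:
            raise ValidationError(
                f"trial [{self.start_s}, {self.stop_s}] has non-positive duration"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


MATCH_COLUMNS = ("assay", "cage", "order", "id_a", "id_b", "outcome", "count_a", "count_b")

_OUTCOME_ALIASES = {
    "a": Outcome.A_WINS,
    "a_wins": Outcome.A_WINS,
    "b": Outcome.B_WINS,
    "b_wins": Outcome.B_WINS,
    "tie": Outcome.TIE,
}


def _parse_count(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    f = float(s)
    if not f.is_integer() or f < 0:
        raise FormatError(f"count value {value!r} is not a non-negative integer")
    return int(f)


def read_matches(path: str | Path) -> list[MatchRecord]:
    """Read a match CSV, validating and sorting by (assay, cage, order).

    Outcome values ``a``/``b``/``tie`` (and ``a_wins``/``b_wins``) are
    accepted case-insensitively; empty count cells mean absent. Malformed
    rows raise :class:`FormatError` naming the offending line; duplicate
    (assay, cage, order) slots for the same dyad raise
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in MATCH_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[MatchRecord] = []
    seen: set[tuple] = set()
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            assay = Assay(row["assay"].strip().lower())
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: unknown assay {row['assay']!r}") from exc
        outcome_raw = row["outcome"].strip().lower()
        if outcome_raw not in _OUTCOME_ALIASES:
            raise FormatError(f"{path}:{line_no}: unknown outcome {row['outcome']!r}")
        try:
            order = int(row["order"])
            rec = MatchRecord(
                assay=assay,
                cage=row["cage"].strip(),
                order=order,
                id_a=row["id_a"].strip(),
                id_b=row["id_b"].strip(),
                outcome=_OUTCOME_ALIASES[outcome_raw],
                count_a=_parse_count(row.get("count_a")),
                count_b=_parse_count(row.get("count_b")),
            )
        except (ValueError, FormatError, ValidationError) as exc:
            raise type(exc)(f"{path}:{line_no}: {exc}") from exc
        key = (rec.assay, rec.cage, rec.order, frozenset((rec.id_a, rec.id_b)))
        if key in seen:
            raise ValidationError(
                f"{path}:{line_no}: duplicate match slot "
                f"({rec.assay.value}, {rec.cage}, {rec.order}, {rec.id_a}-{rec.id_b})"
            )
        seen.add(key)
        records.append(rec)
    records.sort(key=lambda r: (r.assay.value, r.cage, r.order))
    return records


def write_matches(records: Iterable[MatchRecord], path: str | Path) -> None:
    """Write records to the documented CSV dialect; bit-stable for fixed input."""
    rows = [
        {
            "assay": r.assay.value,
            "cage": r.cage,
            "order": r.order,
            "id_a": r.id_a,
            "id_b": r.id_b,
            "outcome": r.outcome.value,
            "count_a": "" if r.count_a is None else r.count_a,
            "count_b": "" if r.count_b is None else r.count_b,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(MATCH_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_ethogram(events_path: str | Path, trials_path: str | Path) -> dict[str, dict[str, Trial]]:
    """Read BORIS-style event and trial CSVs.

    Returns ``{trial_id: {subject: Trial}}`` where each subject's Trial
    shares the trial window but holds only that subject's events.
    """
    events = pd.read_csv(events_path, dtype={"trial_id": str, "subject": str})
    trials = pd.read_csv(trials_path, dtype={"trial_id": str})
    for col in ("trial_id", "subject", "behavior", "start_s", "stop_s"):
        if col not in events.columns:
            raise FormatError(f"{events_path}: missing column {col!r}")
    for col in ("trial_id", "start_s", "stop_s"):
        if col not in trials.columns:
            raise FormatError(f"{trials_path}: missing column {col!r}")

    out: dict[str, dict[str, Trial]] = {}
    for _, trow in trials.iterrows():
        tid = str(trow["trial_id"])
        ev = events[events["trial_id"] == tid]
        per_subject: dict[str, Trial] = {}
        for subject, grp in ev.groupby("subject"):
            evs = tuple(
                EthogramEvent(
                    subject=str(subject),
                    behavior=Behavior(str(r["behavior"]).strip().lower()),
                    start_s=float(r["start_s"]),
                    stop_s=float(r["stop_s"]),
                )
                for _, r in grp.iterrows()
            )
            per_subject[str(subject)] = Trial(
                start_s=float(trow["start_s"]), stop_s=float(trow["stop_s"]), events=evs
            )
        out[tid] = per_subject
    return out


def _union_length(intervals: Sequence[tuple[float, float]]) -> float:
    """Total length of the union of intervals (already clipped)."""
    if not intervals:
        return 0.0
    merged_total = 0.0
    cur_lo, cur_hi = None, None
    for lo, hi in sorted(intervals):
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            merged_total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    merged_total += cur_hi - cur_lo
    return merged_total


def ethogram_percent_time(trial: Trial, behavior: Behavior) -> float:
    """Fraction of the trial the subject spent in ``behavior``.

    Events are clipped to the trial window and overlapping bouts of the
    same behavior are unioned before summing, so the result is in [0, 1]
    (double-scored overlap is treated as an annotation artifact, not
    extra time).
    """
    if trial.duration_s <= 0:
        raise ValidationError("trial has zero duration")
    clipped = []
    for ev in trial.events:
        if ev.behavior is not behavior:
            continue
        lo = max(ev.start_s, trial.start_s)
        hi = min(ev.stop_s, trial.stop_s)
        if hi > lo:
            clipped.append((lo, hi))
    return _union_length(clipped) / trial.duration_s
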