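"""Event-log ingestion, binarisation, exclusion filtering and cohort summaries.

The raw measurement is a log of upload timestamps per participant.  A
day counts as adherent when at least ``min_entries`` (default 2)
dietary entries fall on that calendar date; a 21-day window starting at
``start_date`` (day 1, the first day after the preparation phase) is
binarised into an adherence sequence.  Participants whose whole window
is zero carry no temporal signal and are excluded before modelling;
the retention report keeps the accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("self_management", "tailored_feedback", "intensive_support")


class EmptyCohortError(ValueError):
    """Raised when an operation would leave no participants to model."""


@dataclass
class EventLog:
    """All upload timestamps of one participant (duplicates allowed)."""

    participant_id: str
    entries: list[pd.Timestamp] = field(default_factory=list)


@dataclass
class AdherenceSequence:
    """A fixed-length binary daily adherence vector for one participant."""

    participant_id: str
    days: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        if self.days.ndim != 1 or self.days.size < 1:
            raise ValueError("days must be a non-empty 1-D vector")
        if not np.all(np.isin(self.days, (0, 1))):
            raise ValueError("adherence values must be binary 0/1")
        self.days = self.days.astype(np.int8)


@dataclass
class Cohort:
    """All adherence sequences of one study arm."""

    group_label: str
    sequences: list[AdherenceSequence]

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        lengths = {len(s.days) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences in a cohort must share the same length")
        ids = [s.participant_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def T(self) -> int:
        if not self.sequences:
            raise EmptyCohortError("cohort has no participants")
        return len(self.sequences[0].days)

    @property
    def ids(self) -> list[str]:
        return [s.participant_id for s in self.sequences]

    @property
    def matrix(self) -> np.ndarray:
        if not self.sequences:
            raise EmptyCohortError("cohort has no participants")
        return np.vstack([s.days for s in self.sequences])


@dataclass(frozen=True)
class RetentionReport:
    group: str
    enrolled: int
    retained: int
    excluded: int
    retention_pct: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "enrolled": self.enrolled,
            "retained": self.retained,
            "excluded": self.excluded,
            "retention_pct": self.retention_pct,
        }


@dataclass(frozen=True)
class AdherenceSummary:
    """Per-participant adherence rates with their cohort mean and SD."""

    rates: np.ndarray
    mean: float
    sd: float


def build_sequence(
    log: EventLog,
    start_date,
    T: int = 21,
    min_entries: int = 2,
) -> AdherenceSequence:
    """Binarise an event log over the window ``[start_date, start_date + T - 1]``.

    Day ``n`` is 1 iff at least ``min_entries`` entries carry the
    calendar date ``start_date + (n - 1)``; entries outside the window
    are ignored.  Dates are taken from the timestamps as recorded (no
    timezone conversion).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if min_entries < 1:
        raise ValueError("min_entries must be >= 1")
    start = pd.Timestamp(start_date).normalize()
    days = np.zeros(T, dtype=np.int8)
    counts: dict[int, int] = {}
    for ts in log.entries:
        offset = (pd.Timestamp(ts).normalize() - start).days
        if 0 <= offset < T:
            counts[offset] = counts.get(offset, 0) + 1
    for offset, count in counts.items():
        if count >= min_entries:
            days[offset] = 1
    return AdherenceSequence(participant_id=log.participant_id, days=days)


def build_cohort(
    logs: Iterable[EventLog],
    start_date,
    group_label: str,
    T: int = 21,
    min_entries: int = 2,
) -> Cohort:
    sequences = [build_sequence(log, start_date, T, min_entries) for log in logs]
    return Cohort(group_label=group_label, sequences=sequences)


def exclude_all_zero(cohort: Cohort) -> tuple[Cohort, RetentionReport]:
    """Drop participants with an all-zero window; report the retention.

    The retention percentage is rounded to the nearest integer.
    """
    kept = [s for s in cohort.sequences if s.days.any()]
    enrolled = len(cohort)
    retained = len(kept)
    if enrolled > 0 and retained == 0:
        raise EmptyCohortError(
            f"all {enrolled} participants in {cohort.group_label!r} have all-zero "
            "sequences; nothing left to model"
        )
    pct = 100 if enrolled == 0 else int(math.floor(100.0 * retained / enrolled + 0.5))
    report = RetentionReport(
        group=cohort.group_label,
        enrolled=enrolled,
        retained=retained,
        excluded=enrolled - retained,
        retention_pct=pct,
    )
    return Cohort(group_label=cohort.group_label, sequences=kept), report


def group_adherence_curve(cohort: Cohort) -> np.ndarray:
    """Daily proportion of participants adherent (the quantity the model is fit to)."""
    return cohort.matrix.mean(axis=0)


def count_outcome_events(cohort: Cohort) -> int:
    """Total outcome events: sequence length times number of participants."""
    if len(cohort) == 0:
        return 0
    return cohort.T * len(cohort)


def mean_adherence(cohort: Cohort) -> AdherenceSummary:
    """Per-participant adherence rates and their cohort mean and (sample) SD."""
    rates = cohort.matrix.mean(axis=1)
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return AdherenceSummary(rates=rates, mean=float(rates.mean()), sd=sd)


# ---------------------------------------------------------------------------
# CSV dialects (comma-separated, UTF-8, header row)


def write_event_logs_csv(logs: Sequence[EventLog], path: str | Path) -> None:
    """Long event-log CSV: columns ``participant_id, timestamp`` (ISO-8601)."""
    rows = [
        {"participant_id": log.participant_id, "timestamp": pd.Timestamp(ts).isoformat()}
        for log in logs
        for ts in log.entries
    ]
    pd.DataFrame(rows, columns=["participant_id", "timestamp"]).to_csv(path, index=False)


def read_event_logs_csv(path: str | Path) -> list[EventLog]:
    """Parse an event-log CSV, reporting the offending row on bad timestamps."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if not {"participant_id", "timestamp"} <= set(df.columns):
        raise ValueError("event-log CSV needs columns participant_id, timestamp")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"cannot parse timestamp {df['timestamp'].iloc[i]!r} "
            f"(row {i + 2} of {path}, participant {df['participant_id'].iloc[i]!r})"
        )
    logs: dict[str, EventLog] = {}
    for pid, ts in zip(df["participant_id"], parsed):
        logs.setdefault(pid, EventLog(participant_id=pid)).entries.append(ts)
    return list(logs.values())


def write_sequences_csv(cohort: Cohort, path: str | Path) -> None:
    """Wide sequence CSV: ``participant_id, group, d1 .. dT`` with 0/1 values."""
    T = cohort.T
    records = []
    for s in cohort.sequences:
        row = {"participant_id": s.participant_id, "group": cohort.group_label}
        row.update({f"d{n}": int(v) for n, v in enumerate(s.days, start=1)})
        records.append(row)
    cols = ["participant_id", "group"] + [f"d{n}" for n in range(1, T + 1)]
    pd.DataFrame(records, columns=cols).to_csv(path, index=False)


def read_sequences_csv(path: str | Path, group_label: str | None = None) -> Cohort:
    """Read a wide sequence CSV; the group comes from the file unless overridden."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    day_cols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not day_cols:
        raise ValueError("sequence CSV has no day columns d1..dT")
    if group_label is None:
        if "group" not in df.columns or df["group"].nunique() != 1:
            raise ValueError("pass group_label or provide a single-valued 'group' column")
        group_label = str(df["group"].iloc[0])
    sequences = [
        AdherenceSequence(
            participant_id=row["participant_id"],
            days=np.array([row[c] for c in day_cols]),
        )
        for _, row in df.iterrows()
    ]
    return Cohort(group_label=group_label, sequences=sequences)
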