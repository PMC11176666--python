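"""Event-log and physiology-panel formats: reading, validation, aggregation.

Behavioral data are long-format *counted* records: one row per
(group, observation, day, initiator, receiver, behavior) with a non-negative
frequency. Duplicate keys are legal and are summed on aggregation, so a
per-session logger can append rows freely. Physiology panels are long-format
(subject, analyte, timepoint, value) measurements: hair cortisol, plasma
oxytocin/vasopressin and body weight on the three-sample schedule, fecal
IgG/IgA on the five-week schedule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "Behavior",
    "Analyte",
    "SchemaError",
    "ValidationError",
    "BehaviorEvent",
    "InteractionMatrix",
    "PhysioPanel",
    "EVENT_COLUMNS",
    "PHYSIO_COLUMNS",
    "read_event_log",
    "write_event_log",
    "events_to_frame",
    "frame_to_events",
    "aggregate_interactions",
    "read_physiology",
]


class Observation(str, enum.Enum):
    """Behavioral observation periods: baseline, and weeks 1/4 after release."""

    OBS1 = "OBS1"
    OBS3A = "OBS3A"
    OBS3B = "OBS3B"


class Behavior(str, enum.Enum):
    """Ethogram classes: aggressive, submissive, grooming, proximity."""

    AGG = "AGG"
    SUB = "SUB"
    GRO = "GRO"
    PRO = "PRO"


class Analyte(str, enum.Enum):
    HC = "HC"  # hair cortisol, pg/mg
    OT = "OT"  # plasma oxytocin, pg/mL
    AVP = "AVP"  # plasma vasopressin, pg/mL
    IGG = "IGG"  # fecal immunoglobulin G, ug/g
    IGA = "IGA"  # fecal immunoglobulin A, ug/g
    WEIGHT = "WEIGHT"  # body weight, kg


TRIPHASE_TIMEPOINTS: tuple[str, ...] = ("S1", "S2", "S3")
WEEKLY_TIMEPOINTS: tuple[str, ...] = ("W0", "W1", "W2", "W3", "W4")

#: analytes sampled at the end of each phase (3 samples)
TRIPHASE_ANALYTES = frozenset({Analyte.HC, Analyte.OT, Analyte.AVP, Analyte.WEIGHT})
#: analytes sampled weekly during isolation (5 samples)
WEEKLY_ANALYTES = frozenset({Analyte.IGG, Analyte.IGA})

EVENT_COLUMNS = ["group_id", "observation_id", "day", "initiator", "receiver", "behavior", "count"]
PHYSIO_COLUMNS = ["group_id", "subject_id", "analyte", "timepoint", "value"]


class SchemaError(ValueError):
    """Header of a CSV does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a record-level invariant."""


@dataclass(frozen=True)
class BehaviorEvent:
    """One directed, counted social-behavior record."""

    group_id: str
    observation_id: Observation
    day: int
    initiator: str
    receiver: str
    behavior: Behavior
    count: int

    def __post_init__(self) -> None:
        if self.initiator == self.receiver:
            raise ValidationError(
                f"initiator == receiver ({self.initiator!r}) in group {self.group_id!r}"
            )
        if not 1 <= int(self.day) <= 6:
            raise ValidationError(f"day must be in 1..6, got {self.day!r}")
        if int(self.count) < 0:
            raise ValidationError(f"count must be >= 0, got {self.count!r}")
        object.__setattr__(self, "observation_id", Observation(self.observation_id))
        object.__setattr__(self, "behavior", Behavior(self.behavior))
        object.__setattr__(self, "day", int(self.day))
        object.__setattr__(self, "count", int(self.count))


@dataclass
class InteractionMatrix:
    """Directed frequency matrix M[i, j] for one behavior in one observation."""

    behavior: Behavior
    observation_id: Observation
    subjects: tuple[str, ...]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.behavior = Behavior(self.behavior)
        self.observation_id = Observation(self.observation_id)
        self.subjects = tuple(self.subjects)
        self.M = np.asarray(self.M)
        n = len(self.subjects)
        if self.M.shape != (n, n):
            raise ValidationError(f"matrix shape {self.M.shape} != roster size {n}")
        if np.any(np.diag(self.M) != 0):
            raise ValidationError("interaction matrix must have a zero diagonal")
        if np.any(self.M < 0):
            raise ValidationError("interaction matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.M.sum())

    def index_of(self, subject: str) -> int:
        return self.subjects.index(subject)


class PhysioPanel:
    """Long-format subject x timepoint x analyte panel with schedule validation.

    Wraps a DataFrame with columns ``group_id, subject_id, analyte, timepoint,
    value``. Triphase analytes (HC/OT/AVP/WEIGHT) must carry timepoints S1-S3,
    weekly analytes (IgG/IgA) W0-W4.
    """

    def __init__(self, frame: pd.DataFrame, require_complete: bool = False) -> None:
        missing = [c for c in PHYSIO_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"physiology table missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, PHYSIO_COLUMNS].copy()
        bad = set(frame["analyte"]) - {a.value for a in Analyte}
        if bad:
            raise ValidationError(f"unknown analyte code(s): {sorted(bad)}")
        if (frame["value"] < 0).any():
            row = int(frame.index[frame["value"] < 0][0])
            raise ValidationError(f"negative measurement at row {row}")
        for _, sub in frame.groupby(["subject_id", "analyte"], sort=False):
            analyte = Analyte(sub["analyte"].iloc[0])
            allowed = TRIPHASE_TIMEPOINTS if analyte in TRIPHASE_ANALYTES else WEEKLY_TIMEPOINTS
            bad_tp = set(sub["timepoint"]) - set(allowed)
            if bad_tp:
                raise ValidationError(
                    f"timepoint(s) {sorted(bad_tp)} invalid for analyte {analyte.value}"
                )
            if require_complete and set(sub["timepoint"]) != set(allowed):
                raise ValidationError(
                    f"subject {sub['subject_id'].iloc[0]!r} analyte {analyte.value}: "
                    f"expected timepoints {allowed}, got {sorted(set(sub['timepoint']))}"
                )
        self.frame = frame

    def values_wide(self, analyte: Analyte | str) -> pd.DataFrame:
        """Subjects x ordered-timepoints table for one analyte."""
        analyte = Analyte(analyte)
        order = TRIPHASE_TIMEPOINTS if analyte in TRIPHASE_ANALYTES else WEEKLY_TIMEPOINTS
        sub = self.frame[self.frame["analyte"] == analyte.value]
        wide = sub.pivot_table(
            index="subject_id", columns="timepoint", values="value", aggfunc="mean"
        )
        return wide.reindex(columns=list(order))

    def group_of(self) -> pd.Series:
        """subject_id -> group_id mapping."""
        return self.frame.drop_duplicates("subject_id").set_index("subject_id")["group_id"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def _check_header(frame: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_event_log(path) -> list[BehaviorEvent]:
    """Read a behavioral event-log CSV into validated records, order preserved.

    Raises :class:`SchemaError` for a missing/renamed column and
    :class:`ValidationError` (with the offending row number) for bad rows.
    """
    frame = pd.read_csv(path, dtype={"group_id": str, "initiator": str, "receiver": str})
    _check_header(frame, EVENT_COLUMNS, "event log")
    return frame_to_events(frame)


def frame_to_events(frame: pd.DataFrame) -> list[BehaviorEvent]:
    _check_header(frame, EVENT_COLUMNS, "event table")
    events = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            events.append(
                BehaviorEvent(
                    group_id=str(row.group_id),
                    observation_id=row.observation_id,
                    day=row.day,
                    initiator=str(row.initiator),
                    receiver=str(row.receiver),
                    behavior=row.behavior,
                    count=row.count,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {row_number}: {exc}") from exc
    return events


def events_to_frame(events: Iterable[BehaviorEvent]) -> pd.DataFrame:
    rows = [
        (e.group_id, e.observation_id.value, e.day, e.initiator, e.receiver, e.behavior.value, e.count)
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_event_log(events: Iterable[BehaviorEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def roster_of(events: Iterable[BehaviorEvent]) -> tuple[str, ...]:
    """Sorted roster of all subjects appearing in the events."""
    subjects: set[str] = set()
    for e in events:
        subjects.add(e.initiator)
        subjects.add(e.receiver)
    return tuple(sorted(subjects))


def aggregate_interactions(
    events: Iterable[BehaviorEvent],
    behavior: Behavior | str,
    observation_id: Observation | str,
    roster: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Sum matching event counts into a directed frequency matrix.

    All events must come from a single group. ``roster`` fixes the matrix
    order (and allows subjects with no events); by default the sorted union
    of initiators and receivers is used.
    """
    behavior = Behavior(behavior)
    observation_id = Observation(observation_id)
    events = list(events)
    groups = {e.group_id for e in events}
    if len(groups) > 1:
        raise ValidationError(f"events span multiple groups: {sorted(groups)}")
    subjects = tuple(roster) if roster is not None else roster_of(events)
    index = {s: i for i, s in enumerate(subjects)}
    M = np.zeros((len(subjects), len(subjects)), dtype=int)
    for e in events:
        if e.behavior is behavior and e.observation_id is observation_id:
            try:
                M[index[e.initiator], index[e.receiver]] += e.count
            except KeyError as exc:
                raise ValidationError(f"subject {exc.args[0]!r} not in roster") from exc
    return InteractionMatrix(behavior=behavior, observation_id=observation_id, subjects=subjects, M=M)


def read_physiology(path, require_complete: bool = False) -> PhysioPanel:
    """Read a physiology-panel CSV (see :data:`PHYSIO_COLUMNS`) with validation."""
    frame = pd.read_csv(path, dtype={"group_id": str, "subject_id": str})
    _check_header(frame, PHYSIO_COLUMNS, "physiology table")
    return PhysioPanel(frame, require_complete=require_complete)
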