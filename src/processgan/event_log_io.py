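"""Reading, validating, and writing event logs.

An event log is a table with one row per event (case id, activity label,
timestamp) plus optional per-case context columns. Internally, timestamps
are plain real numbers in the log's declared unit; ISO-8601 strings are
converted on read. The activity vocabulary always reserves a padding token
as its last index.
"""

from __future__ import annotations

import dataclasses
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Event", "ProcessCase", "EventLog", "ActivityVocabulary",
    "read_event_log", "write_event_log", "case_duration",
    "build_vocabulary", "build_event_log", "read_xes",
    "SchemaError", "ValidationError", "PAD_TOKEN",
]

PAD_TOKEN = "[pad]"

DEFAULT_MAPPING = {"case_id": "case_id", "activity": "activity", "timestamp": "timestamp"}


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


class ValidationError(ValueError):
    """Input data violates an event-log invariant."""


@dataclasses.dataclass(frozen=True)
class Event:
    activity: str
    timestamp: float

    def __post_init__(self):
        if not self.activity:
            raise ValidationError("activity label must be non-empty")
        if not np.isfinite(self.timestamp):
            raise ValidationError(f"timestamp must be finite, got {self.timestamp}")


@dataclasses.dataclass
class ProcessCase:
    case_id: str
    events: list[Event]
    contexts: dict[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.events:
            raise ValidationError(f"case {self.case_id!r} has no events")
        ts = [e.timestamp for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError(f"case {self.case_id!r} events not sorted by timestamp")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def activities(self) -> list[str]:
        return [e.activity for e in self.events]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([e.timestamp for e in self.events], dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class ActivityVocabulary:
    """Ordered activity labels with the pad token appended as the last index."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("vocabulary labels must be unique")
        if self.labels[-1] != PAD_TOKEN:
            raise ValidationError("last vocabulary label must be the pad token")

    @property
    def pad_index(self) -> int:
        return len(self.labels) - 1

    @property
    def size(self) -> int:
        """Total number of tokens, pad included."""
        return len(self.labels)

    @property
    def n_real(self) -> int:
        return len(self.labels) - 1

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown activity label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels


def build_vocabulary(labels) -> ActivityVocabulary:
    """Vocabulary over distinct labels in first-seen order, plus the pad token."""
    seen: dict[str, None] = {}
    for lab in labels:
        if lab == PAD_TOKEN:
            raise ValidationError(f"{PAD_TOKEN!r} is reserved for padding")
        seen.setdefault(lab, None)
    if not seen:
        raise ValidationError("cannot build a vocabulary from zero labels")
    return ActivityVocabulary(tuple(seen) + (PAD_TOKEN,))


@dataclasses.dataclass
class EventLog:
    cases: list[ProcessCase]
    vocabulary: ActivityVocabulary
    duration_bounds: tuple[float, float]
    time_unit: str = "seconds"

    def __post_init__(self):
        t_min, t_max = self.duration_bounds
        if t_min > t_max:
            raise ValidationError(f"duration bounds inverted: ({t_min}, {t_max})")
        for case in self.cases:
            for ev in case.events:
                if ev.activity not in self.vocabulary:
                    raise ValidationError(
                        f"activity {ev.activity!r} in case {case.case_id!r} "
                        "missing from vocabulary")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def max_length(self) -> int:
        return max(len(c) for c in self.cases)

    def durations(self) -> np.ndarray:
        return np.array([case_duration(c) for c in self.cases])

    def context_names(self) -> list[str]:
        names: dict[str, None] = {}
        for c in self.cases:
            for k in c.contexts:
                names.setdefault(k, None)
        return list(names)


def case_duration(case: ProcessCase) -> float:
    """Last event timestamp minus first event timestamp (0 for one event)."""
    return case.events[-1].timestamp - case.events[0].timestamp


def build_event_log(cases: list[ProcessCase], time_unit: str = "seconds",
                    vocabulary: ActivityVocabulary | None = None) -> EventLog:
    if not cases:
        raise ValidationError("event log has no cases")
    if vocabulary is None:
        vocabulary = build_vocabulary(
            a for c in cases for a in c.activities)
    durations = [case_duration(c) for c in cases]
    return EventLog(cases, vocabulary, (min(durations), max(durations)), time_unit)


def _parse_timestamp(raw, row: int) -> float:
    if isinstance(raw, (int, float, np.integer, np.floating)) and not isinstance(raw, bool):
        val = float(raw)
    else:
        text = str(raw).strip()
        try:
            val = float(text)
        except ValueError:
            try:
                val = pd.Timestamp(text).timestamp()
            except (ValueError, TypeError):
                raise ValidationError(
                    f"row {row}: unparseable timestamp {raw!r}") from None
    if not np.isfinite(val):
        raise ValidationError(f"row {row}: timestamp {raw!r} is not finite")
    return val


def read_event_log(path, mapping: dict[str, str] | None = None,
                   time_unit: str = "seconds") -> EventLog:
    """Read a CSV event log; group rows into cases sorted by timestamp.

    ``mapping`` maps the canonical names (case_id, activity, timestamp) to the
    file's column names. Columns named ``context_*`` (or any extra columns
    listed under ``mapping['contexts']``) become per-case context attributes.
    """
    mapping = {**DEFAULT_MAPPING, **(mapping or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={mapping["case_id"]: str, mapping["activity"]: str})
    for key in ("case_id", "activity", "timestamp"):
        if mapping[key] not in df.columns:
            raise SchemaError(f"missing column {mapping[key]!r} in {path}")
    if len(df) == 0:
        raise ValidationError(f"empty event log: {path}")
    context_cols = mapping.get("contexts")
    if context_cols is None:
        context_cols = [c for c in df.columns if c.startswith("context_")]

    cases: list[ProcessCase] = []
    # groupby(sort=False) keeps first-appearance case order; stable sort keeps
    # file order among tied timestamps.
    ts_col = [
        _parse_timestamp(v, i) for i, v in zip(df.index, df[mapping["timestamp"]])
    ]
    df = df.assign(__ts=ts_col)
    for case_id, group in df.groupby(mapping["case_id"], sort=False):
        group = group.sort_values("__ts", kind="stable")
        events = [Event(a, t) for a, t in zip(group[mapping["activity"]], group["__ts"])]
        contexts = {}
        for col in context_cols:
            vals = group[col].dropna().unique()
            if len(vals):
                contexts[col] = vals[0]
        cases.append(ProcessCase(str(case_id), events, contexts))
    return build_event_log(cases, time_unit=time_unit)


def write_event_log(log: EventLog, path) -> None:
    """Write as CSV (case_id, activity, timestamp[, context_*]), case order kept."""
    rows = []
    context_names = log.context_names()
    for case in log.cases:
        for ev in case.events:
            row = {"case_id": case.case_id, "activity": ev.activity,
                   "timestamp": repr(ev.timestamp)}
            for name in context_names:
                row[name] = case.contexts.get(name, "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_XES_NS = "{http://www.xes-standard.org/}"


def read_xes(path, time_unit: str = "seconds") -> EventLog:
    """Minimal XES import: concept:name -> activity, time:timestamp -> timestamp."""
    root = ET.parse(path).getroot()
    cases: list[ProcessCase] = []
    for i, trace in enumerate(root.iter(f"{_XES_NS}trace")):
        case_id = str(i)
        for attr in trace.findall(f"{_XES_NS}string"):
            if attr.get("key") == "concept:name":
                case_id = attr.get("value", case_id)
        events = []
        for event in trace.iter(f"{_XES_NS}event"):
            activity, ts = None, None
            for attr in event:
                if attr.get("key") == "concept:name":
                    activity = attr.get("value")
                elif attr.get("key") == "time:timestamp":
                    ts = _parse_timestamp(attr.get("value"), i)
            if activity is not None and ts is not None:
                events.append((ts, activity))
        if events:
            events.sort(key=lambda e: e[0])
            cases.append(ProcessCase(case_id, [Event(a, t) for t, a in events]))
    if not cases:
        raise ValidationError(f"no traces found in {path}")
    return build_event_log(cases, time_unit=time_unit)
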