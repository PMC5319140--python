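"""Domain types and on-disk formats for monitoring sessions, review actions and cohorts.

One :class:`MonitoringSession` is one patient-day interaction with the
self-monitoring application: the 9-item symptom diary, the oximetry summary
(SpO2 %, pulse rate bpm) with its quality outcome, and timing metadata.
Sessions and nurse review actions are stored as flat CSV or JSONL files with
a fixed column schema, so every other module can consume a validated
:class:`CohortTable` without re-parsing.

Timestamps are timezone-naive local clock time at minute resolution: the
time-of-day habit analyses operate on the patient's own clock, and the
source data carries no zone information.  Missing numeric fields are
serialised as empty CSV cells / JSON nulls; no sentinel numbers are used.
Diary-only sessions (no oximetry) are legal.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "QualityLabel",
    "ACTION_CODES",
    "MonitoringSession",
    "VitalsStream",
    "ReviewAction",
    "CohortTable",
    "SchemaError",
    "RowError",
    "read_sessions",
    "write_sessions",
    "read_actions",
    "write_actions",
    "SESSION_COLUMNS",
    "ACTION_COLUMNS",
]

N_DIARY_ITEMS = 9

SESSION_COLUMNS = (
    ["patient_id", "timestamp"]
    + [f"q{i}" for i in range(1, N_DIARY_ITEMS + 1)]
    + ["diary_seconds", "spo2", "pulse", "quality", "attempts"]
)
ACTION_COLUMNS = ["patient_id", "timestamp", "action_code", "note"]

ACTION_CODES = frozenset("abcdefg")


class QualityLabel(str, Enum):
    """Outcome of the oximetry quality protocol for a session."""

    HIGH = "high"
    LOW_BEST_EFFORT = "low_best_effort"
    ABSENT = "absent"


class SchemaError(ValueError):
    """File-level problem: missing file content, wrong or missing columns."""


class RowError(ValueError):
    """Row-level invariant violation; carries the row index and field name."""

    def __init__(self, row: int, fieldname: str, message: str):
        self.row = row
        self.field = fieldname
        super().__init__(f"row {row}, field '{fieldname}': {message}")


@dataclass(frozen=True)
class MonitoringSession:
    """One patient-day record.

    Invariants enforced on construction:

    * ``diary_answers``, when present, has exactly 9 integer entries;
    * ``spo2_percent`` and ``pulse_rate_bpm`` are present together or absent
      together;
    * ``quality_label`` is ``absent`` iff both vitals are absent;
    * the timestamp is minute resolution (zero seconds/microseconds).

    The per-item diary answer range is configuration (see
    :mod:`edgemonitor.questionnaires`) and is checked at file-read time,
    not here.
    """

    patient_id: str
    timestamp: datetime
    diary_answers: tuple[int, ...] | None = None
    diary_completion_seconds: float | None = None
    spo2_percent: float | None = None
    pulse_rate_bpm: float | None = None
    quality_label: QualityLabel = QualityLabel.ABSENT
    attempt_count: int = 0

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be a nonempty string")
        if self.timestamp.second or self.timestamp.microsecond:
            raise ValueError("timestamps are minute resolution")
        if self.diary_answers is not None:
            if len(self.diary_answers) != N_DIARY_ITEMS:
                raise ValueError(
                    f"diary_answers must have exactly {N_DIARY_ITEMS} entries, "
                    f"got {len(self.diary_answers)}"
                )
            if not all(isinstance(a, int) and not isinstance(a, bool) for a in self.diary_answers):
                raise ValueError("diary answers must be integers")
        if self.diary_completion_seconds is not None and self.diary_completion_seconds < 0:
            raise ValueError("diary_completion_seconds must be nonnegative")
        has_spo2 = self.spo2_percent is not None
        has_pulse = self.pulse_rate_bpm is not None
        if has_spo2 != has_pulse:
            raise ValueError("spo2_percent and pulse_rate_bpm must be present together")
        if has_spo2:
            if not (0.0 <= self.spo2_percent <= 100.0):
                raise ValueError("spo2_percent must lie in [0, 100]")
            if self.pulse_rate_bpm <= 0:
                raise ValueError("pulse_rate_bpm must be positive")
            if self.quality_label is QualityLabel.ABSENT:
                raise ValueError("vitals present but quality_label is 'absent'")
        elif self.quality_label is not QualityLabel.ABSENT:
            raise ValueError("quality_label must be 'absent' when vitals are absent")
        if self.attempt_count not in (0, 1, 2):
            raise ValueError("attempt_count must be 0, 1 or 2")

    @property
    def has_vitals(self) -> bool:
        return self.spo2_percent is not None

    @property
    def symptom_score(self) -> int | None:
        """Total diary score (sum of the 9 item values), or None if no diary."""
        if self.diary_answers is None:
            return None
        return sum(self.diary_answers)


@dataclass(frozen=True)
class VitalsStream:
    """Raw per-session oximeter output at the vitals sample rate (3 Hz).

    ``sqi_flags[i]`` is True when sample ``i`` is artefact-free according to
    the oximeter's signal-quality index.
    """

    sample_rate_hz: float
    spo2_samples: tuple[float, ...]
    pulse_samples: tuple[float, ...]
    sqi_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n = len(self.spo2_samples)
        if len(self.pulse_samples) != n or len(self.sqi_flags) != n:
            raise ValueError("spo2, pulse and sqi sequences must have equal length")


@dataclass(frozen=True)
class ReviewAction:
    """A nurse's alert-dismissal action on a patient profile.

    The seven action codes mirror the community-nurse workflow:
    a) diary reviewed, no action; b) GP/practice nurse contacted;
    c) respiratory nurse contacted; d) community respiratory nurse handover;
    e) patient contacted directly; f) letter to GP after a mood-questionnaire
    alert; g) sign-off tick.  Actions e and g suppress alerts for 3 days.
    """

    patient_id: str
    timestamp: datetime
    action_code: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.action_code not in ACTION_CODES:
            raise ValueError(
                f"unknown action code {self.action_code!r}; expected one of a-g"
            )


@dataclass
class CohortTable:
    """A validated bundle of sessions + review actions for a patient cohort.

    Sessions are kept sorted by (patient_id, timestamp) and every referenced
    patient_id appears in ``patients``.
    """

    sessions: list[MonitoringSession] = field(default_factory=list)
    actions: list[ReviewAction] = field(default_factory=list)
    patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.patients)
        for s in self.sessions:
            if s.patient_id not in known:
                raise ValueError(f"session patient_id {s.patient_id!r} not in patients")
        for a in self.actions:
            if a.patient_id not in known:
                raise ValueError(f"action patient_id {a.patient_id!r} not in patients")
        key = [(s.patient_id, s.timestamp) for s in self.sessions]
        if key != sorted(key):
            raise ValueError("sessions must be sorted by (patient_id, timestamp)")

    @classmethod
    def from_parts(
        cls,
        sessions: Iterable[MonitoringSession],
        actions: Iterable[ReviewAction] = (),
        patients: Iterable[str] | None = None,
    ) -> "CohortTable":
        """Build a table, sorting sessions and inferring the patient list."""
        sessions = sorted(sessions, key=lambda s: (s.patient_id, s.timestamp))
        actions = list(actions)
        if patients is None:
            ids = {s.patient_id for s in sessions} | {a.patient_id for a in actions}
            patients = sorted(ids)
        return cls(sessions=sessions, actions=actions, patients=list(patients))

    def sessions_for(self, patient_id: str) -> list[MonitoringSession]:
        return [s for s in self.sessions if s.patient_id == patient_id]


# ---------------------------------------------------------------------------
# serialisation helpers

def _fmt_num(v: float | int | None) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(v)


def _parse_float(raw: str, row: int, name: str) -> float | None:
    if raw == "":
        return None
    try:
        v = float(raw)
    except ValueError:
        raise RowError(row, name, f"not a number: {raw!r}") from None
    if not math.isfinite(v):
        raise RowError(row, name, f"non-finite value: {raw!r}")
    return v


def _parse_int(raw: str, row: int, name: str) -> int | None:
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError:
        raise RowError(row, name, f"not an integer: {raw!r}") from None


def _parse_timestamp(raw: str, row: int) -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except ValueError:
        raise RowError(row, "timestamp", f"not ISO-8601: {raw!r}") from None


def _session_to_record(s: MonitoringSession) -> dict[str, str]:
    rec = {"patient_id": s.patient_id, "timestamp": s.timestamp.isoformat(timespec="minutes")}
    for i in range(N_DIARY_ITEMS):
        rec[f"q{i + 1}"] = "" if s.diary_answers is None else str(s.diary_answers[i])
    rec["diary_seconds"] = _fmt_num(s.diary_completion_seconds)
    rec["spo2"] = _fmt_num(s.spo2_percent)
    rec["pulse"] = _fmt_num(s.pulse_rate_bpm)
    rec["quality"] = s.quality_label.value
    rec["attempts"] = str(s.attempt_count)
    return rec


def _session_from_record(
    rec: dict[str, object], row: int, item_range: tuple[int, int]
) -> MonitoringSession:
    def get(name: str) -> str:
        v = rec.get(name)
        return "" if v is None else str(v)

    answers_raw = [get(f"q{i}") for i in range(1, N_DIARY_ITEMS + 1)]
    present = [a for a in answers_raw if a != ""]
    if present and len(present) != N_DIARY_ITEMS:
        raise RowError(
            row, "q1..q9",
            f"diary must have all {N_DIARY_ITEMS} answers or none; got {len(present)}",
        )
    answers: tuple[int, ...] | None = None
    if present:
        parsed = []
        lo, hi = item_range
        for i, raw in enumerate(answers_raw, start=1):
            v = _parse_int(raw, row, f"q{i}")
            if not (lo <= v <= hi):
                raise RowError(row, f"q{i}", f"answer {v} outside item range [{lo}, {hi}]")
            parsed.append(v)
        answers = tuple(parsed)

    quality_raw = get("quality") or "absent"
    try:
        quality = QualityLabel(quality_raw)
    except ValueError:
        raise RowError(row, "quality", f"unknown quality label {quality_raw!r}") from None

    attempts = _parse_int(get("attempts") or "0", row, "attempts")
    try:
        return MonitoringSession(
            patient_id=get("patient_id"),
            timestamp=_parse_timestamp(get("timestamp"), row),
            diary_answers=answers,
            diary_completion_seconds=_parse_float(get("diary_seconds"), row, "diary_seconds"),
            spo2_percent=_parse_float(get("spo2"), row, "spo2"),
            pulse_rate_bpm=_parse_float(get("pulse"), row, "pulse"),
            quality_label=quality,
            attempt_count=attempts,
        )
    except ValueError as exc:
        raise RowError(row, "session", str(exc)) from None


def read_sessions(
    path: str | Path,
    dialect: str = "csv",
    item_range: tuple[int, int] = (0, 3),
) -> CohortTable:
    """Read a sessions file into a validated :class:`CohortTable`.

    ``dialect`` is ``"csv"`` (fixed header) or ``"jsonl"`` (one object per
    line with the same field names).  Rows violating the schema raise
    :class:`RowError` naming the 1-based data row and the offending field.
    The table's action log is empty; see :func:`read_actions`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sessions: list[MonitoringSession] = []
    if dialect == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, expected header")
            if list(reader.fieldnames) != SESSION_COLUMNS:
                raise SchemaError(
                    f"{path}: bad header {reader.fieldnames}; expected {SESSION_COLUMNS}"
                )
            for row_idx, rec in enumerate(reader, start=1):
                sessions.append(_session_from_record(rec, row_idx, item_range))
    elif dialect == "jsonl":
        with path.open() as fh:
            for row_idx, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}: line {row_idx} is not valid JSON: {exc}")
                unknown = set(rec) - set(SESSION_COLUMNS)
                if unknown:
                    raise SchemaError(f"{path}: line {row_idx} has unknown keys {sorted(unknown)}")
                sessions.append(_session_from_record(rec, row_idx, item_range))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'jsonl'")
    return CohortTable.from_parts(sessions)


def write_sessions(table: CohortTable, path: str | Path, dialect: str = "csv") -> Path:
    """Write the table's sessions with deterministic column order and formatting.

    Timestamps are ISO-8601 at minute resolution; absent values are empty
    CSV cells / JSON nulls.  Writing the same table twice produces
    byte-identical files.
    """
    path = Path(path)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=SESSION_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for s in table.sessions:
                writer.writerow(_session_to_record(s))
    elif dialect == "jsonl":
        with path.open("w") as fh:
            for s in table.sessions:
                rec = _session_to_record(s)
                obj = {k: (None if v == "" else v) for k, v in rec.items()}
                # numeric fields as numbers, not strings
                for k in ("diary_seconds", "spo2", "pulse"):
                    if obj[k] is not None:
                        obj[k] = float(obj[k])
                for k in [f"q{i}" for i in range(1, N_DIARY_ITEMS + 1)] + ["attempts"]:
                    if obj[k] is not None:
                        obj[k] = int(obj[k])
                fh.write(json.dumps(obj, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'jsonl'")
    return path


def read_actions(path: str | Path) -> list[ReviewAction]:
    """Read the nurse review-action CSV (patient_id,timestamp,action_code,note)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    actions: list[ReviewAction] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != ACTION_COLUMNS:
            raise SchemaError(
                f"{path}: bad header {reader.fieldnames}; expected {ACTION_COLUMNS}"
            )
        for row_idx, rec in enumerate(reader, start=1):
            try:
                actions.append(
                    ReviewAction(
                        patient_id=rec["patient_id"],
                        timestamp=_parse_timestamp(rec["timestamp"], row_idx),
                        action_code=rec["action_code"],
                        note=rec.get("note") or "",
                    )
                )
            except RowError:
                raise
            except ValueError as exc:
                raise RowError(row_idx, "action_code", str(exc)) from None
    return actions


def write_actions(actions: Sequence[ReviewAction], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=ACTION_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for a in actions:
            writer.writerow(
                {
                    "patient_id": a.patient_id,
                    "timestamp": a.timestamp.isoformat(timespec="minutes"),
                    "action_code": a.action_code,
                    "note": a.note,
                }
            )
    return path
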