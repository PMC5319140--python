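"""Compliance, habit, learning-curve and nurse-workload analytics.

Patient compliance is the number of distinct days per week with at least
one monitoring session (maximum 7).  Cohort compliance is summarised per
calendar month as the mean (sd) of patient-week values, excluding months
with too few active participants to be meaningful.  The learning curve is
tracked by the empirical CDF of diary completion times for each month in
the study (months counted from each patient's own enrolment), which drifts
leftward as patients become proficient.  Time-of-day habit is summarised
circularly (modal hour and the fraction of sessions within ±2 h of it).
Nurse workload is tallied from the review-action log as per-action totals,
per-patient means and per-month rates.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .sessions_io import ACTION_CODES, CohortTable, MonitoringSession, QualityLabel, ReviewAction

__all__ = [
    "ComplianceSeries",
    "MonthlyCompliance",
    "CompletionCdf",
    "HabitStats",
    "ActionReport",
    "DataQualitySummary",
    "weekly_compliance",
    "cohort_monthly_compliance",
    "completion_time_cdf",
    "habitual_time_stats",
    "nurse_action_report",
    "quality_percentages",
    "data_quality_summary",
]

DAYS_PER_STUDY_MONTH = 30


@dataclass(frozen=True)
class MonthlyCompliance:
    year: int
    month: int
    mean: float | None
    sd: float | None
    n_patients: int
    n_patient_weeks: int
    excluded: bool


@dataclass(frozen=True)
class ComplianceSeries:
    """Weekly patient-level day counts plus cohort monthly summaries."""

    weekly: Mapping[tuple[str, date], int]  # (patient_id, week_start) -> days used
    monthly: tuple[MonthlyCompliance, ...]

    def __post_init__(self) -> None:
        for (pid, wk), v in self.weekly.items():
            if not 0 <= v <= 7:
                raise ValueError(f"weekly compliance {v} for {pid} week {wk} outside [0, 7]")


@dataclass(frozen=True)
class CompletionCdf:
    """Empirical CDF of diary completion times for one month in the study."""

    month_in_study: int
    times: tuple[float, ...]  # sorted, seconds

    def __post_init__(self) -> None:
        if not self.times:
            raise ValueError(f"no completion times for month {self.month_in_study}")
        if list(self.times) != sorted(self.times):
            raise ValueError("times must be sorted")

    def __call__(self, x: float) -> float:
        """Right-continuous empirical CDF: fraction of times ≤ x."""
        return float(np.searchsorted(self.times, x, side="right")) / len(self.times)


@dataclass(frozen=True)
class HabitStats:
    modal_hour: int
    fraction_within_2h: float
    n_sessions: int


@dataclass(frozen=True)
class ActionReport:
    totals: Mapping[str, int]
    per_patient_mean: Mapping[str, float]
    per_patient_sd: Mapping[str, float]
    per_month_rate: Mapping[str, float]
    months_per_patient: float
    n_patients: int


@dataclass(frozen=True)
class DataQualitySummary:
    n_vitals_sessions: int
    n_high: int
    n_low: int
    n_diary_only: int
    pct_high: float
    pct_low: float


def weekly_compliance(
    sessions: Sequence[MonitoringSession], patient_id: str, week_start: date
) -> int:
    """Distinct days with ≥1 session for the patient in the 7-day week
    starting at ``week_start``.  Duplicate sessions on a day count once."""
    week_end = week_start + timedelta(days=7)
    days = {
        s.timestamp.date()
        for s in sessions
        if s.patient_id == patient_id and week_start <= s.timestamp.date() < week_end
    }
    return len(days)


def _patient_weeks(
    sessions: Sequence[MonitoringSession],
) -> dict[tuple[str, date], int]:
    """Per-patient consecutive 7-day blocks anchored at each patient's first
    session day, mapped to distinct-day counts."""
    by_patient: dict[str, list[date]] = defaultdict(list)
    for s in sessions:
        by_patient[s.patient_id].append(s.timestamp.date())
    out: dict[tuple[str, date], int] = {}
    for pid, days in by_patient.items():
        first, last = min(days), max(days)
        day_set = set(days)
        wk = first
        while wk <= last:
            end = wk + timedelta(days=7)
            out[(pid, wk)] = sum(1 for d in day_set if wk <= d < end)
            wk = end
    return out


def cohort_monthly_compliance(
    table: CohortTable | Sequence[MonitoringSession],
    min_participants: int = 5,
) -> ComplianceSeries:
    """Cohort compliance summarised per calendar month.

    Weeks are consecutive 7-day blocks from each patient's first session;
    a week contributes to the calendar month containing its start.  A
    patient is *active* in a month when they have ≥1 session that month;
    months with fewer than ``min_participants`` active patients are kept
    in the output but flagged excluded (mean/sd set to None).
    """
    sessions = table.sessions if isinstance(table, CohortTable) else list(table)
    weekly = _patient_weeks(sessions)

    active: dict[tuple[int, int], set[str]] = defaultdict(set)
    for s in sessions:
        active[(s.timestamp.year, s.timestamp.month)].add(s.patient_id)

    month_values: dict[tuple[int, int], list[int]] = defaultdict(list)
    for (pid, wk), count in weekly.items():
        month_values[(wk.year, wk.month)].append(count)

    monthly: list[MonthlyCompliance] = []
    for ym in sorted(set(active) | set(month_values)):
        vals = np.asarray(month_values.get(ym, []), dtype=float)
        n_pat = len(active.get(ym, ()))
        excluded = n_pat < min_participants
        if excluded or vals.size == 0:
            mean = sd = None
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        monthly.append(
            MonthlyCompliance(
                year=ym[0],
                month=ym[1],
                mean=mean,
                sd=sd,
                n_patients=n_pat,
                n_patient_weeks=int(vals.size),
                excluded=excluded,
            )
        )
    return ComplianceSeries(weekly=weekly, monthly=tuple(monthly))


def completion_time_cdf(
    sessions: Sequence[MonitoringSession],
    month_in_study: int,
    enrolment: Mapping[str, datetime] | None = None,
    days_per_month: int = DAYS_PER_STUDY_MONTH,
) -> CompletionCdf:
    """Empirical CDF of diary completion times for one month in the study.

    Month ``m`` (1-based) covers study days [(m−1)·30, m·30) counted from
    each patient's enrolment (their first session unless given).  Times
    are pooled across patients.  Raises ``ValueError`` when the month has
    no diary completion times.
    """
    if month_in_study < 1:
        raise ValueError("month_in_study is 1-based")
    if enrolment is None:
        enrol: dict[str, datetime] = {}
        for s in sessions:
            if s.patient_id not in enrol or s.timestamp < enrol[s.patient_id]:
                enrol[s.patient_id] = s.timestamp
    else:
        enrol = dict(enrolment)

    lo, hi = (month_in_study - 1) * days_per_month, month_in_study * days_per_month
    times = []
    for s in sessions:
        if s.diary_completion_seconds is None:
            continue
        start = enrol.get(s.patient_id)
        if start is None:
            continue
        day = (s.timestamp.date() - start.date()).days
        if lo <= day < hi:
            times.append(float(s.diary_completion_seconds))
    if not times:
        raise ValueError(f"no completion-time data for month {month_in_study}")
    return CompletionCdf(month_in_study=month_in_study, times=tuple(sorted(times)))


def _circular_distance_hours(a: float, b: float) -> float:
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


def habitual_time_stats(
    sessions: Sequence[MonitoringSession],
    patient_id: str,
    min_sessions: int = 10,
    window_hours: float = 2.0,
) -> HabitStats:
    """Modal session hour (24 circular hourly bins) and the fraction of the
    patient's sessions within ±``window_hours`` of it (wraparound honoured,
    boundary inclusive).  Ties in the histogram resolve to the earliest
    hour."""
    times = [
        s.timestamp.hour + s.timestamp.minute / 60.0
        for s in sessions
        if s.patient_id == patient_id
    ]
    if len(times) < min_sessions:
        raise ValueError(
            f"patient {patient_id}: {len(times)} sessions, needs {min_sessions} "
            "for habit analysis"
        )
    hours = [int(t) % 24 for t in times]
    counts = Counter(hours)
    modal_hour = max(range(24), key=lambda h: (counts.get(h, 0), -h))
    within = sum(
        1 for t in times if _circular_distance_hours(t, float(modal_hour)) <= window_hours
    )
    return HabitStats(
        modal_hour=modal_hour,
        fraction_within_2h=within / len(times),
        n_sessions=len(times),
    )


def nurse_action_report(
    actions: Sequence[ReviewAction],
    patients: Sequence[str],
    months_per_patient: float = 12.0,
) -> ActionReport:
    """Per-action totals, per-patient means ± sd, and per-month rates.

    Patients with no logged actions contribute zeros to the means, so
    ``per_month_rate = per_patient_mean / months_per_patient`` exactly (no
    internal rounding; round only at presentation).
    """
    if months_per_patient <= 0:
        raise ValueError("months_per_patient must be positive")
    if not patients:
        raise ValueError("patient list must be nonempty")
    patients = list(patients)
    for a in actions:
        if a.action_code not in ACTION_CODES:  # ReviewAction already validates; belt-and-braces
            raise ValueError(f"unknown action code {a.action_code!r}")

    per_patient: dict[str, Counter] = {p: Counter() for p in patients}
    for a in actions:
        if a.patient_id not in per_patient:
            raise ValueError(f"action for unknown patient {a.patient_id!r}")
        per_patient[a.patient_id][a.action_code] += 1

    codes = sorted(ACTION_CODES)
    totals = {c: sum(per_patient[p][c] for p in patients) for c in codes}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    rate: dict[str, float] = {}
    for c in codes:
        counts = np.asarray([per_patient[p][c] for p in patients], dtype=float)
        mean[c] = float(counts.mean())
        sd[c] = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        rate[c] = mean[c] / months_per_patient
    return ActionReport(
        totals=totals,
        per_patient_mean=mean,
        per_patient_sd=sd,
        per_month_rate=rate,
        months_per_patient=months_per_patient,
        n_patients=len(patients),
    )


def quality_percentages(n_high: int, n_low: int, ndigits: int = 1) -> tuple[float, float]:
    """High/low-quality percentages of the oximetry sessions, rounded for
    presentation (one decimal by default)."""
    total = n_high + n_low
    if total <= 0:
        raise ValueError("no oximetry sessions")
    return (
        round(100.0 * n_high / total, ndigits),
        round(100.0 * n_low / total, ndigits),
    )


def data_quality_summary(
    sessions: Sequence[MonitoringSession], ndigits: int = 1
) -> DataQualitySummary:
    """Tally session quality labels and derive the high/low percentages."""
    n_high = sum(1 for s in sessions if s.quality_label is QualityLabel.HIGH)
    n_low = sum(1 for s in sessions if s.quality_label is QualityLabel.LOW_BEST_EFFORT)
    n_diary_only = sum(1 for s in sessions if not s.has_vitals)
    pct_high, pct_low = quality_percentages(n_high, n_low, ndigits)
    return DataQualitySummary(
        n_vitals_sessions=n_high + n_low,
        n_high=n_high,
        n_low=n_low,
        n_diary_only=n_diary_only,
        pct_high=pct_high,
        pct_low=pct_low,
    )
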