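"""Alert generation, clustering, prioritisation and nurse-review bookkeeping.

A session raises one alert per parameter whose observed value strictly
crosses that patient's personalised threshold in the alerting direction
(above for symptom score and pulse rate, below for SpO2).  Review actions
"patient contacted" (e) and "sign-off" (g) suppress a patient's alerts for
the following three days.  For workload reporting, alerts within a 7-day
window are clustered into episodes, and patients are ranked for review by
the number of alerts in the most recent two weeks since their last review.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

from .sessions_io import MonitoringSession, QualityLabel, ReviewAction
from .threshold_engine import Direction, Parameter, ThresholdSet

__all__ = [
    "Alert",
    "AlertCluster",
    "PatientState",
    "UntrainedParameterError",
    "SUPPRESSION_DAYS",
    "SUPPRESSING_ACTIONS",
    "evaluate_session",
    "cluster_alerts",
    "priority_score",
    "rank_patients",
    "apply_review_action",
    "replay_cohort",
]

SUPPRESSION_DAYS = 3
SUPPRESSING_ACTIONS = frozenset({"e", "g"})
CLUSTER_WINDOW_DAYS = 7
PRIORITY_WINDOW_DAYS = 14


class UntrainedParameterError(KeyError):
    """A session carries a parameter with no trained threshold."""


@dataclass(frozen=True)
class Alert:
    patient_id: str
    timestamp: datetime
    parameter: Parameter
    observed_value: float
    threshold_value: float
    direction: Direction
    quality_caveat: bool = False  # vitals were best-effort quality

    def __post_init__(self) -> None:
        if self.direction is Direction.ALERT_ABOVE:
            ok = self.observed_value > self.threshold_value
        else:
            ok = self.observed_value < self.threshold_value
        if not ok:
            raise ValueError(
                f"alert invariant violated: {self.observed_value} does not cross "
                f"{self.threshold_value} ({self.direction.value})"
            )


@dataclass(frozen=True)
class AlertCluster:
    """A maximal run of alerts starting within 7 days of the first one."""

    patient_id: str
    alerts: tuple[Alert, ...]

    def __post_init__(self) -> None:
        if not self.alerts:
            raise ValueError("cluster must be nonempty")
        times = [a.timestamp for a in self.alerts]
        if times != sorted(times):
            raise ValueError("cluster alerts must be time-sorted")
        if self.end - self.start > timedelta(days=CLUSTER_WINDOW_DAYS):
            raise ValueError("cluster spans more than the clustering window")

    @property
    def start(self) -> datetime:
        return self.alerts[0].timestamp

    @property
    def end(self) -> datetime:
        return self.alerts[-1].timestamp


@dataclass(frozen=True)
class PatientState:
    """Review bookkeeping for one patient."""

    patient_id: str
    last_review: datetime | None = None
    suppress_until: datetime | None = None
    action_log: tuple[ReviewAction, ...] = ()


def evaluate_session(
    session: MonitoringSession,
    thresholds: ThresholdSet,
    state: PatientState | None = None,
    include_best_effort: bool = True,
) -> list[Alert]:
    """Alerts raised by one session (0–3, one per crossed parameter).

    Crossings are strict: a value exactly on the threshold does not alert.
    A session inside the patient's 3-day suppression window raises nothing.
    Best-effort-quality vitals still alert by default but the alerts carry
    ``quality_caveat=True``; set ``include_best_effort=False`` to skip their
    vitals entirely (the symptom score is diary-based and always evaluated).
    """
    if state is not None and state.suppress_until is not None:
        if session.timestamp < state.suppress_until:
            return []

    best_effort = session.quality_label is QualityLabel.LOW_BEST_EFFORT
    observed: list[tuple[Parameter, float, bool]] = []
    if session.symptom_score is not None:
        observed.append((Parameter.SYMPTOM_SCORE, float(session.symptom_score), False))
    if session.has_vitals and (include_best_effort or not best_effort):
        observed.append((Parameter.SPO2, float(session.spo2_percent), best_effort))
        observed.append((Parameter.PULSE_RATE, float(session.pulse_rate_bpm), best_effort))

    alerts: list[Alert] = []
    for p, value, caveat in observed:
        if p not in thresholds:
            raise UntrainedParameterError(
                f"patient {session.patient_id}: no trained threshold for {p.value}"
            )
        t = thresholds[p]
        crossed = value > t.value if t.direction is Direction.ALERT_ABOVE else value < t.value
        if crossed:
            alerts.append(
                Alert(
                    patient_id=session.patient_id,
                    timestamp=session.timestamp,
                    parameter=p,
                    observed_value=value,
                    threshold_value=t.value,
                    direction=t.direction,
                    quality_caveat=caveat,
                )
            )
    return alerts


def cluster_alerts(alerts: Sequence[Alert], window_days: int = CLUSTER_WINDOW_DAYS) -> list[AlertCluster]:
    """Greedy left-to-right clustering of one patient's time-sorted alerts.

    A new cluster starts at the first alert strictly more than
    ``window_days`` after the current cluster's start, so each cluster spans
    at most ``window_days``.  Every alert lands in exactly one cluster.
    """
    if not alerts:
        return []
    times = [a.timestamp for a in alerts]
    if times != sorted(times):
        raise ValueError("alerts must be time-sorted")
    pids = {a.patient_id for a in alerts}
    if len(pids) != 1:
        raise ValueError("cluster_alerts expects a single patient's alerts")

    window = timedelta(days=window_days)
    clusters: list[AlertCluster] = []
    current: list[Alert] = [alerts[0]]
    start = alerts[0].timestamp
    for a in alerts[1:]:
        if a.timestamp - start > window:
            clusters.append(AlertCluster(patient_id=a.patient_id, alerts=tuple(current)))
            current = [a]
            start = a.timestamp
        else:
            current.append(a)
    clusters.append(AlertCluster(patient_id=alerts[0].patient_id, alerts=tuple(current)))
    return clusters


def priority_score(
    alerts: Sequence[Alert],
    state: PatientState,
    now: datetime,
    window_days: int = PRIORITY_WINDOW_DAYS,
) -> int:
    """Number of alerts in the most recent two weeks since the last review.

    Counts alerts with timestamp in (max(now − window, last_review), now]:
    the intersection of the trailing two-week window with the post-review
    period.  Both bounds are exclusive at the left, inclusive at ``now``.
    """
    lower = now - timedelta(days=window_days)
    if state.last_review is not None and state.last_review > lower:
        lower = state.last_review
    return sum(1 for a in alerts if lower < a.timestamp <= now)


def rank_patients(
    cohort: Mapping[str, tuple[Sequence[Alert], PatientState]],
    now: datetime,
    window_days: int = PRIORITY_WINDOW_DAYS,
) -> list[tuple[str, int]]:
    """Rank patients for nurse review, most urgent first.

    Descending priority score; ties broken by most-recent alert first, then
    patient_id lexicographically — fully deterministic regardless of input
    order.
    """
    rows = []
    for pid, (alerts, state) in cohort.items():
        score = priority_score(alerts, state, now, window_days)
        latest = max((a.timestamp for a in alerts), default=datetime.min)
        rows.append((pid, score, latest))
    rows.sort(key=lambda r: (-r[1], datetime.max - r[2], r[0]))
    return [(pid, score) for pid, score, _ in rows]


def apply_review_action(state: PatientState, action: ReviewAction) -> PatientState:
    """Fold one review action into the patient's state.

    Every action updates ``last_review`` and is appended to the log;
    actions e and g additionally set ``suppress_until`` to the action time
    plus three days (a later suppressing action overwrites an earlier one).
    """
    if action.patient_id != state.patient_id:
        raise ValueError(
            f"action for {action.patient_id!r} applied to state of {state.patient_id!r}"
        )
    suppress = state.suppress_until
    if action.action_code in SUPPRESSING_ACTIONS:
        suppress = action.timestamp + timedelta(days=SUPPRESSION_DAYS)
    return replace(
        state,
        last_review=action.timestamp,
        suppress_until=suppress,
        action_log=state.action_log + (action,),
    )


def replay_cohort(
    sessions: Sequence[MonitoringSession],
    actions: Sequence[ReviewAction],
    thresholds_by_patient: Mapping[str, ThresholdSet],
    include_best_effort: bool = True,
) -> tuple[dict[str, list[Alert]], dict[str, PatientState]]:
    """Replay a cohort's history chronologically, interleaving sessions and
    review actions, and return per-patient alert streams and final states.

    Sessions without a trained threshold set for their patient are skipped
    (their patient is still in the run-in period).
    """
    events: list[tuple[datetime, int, object]] = []
    events += [(s.timestamp, 0, s) for s in sessions]
    # actions sort after sessions at the same instant: review follows data
    events += [(a.timestamp, 1, a) for a in actions]
    events.sort(key=lambda e: (e[0], e[1]))

    states: dict[str, PatientState] = {}
    alert_streams: dict[str, list[Alert]] = {}
    for _, kind, ev in events:
        pid = ev.patient_id  # type: ignore[attr-defined]
        state = states.setdefault(pid, PatientState(patient_id=pid))
        if kind == 0:
            ts = thresholds_by_patient.get(pid)
            if ts is None:
                continue
            alert_streams.setdefault(pid, []).extend(
                evaluate_session(ev, ts, state, include_best_effort=include_best_effort)
            )
        else:
            states[pid] = apply_review_action(state, ev)
    return alert_streams, states
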