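"""Synthetic monitoring cohorts with the statistical structure of home
COPD self-monitoring data.

Each simulated patient has their own physiological baselines (SpO2 and
pulse-rate truncated normals, an ordinal symptom-item distribution), a
diurnal usage habit (a preferred clock hour with Gaussian jitter), ~6/7
daily adherence, a learning curve in diary completion time, motion-artefact
sessions resolved through the oximetry acquisition protocol, and episodic
exacerbations during which SpO2 falls while pulse rate and symptom burden
rise.  A ground-truth log records the generating parameters, exacerbation
intervals and any injected baseline shifts, so detector and threshold
behaviour can be asserted against what was actually simulated.

Everything is deterministic under the cohort master seed: per-patient
generators are derived with ``numpy.random.SeedSequence`` spawn keys, so
the same seed reproduces the cohort byte-for-byte and adding patients does
not reshuffle existing ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np

from .oximetry_quality import (
    ProtocolConfig,
    RecordingAttempt,
    quality_label_for,
    run_protocol,
    synthesize_ppg,
)
from .sessions_io import CohortTable, MonitoringSession, QualityLabel
from .threshold_engine import Parameter

__all__ = [
    "PatientParams",
    "CohortConfig",
    "ShiftRecord",
    "PatientTruth",
    "CohortTruth",
    "truncated_normal",
    "draw_patient_params",
    "simulate_patient",
    "simulate_cohort",
    "inject_baseline_shift",
]

# Artefact geometry (seconds into the recording) used to realise the three
# per-attempt severities through the acquisition protocol:
#  - clean: no artefact segments;
#  - recoverable: artefact over the first 5 s, so the base 30 s window holds
#    only a 25 s clean run but the 10 s extension yields 35 s;
#  - unrecoverable: artefacts at 18-19 s and (when extended) 38-39 s, so no
#    window ever contains a 30 s clean run.
_RECOVERABLE_SEGMENTS = ((0.0, 5.0),)
_UNRECOVERABLE_SEGMENTS = ((18.0, 19.0), (38.0, 39.0))


@dataclass(frozen=True)
class PatientParams:
    """Generating parameters for one simulated patient.

    Defaults encode a plausible moderate-COPD home-monitoring profile;
    per-patient values are drawn from the ranges in :class:`CohortConfig`.
    ``artifact_attempt_prob`` (q) is the chance a recording attempt carries
    artefact, and ``extension_recovery_prob`` (r) the chance the 10 s
    extension rescues such an attempt; with two independent attempts the
    best-effort session fraction is (q·(1−r))² ≈ 6.7% at the defaults.
    """

    spo2_baseline_mean: float = 92.0
    spo2_sd: float = 1.4
    pulse_baseline_mean: float = 80.0
    pulse_sd: float = 5.0
    symptom_item_probs: tuple[float, ...] = (0.55, 0.30, 0.10, 0.05)
    adherence_prob: float = 6.0 / 7.0
    habit_hour: float = 9.0
    habit_jitter_sd: float = 1.0
    vitals_prob: float = 0.89  # remaining sessions are diary-only
    artifact_attempt_prob: float = 0.37
    extension_recovery_prob: float = 0.30
    exacerbation_rate_per_year: float = 2.0
    exacerbation_spo2_drop: float = 4.0
    exacerbation_pulse_rise: float = 10.0
    exacerbation_symptom_rise: float = 6.0
    exacerbation_duration_mean_days: float = 7.0
    completion_initial_median_s: float = 150.0
    completion_final_median_s: float = 60.0
    completion_tau_days: float = 25.0
    completion_sigma: float = 0.30

    def __post_init__(self) -> None:
        for name in ("adherence_prob", "vitals_prob", "artifact_attempt_prob",
                     "extension_recovery_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not math.isclose(sum(self.symptom_item_probs), 1.0, abs_tol=1e-9):
            raise ValueError("symptom_item_probs must sum to 1")
        if min(self.symptom_item_probs) < 0:
            raise ValueError("symptom_item_probs must be nonnegative")
        if self.spo2_baseline_mean > 100.0:
            raise ValueError("spo2 baseline cannot exceed 100%")
        if self.spo2_sd <= 0 or self.pulse_sd <= 0:
            raise ValueError("vitals sds must be positive")
        if self.exacerbation_rate_per_year < 0:
            raise ValueError("exacerbation rate must be nonnegative")
        if self.exacerbation_duration_mean_days < 1:
            raise ValueError("exacerbation mean duration must be >= 1 day")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulator settings and per-patient draw ranges."""

    n_patients: int = 110
    follow_up_days: int = 365
    seed: int = 0
    start_date: date = date(2021, 1, 4)
    spo2_mean_range: tuple[float, float] = (88.0, 96.0)
    spo2_sd_range: tuple[float, float] = (0.8, 2.0)
    pulse_mean_range: tuple[float, float] = (65.0, 95.0)
    pulse_sd_range: tuple[float, float] = (3.0, 8.0)
    habit_hour_range: tuple[float, float] = (6.0, 23.0)
    base_params: PatientParams = field(default_factory=PatientParams)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.follow_up_days < 1:
            raise ValueError("follow_up_days must be >= 1")


@dataclass(frozen=True)
class ShiftRecord:
    day: int
    parameter: Parameter
    magnitude: float


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    params: PatientParams
    exacerbation_intervals: tuple[tuple[int, int], ...]  # [start_day, end_day)
    shifts: tuple[ShiftRecord, ...] = ()

    def in_exacerbation(self, day: int) -> bool:
        return any(a <= day < b for a, b in self.exacerbation_intervals)


@dataclass(frozen=True)
class CohortTruth:
    patients: Mapping[str, PatientTruth]

    def to_json(self) -> str:
        obj = {}
        for pid, t in self.patients.items():
            obj[pid] = {
                "params": asdict(t.params),
                "exacerbation_intervals": [list(iv) for iv in t.exacerbation_intervals],
                "shifts": [
                    {"day": s.day, "parameter": s.parameter.value, "magnitude": s.magnitude}
                    for s in t.shifts
                ],
            }
        return json.dumps(obj, indent=1)


def truncated_normal(
    rng: np.random.Generator,
    mean: float | np.ndarray,
    sd: float,
    size: int,
    upper: float = 100.0,
) -> np.ndarray:
    """Sample a normal truncated above at ``upper`` by vectorised rejection.

    Used for SpO2 day values (physical ceiling 100%).  Rejection keeps the
    analytic quantiles of the truncated law exact, unlike clipping, which
    would pile probability mass on the boundary.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    out = rng.normal(mean, sd)
    bad = out > upper
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = out > upper
    return out


def draw_patient_params(rng: np.random.Generator, config: CohortConfig) -> PatientParams:
    """Draw one patient's generating parameters from the cohort ranges."""
    return replace(
        config.base_params,
        spo2_baseline_mean=float(rng.uniform(*config.spo2_mean_range)),
        spo2_sd=float(rng.uniform(*config.spo2_sd_range)),
        pulse_baseline_mean=float(rng.uniform(*config.pulse_mean_range)),
        pulse_sd=float(rng.uniform(*config.pulse_sd_range)),
        habit_hour=float(rng.uniform(*config.habit_hour_range)),
    )


def _draw_exacerbations(
    rng: np.random.Generator, params: PatientParams, days: int
) -> tuple[tuple[int, int], ...]:
    lam = params.exacerbation_rate_per_year * days / 365.0
    n = int(rng.poisson(lam)) if lam > 0 else 0
    intervals = []
    for _ in range(n):
        start = int(rng.integers(0, days))
        dur = int(rng.geometric(1.0 / params.exacerbation_duration_mean_days))
        intervals.append((start, min(start + dur, days)))
    return tuple(sorted(intervals))


def _attempt_segments(category: int, duration_s: float) -> tuple[tuple[float, float], ...]:
    if category == 0:  # clean
        return ()
    if category == 1:  # recoverable by extension
        return _RECOVERABLE_SEGMENTS
    return tuple(seg for seg in _UNRECOVERABLE_SEGMENTS if seg[1] <= duration_s)


def _record_session_vitals(
    rng: np.random.Generator,
    params: PatientParams,
    spo2_day: float,
    pulse_day: float,
) -> tuple[float, float, QualityLabel, int]:
    """Acquire one session's vitals through the quality protocol."""
    # per-attempt severity: 0 clean, 1 recoverable, 2 unrecoverable
    cats = []
    for _ in range(2):
        if rng.random() >= params.artifact_attempt_prob:
            cats.append(0)
        elif rng.random() < params.extension_recovery_prob:
            cats.append(1)
        else:
            cats.append(2)
    seeds = [int(s) for s in rng.integers(0, 2**31, size=2)]

    def source(duration_s: float, attempt_idx: int) -> RecordingAttempt:
        cat = cats[attempt_idx - 1]
        return synthesize_ppg(
            duration_s,
            pulse_bpm=pulse_day,
            artifact_segments=_attempt_segments(cat, duration_s),
            seed=seeds[attempt_idx - 1],
            spo2_percent=spo2_day,
            include_ppg=False,
        )

    outcome = run_protocol(source, ProtocolConfig())
    spo2 = min(outcome.summary_spo2, 100.0)
    pulse = max(outcome.summary_pulse, 1.0)
    return spo2, pulse, quality_label_for(outcome.status), outcome.attempts_used


def simulate_patient(
    params: PatientParams,
    days: int,
    seed: int | np.random.SeedSequence,
    patient_id: str = "P001",
    start_date: date = date(2021, 1, 4),
) -> tuple[list[MonitoringSession], PatientTruth]:
    """Simulate one patient's session stream over ``days`` days.

    Each adherent day yields one session at the patient's habitual hour
    plus Gaussian jitter.  Day-level vitals are drawn from the (possibly
    exacerbation-shifted) baselines, then measured through the oximetry
    protocol on synthetic flag patterns; symptom items come from the
    ordinal item distribution with exacerbation-driven upward shifts.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(seq))

    exacerbations = _draw_exacerbations(rng, params, days)
    ex_delta = np.zeros(days)
    for a, b in exacerbations:
        ex_delta[a:b] = 1.0

    adherent = rng.random(days) < params.adherence_prob
    jitter = rng.normal(0.0, params.habit_jitter_sd, days)
    has_vitals = rng.random(days) < params.vitals_prob

    spo2_day = truncated_normal(
        rng, params.spo2_baseline_mean - params.exacerbation_spo2_drop * ex_delta,
        params.spo2_sd, days,
    )
    pulse_day = rng.normal(
        params.pulse_baseline_mean + params.exacerbation_pulse_rise * ex_delta,
        params.pulse_sd,
    )
    pulse_day = np.maximum(pulse_day, 1.0)

    n_levels = len(params.symptom_item_probs)
    items = rng.choice(n_levels, size=(days, 9), p=np.asarray(params.symptom_item_probs))
    extra = rng.poisson(params.exacerbation_symptom_rise / 9.0, size=(days, 9))
    items = np.minimum(items + extra * ex_delta[:, None].astype(int), n_levels - 1).astype(int)

    # learning curve: lognormal completion time with decaying median
    median_t = params.completion_final_median_s + (
        params.completion_initial_median_s - params.completion_final_median_s
    ) * np.exp(-np.arange(days) / params.completion_tau_days)
    completion = np.exp(
        np.log(median_t) + rng.normal(0.0, params.completion_sigma, days)
    )

    sessions: list[MonitoringSession] = []
    for d in range(days):
        if not adherent[d]:
            continue
        clock = params.habit_hour + jitter[d]
        clock = min(max(clock, 0.0), 23.983)  # clamp to the calendar day
        hour = int(clock)
        minute = int(round((clock - hour) * 60.0)) % 60
        ts = datetime.combine(start_date + timedelta(days=d), time(hour, minute))

        if has_vitals[d]:
            spo2, pulse, quality, attempts = _record_session_vitals(
                rng, params, float(spo2_day[d]), float(pulse_day[d])
            )
        else:
            spo2 = pulse = None
            quality, attempts = QualityLabel.ABSENT, 0

        sessions.append(
            MonitoringSession(
                patient_id=patient_id,
                timestamp=ts,
                diary_answers=tuple(int(v) for v in items[d]),
                diary_completion_seconds=round(float(completion[d]), 1),
                spo2_percent=spo2,
                pulse_rate_bpm=pulse,
                quality_label=quality,
                attempt_count=attempts,
            )
        )
    truth = PatientTruth(
        patient_id=patient_id, params=params, exacerbation_intervals=exacerbations
    )
    return sessions, truth


def simulate_cohort(config: CohortConfig) -> tuple[CohortTable, CohortTruth]:
    """Simulate a full cohort; deterministic under ``config.seed``."""
    width = max(3, len(str(config.n_patients)))
    all_sessions: list[MonitoringSession] = []
    truths: dict[str, PatientTruth] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        param_seq, sim_seq = seq.spawn(2)
        params = draw_patient_params(np.random.Generator(np.random.PCG64(param_seq)), config)
        sessions, truth = simulate_patient(
            params, config.follow_up_days, sim_seq, patient_id=pid,
            start_date=config.start_date,
        )
        all_sessions.extend(sessions)
        truths[pid] = truth
    table = CohortTable.from_parts(all_sessions, patients=sorted(truths))
    return table, CohortTruth(patients=truths)


def inject_baseline_shift(
    sessions: Sequence[MonitoringSession],
    day: int,
    parameter: Parameter,
    magnitude: float,
    truth: PatientTruth | None = None,
    item_max: int = 3,
) -> tuple[list[MonitoringSession], PatientTruth | None]:
    """Shift one parameter of a patient's series from ``day`` onwards.

    ``day`` counts from the date of the first session.  SpO2 and pulse
    values move by ``magnitude`` (SpO2 capped at 100, pulse floored above
    0); a symptom shift adds round(magnitude) distributed one unit at a
    time across the nine items, clipping at the item range, so the score
    moves by ``magnitude`` except near the scale boundary.  Returns the
    modified series and, when a :class:`PatientTruth` is supplied, a copy
    with the shift appended to its record.
    """
    if parameter not in (Parameter.SPO2, Parameter.PULSE_RATE, Parameter.SYMPTOM_SCORE):
        raise ValueError(f"unknown parameter {parameter!r}")
    if not sessions:
        raise ValueError("empty session list")
    if not 0 <= day <= (sessions[-1].timestamp.date() - sessions[0].timestamp.date()).days:
        raise ValueError(f"day {day} outside the series")

    first_day = sessions[0].timestamp.date()
    out: list[MonitoringSession] = []
    for s in sessions:
        if (s.timestamp.date() - first_day).days < day or magnitude == 0:
            out.append(s)
            continue
        if parameter is Parameter.SPO2 and s.spo2_percent is not None:
            out.append(replace(s, spo2_percent=min(max(s.spo2_percent + magnitude, 0.0), 100.0)))
        elif parameter is Parameter.PULSE_RATE and s.pulse_rate_bpm is not None:
            out.append(replace(s, pulse_rate_bpm=max(s.pulse_rate_bpm + magnitude, 1.0)))
        elif parameter is Parameter.SYMPTOM_SCORE and s.diary_answers is not None:
            items = list(s.diary_answers)
            remaining = int(round(abs(magnitude)))
            step = 1 if magnitude > 0 else -1
            idx = 0
            guard = 0
            while remaining > 0 and guard < 9:
                v = items[idx % 9] + step
                if 0 <= v <= item_max:
                    items[idx % 9] = v
                    remaining -= 1
                    guard = 0
                else:
                    guard += 1
                idx += 1
            out.append(replace(s, diary_answers=tuple(items)))
        else:
            out.append(s)

    record = ShiftRecord(day=day, parameter=parameter, magnitude=magnitude)
    new_truth = None
    if truth is not None:
        new_truth = replace(truth, shifts=truth.shifts + (record,))
    return out, new_truth
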