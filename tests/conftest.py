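from datetime import date, datetime, time, timedelta

import pytest

from edgemonitor.sessions_io import MonitoringSession, QualityLabel
from edgemonitor.synthetic_cohort import CohortConfig, PatientParams, simulate_cohort


def make_session(
    patient_id="P001",
    day=0,
    hour=9,
    minute=0,
    answers=(1, 0, 1, 0, 0, 1, 0, 0, 1),
    spo2=94.0,
    pulse=75.0,
    quality=QualityLabel.HIGH,
    diary_seconds=80.0,
    attempts=1,
    start=date(2021, 1, 4),
):
    """Hand-rolled valid session with overridable fields."""
    return MonitoringSession(
        patient_id=patient_id,
        timestamp=datetime.combine(start + timedelta(days=day), time(hour, minute)),
        diary_answers=None if answers is None else tuple(answers),
        diary_completion_seconds=diary_seconds,
        spo2_percent=spo2,
        pulse_rate_bpm=pulse,
        quality_label=quality if spo2 is not None else QualityLabel.ABSENT,
        attempt_count=attempts if spo2 is not None else 0,
    )


def spo2_series_sessions(values, patient_id="P001", start=date(2021, 1, 4)):
    """One session per day carrying the given SpO2 values (pulse held flat)."""
    return [
        make_session(patient_id=patient_id, day=i, spo2=float(v), pulse=75.0, start=start)
        for i, v in enumerate(values)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 6-patient, 100-day cohort with default behaviour."""
    table, truth = simulate_cohort(CohortConfig(n_patients=6, follow_up_days=100, seed=42))
    return table, truth


@pytest.fixture(scope="session")
def stationary_patient_params():
    """Fully adherent, artefact-free, exacerbation-free patient."""
    return PatientParams(
        adherence_prob=1.0,
        vitals_prob=1.0,
        artifact_attempt_prob=0.0,
        exacerbation_rate_per_year=0.0,
    )
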