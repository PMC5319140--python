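"""Pulse-oximetry acquisition protocol: quality gating, extension, retry.

The home oximeter streams SpO2 and pulse rate at 3 Hz (plus the raw PPG
waveform at 75 Hz) together with a per-sample signal-quality flag.  A
session is accepted as high quality when it contains a continuous
artefact-free run of at least 30 s.  The acquisition state machine is:

1. record 30 s; accept if the clean-run criterion holds;
2. otherwise extend the same recording by 10 s and re-check;
3. otherwise offer exactly one fresh attempt, with the same 30 s + 10 s
   logic;
4. otherwise keep the data as *best effort*: retained for analysis and
   flagged, but not shown to the patient.

There is never a third attempt.  The extension-then-recheck logic on the
second attempt mirrors the first; the session summary (SpO2, pulse) is the
median over the accepted clean window, or over all samples of the best
attempt when no window qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .sessions_io import QualityLabel, VitalsStream

__all__ = [
    "RecordingAttempt",
    "RecordingOutcome",
    "OutcomeStatus",
    "ProtocolConfig",
    "longest_clean_run",
    "run_protocol",
    "summarize_vitals",
    "synthesize_ppg",
    "quality_label_for",
]

VITALS_RATE_HZ = 3.0
PPG_RATE_HZ = 75.0


class OutcomeStatus(str, Enum):
    ACCEPTED = "accepted"
    ACCEPTED_AFTER_EXTENSION = "accepted_after_extension"
    ACCEPTED_BEST_EFFORT = "accepted_best_effort"


@dataclass(frozen=True)
class ProtocolConfig:
    base_seconds: float = 30.0
    extension_seconds: float = 10.0
    required_clean_seconds: float = 30.0
    max_attempts: int = 2
    sample_rate_hz: float = VITALS_RATE_HZ


@dataclass(frozen=True)
class RecordingAttempt:
    """One continuous oximeter recording with per-sample quality flags."""

    duration_seconds: float
    vitals: VitalsStream
    ppg_samples: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0:
            raise ValueError("duration must be positive")
        expected = round(self.duration_seconds * self.vitals.sample_rate_hz)
        if len(self.vitals.sqi_flags) != expected:
            raise ValueError(
                f"sqi_flags length {len(self.vitals.sqi_flags)} != duration × rate = {expected}"
            )
        if self.ppg_samples is not None:
            expected_ppg = round(self.duration_seconds * PPG_RATE_HZ)
            if len(self.ppg_samples) != expected_ppg:
                raise ValueError(
                    f"ppg length {len(self.ppg_samples)} != duration × 75 Hz = {expected_ppg}"
                )

    @property
    def sqi_flags(self) -> tuple[bool, ...]:
        return self.vitals.sqi_flags


@dataclass(frozen=True)
class RecordingOutcome:
    status: OutcomeStatus
    attempts_used: int
    extended: bool
    clean_run_seconds: float
    summary_spo2: float
    summary_pulse: float

    def __post_init__(self) -> None:
        if self.attempts_used not in (1, 2):
            raise ValueError("attempts_used must be 1 or 2")
        if self.status is not OutcomeStatus.ACCEPTED_BEST_EFFORT:
            if self.clean_run_seconds < 30.0 - 1e-9:
                raise ValueError("accepted outcomes require a clean run of at least 30 s")


def quality_label_for(status: OutcomeStatus) -> QualityLabel:
    """Map a protocol outcome onto the session quality label."""
    if status is OutcomeStatus.ACCEPTED_BEST_EFFORT:
        return QualityLabel.LOW_BEST_EFFORT
    return QualityLabel.HIGH


def longest_clean_run(
    sqi_flags: Sequence[bool], sample_rate_hz: float = VITALS_RATE_HZ
) -> float:
    """Length in seconds of the longest contiguous artefact-free run."""
    if len(sqi_flags) == 0:
        raise ValueError("empty flag sequence")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    best = cur = 0
    for ok in sqi_flags:
        cur = cur + 1 if ok else 0
        best = max(best, cur)
    return best / sample_rate_hz


def _best_clean_window(sqi_flags: Sequence[bool]) -> tuple[int, int] | None:
    """Index span [start, stop) of the longest clean run, or None if no clean sample."""
    best = (0, 0)
    start = None
    for i, ok in enumerate(sqi_flags):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(sqi_flags) - start > best[1] - best[0]:
        best = (start, len(sqi_flags))
    return best if best[1] > best[0] else None


def summarize_vitals(
    attempt: RecordingAttempt, window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Session-level (SpO2, pulse) summary: median over the clean window.

    With ``window=None`` (best-effort outcomes) the median is taken over
    all samples.  Medians rather than means so isolated spikes inside an
    accepted window cannot skew the stored value.
    """
    spo2 = np.asarray(attempt.vitals.spo2_samples, dtype=float)
    pulse = np.asarray(attempt.vitals.pulse_samples, dtype=float)
    if window is not None:
        lo, hi = window
        if not (0 <= lo < hi <= spo2.size):
            raise ValueError(f"window {window} outside attempt of {spo2.size} samples")
        spo2, pulse = spo2[lo:hi], pulse[lo:hi]
    if spo2.size == 0:
        raise ValueError("empty summary window")
    return float(np.median(spo2)), float(np.median(pulse))


def run_protocol(
    attempt_source: Callable[[float, int], RecordingAttempt],
    config: ProtocolConfig | None = None,
) -> RecordingOutcome:
    """Run the acquisition state machine against an attempt source.

    ``attempt_source(duration_seconds, attempt_index)`` must return a
    :class:`RecordingAttempt` of the requested duration; for the extension
    the same attempt index is requested again at base + extension duration
    (the source models the continuation of the same physical recording).
    The protocol requests at most two attempts and one extension per
    attempt.
    """
    config = config or ProtocolConfig()
    need = config.required_clean_seconds
    rate = config.sample_rate_hz

    best_attempt: RecordingAttempt | None = None
    best_run = -1.0
    for attempt_idx in range(1, config.max_attempts + 1):
        attempt = attempt_source(config.base_seconds, attempt_idx)
        run = longest_clean_run(attempt.sqi_flags, rate)
        extended = False
        if run < need:
            attempt = attempt_source(config.base_seconds + config.extension_seconds, attempt_idx)
            run = longest_clean_run(attempt.sqi_flags, rate)
            extended = True
        if run > best_run:
            best_attempt, best_run = attempt, run
        if run >= need:
            window = _best_clean_window(attempt.sqi_flags)
            spo2, pulse = summarize_vitals(attempt, window)
            status = (
                OutcomeStatus.ACCEPTED_AFTER_EXTENSION if extended else OutcomeStatus.ACCEPTED
            )
            return RecordingOutcome(
                status=status,
                attempts_used=attempt_idx,
                extended=extended,
                clean_run_seconds=run,
                summary_spo2=spo2,
                summary_pulse=pulse,
            )

    assert best_attempt is not None
    spo2, pulse = summarize_vitals(best_attempt, None)
    return RecordingOutcome(
        status=OutcomeStatus.ACCEPTED_BEST_EFFORT,
        attempts_used=config.max_attempts,
        extended=True,
        clean_run_seconds=max(best_run, 0.0),
        summary_spo2=spo2,
        summary_pulse=pulse,
    )


def synthesize_ppg(
    duration_s: float,
    pulse_bpm: float,
    artifact_segments: Sequence[tuple[float, float]] = (),
    seed: int | np.random.Generator = 0,
    spo2_percent: float = 95.0,
    include_ppg: bool = True,
) -> RecordingAttempt:
    """Deterministic synthetic oximeter recording for protocol fixtures.

    Produces a pulse-shaped 75 Hz waveform (fundamental at the pulse rate
    plus a second harmonic), 3 Hz SpO2/pulse streams with small sensor
    noise, and SQI flags that are False for every 3 Hz sample whose time
    falls inside an artifact segment.  Inside artifact segments the vitals
    samples are corrupted with large noise, as motion artefact would.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    segs = sorted((float(a), float(b)) for a, b in artifact_segments)
    prev_end = 0.0
    for a, b in segs:
        if a < 0 or b > duration_s or a >= b:
            raise ValueError(f"artifact segment ({a}, {b}) out of range [0, {duration_s}]")
        if a < prev_end:
            raise ValueError("artifact segments must not overlap")
        prev_end = b
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_vitals = round(duration_s * VITALS_RATE_HZ)
    t_vitals = np.arange(n_vitals) / VITALS_RATE_HZ
    dirty = np.zeros(n_vitals, dtype=bool)
    for a, b in segs:
        dirty |= (t_vitals >= a) & (t_vitals < b)

    spo2 = spo2_percent + rng.normal(0.0, 0.2, n_vitals)
    pulse = pulse_bpm + rng.normal(0.0, 0.8, n_vitals)
    spo2[dirty] += rng.normal(0.0, 8.0, int(dirty.sum()))
    pulse[dirty] += rng.normal(0.0, 25.0, int(dirty.sum()))
    spo2 = np.clip(spo2, 0.0, 100.0)
    pulse = np.maximum(pulse, 1.0)

    ppg: tuple[float, ...] | None = None
    if include_ppg:
        n_ppg = round(duration_s * PPG_RATE_HZ)
        t = np.arange(n_ppg) / PPG_RATE_HZ
        f = pulse_bpm / 60.0
        wave = np.sin(2 * np.pi * f * t) + 0.35 * np.sin(4 * np.pi * f * t + 0.6)
        wave += rng.normal(0.0, 0.03, n_ppg)
        dirty_ppg = np.zeros(n_ppg, dtype=bool)
        for a, b in segs:
            dirty_ppg |= (t >= a) & (t < b)
        wave[dirty_ppg] += rng.normal(0.0, 1.5, int(dirty_ppg.sum()))
        ppg = tuple(float(v) for v in wave)

    vitals = VitalsStream(
        sample_rate_hz=VITALS_RATE_HZ,
        spo2_samples=tuple(float(v) for v in spo2),
        pulse_samples=tuple(float(v) for v in pulse),
        sqi_flags=tuple(bool(v) for v in ~dirty),
    )
    return RecordingAttempt(duration_seconds=duration_s, vitals=vitals, ppg_samples=ppg)
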