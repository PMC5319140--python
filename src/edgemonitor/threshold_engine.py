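"""Personalised alert thresholds from run-in self-monitoring data.

Fixed population-wide alert thresholds ignore the large between-patient
variability in resting SpO2, pulse rate and symptom burden, so each
patient's thresholds are learned from their own run-in (training) period:
the first ``training_size`` observations (default 40, roughly the first six
weeks of daily use) of each monitored parameter.

For each parameter a Gaussian kernel density estimate is fitted to the
training values and the alert threshold is the inverse of its smoothed CDF
at a configured percentile — the 95th for symptom score and pulse rate
(alert when the observation is strictly above), the 5th for SpO2 (alert
when strictly below).  By construction a stationary patient then crosses
each threshold on roughly 5% of subsequent days.

When a patient's baseline moves (e.g. disease progression or a change in
therapy), the thresholds trained on the old baseline become stale.  A
robust shift detector compares the median of a recent window against the
training median on the MAD scale, and `retrain` refits the affected
parameter on the most recent ``training_size`` values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .sessions_io import MonitoringSession

__all__ = [
    "Parameter",
    "Direction",
    "KdeModel",
    "ThresholdSpec",
    "ParameterThreshold",
    "ThresholdSet",
    "ThresholdConfig",
    "ShiftResult",
    "InsufficientDataError",
    "select_bandwidth",
    "kde_cdf",
    "kde_pdf",
    "invert_cdf",
    "fit_threshold",
    "parameter_series",
    "train_thresholds",
    "shift_detected",
    "detect_baseline_shift",
    "retrain",
    "DEFAULT_SPECS",
]


class Parameter(str, Enum):
    SYMPTOM_SCORE = "symptom_score"
    SPO2 = "spo2"
    PULSE_RATE = "pulse_rate"


class Direction(str, Enum):
    ALERT_ABOVE = "alert_above"
    ALERT_BELOW = "alert_below"


class InsufficientDataError(ValueError):
    """Raised when a patient's history is too short for the requested fit."""


MIN_TRAINING_POINTS = 2


@dataclass(frozen=True)
class KdeModel:
    """Gaussian-kernel density estimate of one parameter's run-in values."""

    training_values: tuple[float, ...]
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.training_values) < MIN_TRAINING_POINTS:
            raise InsufficientDataError(
                f"KDE needs at least {MIN_TRAINING_POINTS} values, got {len(self.training_values)}"
            )
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class ThresholdSpec:
    """Which tail of the smoothed CDF defines the alert threshold."""

    parameter: Parameter
    percentile: float
    direction: Direction

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie in (0, 1)")
        expected = Direction.ALERT_BELOW if self.parameter is Parameter.SPO2 else Direction.ALERT_ABOVE
        if self.direction is not expected:
            raise ValueError(f"{self.parameter.value} must use {expected.value}")


DEFAULT_SPECS: dict[Parameter, ThresholdSpec] = {
    Parameter.SYMPTOM_SCORE: ThresholdSpec(Parameter.SYMPTOM_SCORE, 0.95, Direction.ALERT_ABOVE),
    Parameter.SPO2: ThresholdSpec(Parameter.SPO2, 0.05, Direction.ALERT_BELOW),
    Parameter.PULSE_RATE: ThresholdSpec(Parameter.PULSE_RATE, 0.95, Direction.ALERT_ABOVE),
}


@dataclass(frozen=True)
class ParameterThreshold:
    """A trained threshold for one parameter, with training provenance."""

    value: float
    percentile: float
    direction: Direction
    trained_at: datetime
    training_window: tuple[int, int]  # [start, stop) indices into the value series
    training_median: float
    training_scale: float  # robust scale (1.4826·MAD, floored at h_min)
    retrain_count: int = 0
    retrain_history: tuple[datetime, ...] = ()

    def __post_init__(self) -> None:
        if self.retrain_count < 0:
            raise ValueError("retrain_count must be nonnegative")
        if len(self.retrain_history) != self.retrain_count:
            raise ValueError("retrain_history length must equal retrain_count")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-patient trained thresholds for every monitored parameter."""

    patient_id: str
    thresholds: Mapping[Parameter, ParameterThreshold]

    def __getitem__(self, p: Parameter) -> ParameterThreshold:
        return self.thresholds[p]

    def __contains__(self, p: Parameter) -> bool:
        return p in self.thresholds

    def to_json(self) -> str:
        obj = {
            "patient_id": self.patient_id,
            "thresholds": {
                p.value: {
                    "value": t.value,
                    "percentile": t.percentile,
                    "direction": t.direction.value,
                    "trained_at": t.trained_at.isoformat(timespec="minutes"),
                    "training_window": list(t.training_window),
                    "training_median": t.training_median,
                    "training_scale": t.training_scale,
                    "retrain_count": t.retrain_count,
                    "retrain_history": [
                        ts.isoformat(timespec="minutes") for ts in t.retrain_history
                    ],
                }
                for p, t in self.thresholds.items()
            },
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        obj = json.loads(text)
        thresholds = {
            Parameter(name): ParameterThreshold(
                value=rec["value"],
                percentile=rec["percentile"],
                direction=Direction(rec["direction"]),
                trained_at=datetime.fromisoformat(rec["trained_at"]),
                training_window=tuple(rec["training_window"]),
                training_median=rec["training_median"],
                training_scale=rec["training_scale"],
                retrain_count=rec["retrain_count"],
                retrain_history=tuple(
                    datetime.fromisoformat(ts) for ts in rec["retrain_history"]
                ),
            )
            for name, rec in obj["thresholds"].items()
        }
        return cls(patient_id=obj["patient_id"], thresholds=thresholds)


@dataclass(frozen=True)
class ThresholdConfig:
    """Tunable parameters of the threshold engine.

    ``training_size``: run-in length in observations (40 ≈ six weeks of
    near-daily use; 50 is offered as an alternative preset matching a
    50-day run-in).  ``h_min``: per-parameter bandwidth floor in the
    parameter's own units, which keeps the KDE nondegenerate for constant
    or heavily tied run-in data.  ``shift_window`` and ``shift_k``: the
    baseline-shift rule flags a parameter when the median of the last
    ``shift_window`` values moves more than ``shift_k`` robust scales away
    from the training median.
    """

    training_size: int = 40
    h_min: Mapping[Parameter, float] = field(
        default_factory=lambda: {
            Parameter.SPO2: 0.25,
            Parameter.PULSE_RATE: 1.0,
            Parameter.SYMPTOM_SCORE: 0.25,
        }
    )
    shift_window: int = 14
    shift_k: float = 2.0
    specs: Mapping[Parameter, ThresholdSpec] = field(default_factory=lambda: dict(DEFAULT_SPECS))

    def __post_init__(self) -> None:
        if self.training_size < MIN_TRAINING_POINTS:
            raise ValueError("training_size too small")
        if self.shift_window < 1:
            raise ValueError("shift_window must be >= 1")
        if self.shift_k <= 0:
            raise ValueError("shift_k must be positive")


# ---------------------------------------------------------------------------
# KDE primitives

def select_bandwidth(values: Sequence[float], h_min: float = 1e-6) -> float:
    """Silverman's rule-of-thumb bandwidth with a floor for degenerate data.

    h = 0.9 · min(sd, IQR/1.34) · n^(−1/5), floored at ``h_min`` (so a
    constant run-in still yields a usable, narrow kernel).
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_TRAINING_POINTS:
        raise InsufficientDataError(f"need at least {MIN_TRAINING_POINTS} values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    candidates = [c for c in (sd, iqr / 1.34) if c > 0]
    if not candidates:
        return h_min
    h = 0.9 * min(candidates) * x.size ** (-0.2)
    return max(h, h_min)


def kde_cdf(model: KdeModel, x: float | np.ndarray) -> float | np.ndarray:
    """Smoothed CDF: F(x) = (1/n) Σ Φ((x − xᵢ)/h).

    Strictly increasing in x with limits 0 and 1, hence invertible.
    """
    xs = np.asarray(model.training_values, dtype=float)
    x_arr = np.asarray(x, dtype=float)
    z = (x_arr[..., None] - xs) / model.bandwidth
    out = ndtr(z).mean(axis=-1)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def kde_pdf(model: KdeModel, x: float | np.ndarray) -> float | np.ndarray:
    """Smoothed density: f(x) = (1/(n·h)) Σ φ((x − xᵢ)/h)."""
    xs = np.asarray(model.training_values, dtype=float)
    x_arr = np.asarray(x, dtype=float)
    z = (x_arr[..., None] - xs) / model.bandwidth
    out = np.exp(-0.5 * z * z).mean(axis=-1) / (model.bandwidth * math.sqrt(2 * math.pi))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def invert_cdf(model: KdeModel, q: float, tol: float = 1e-9, max_iter: int = 200) -> float:
    """Quantile of the smoothed CDF by bisection.

    Strict monotonicity makes the root unique; the bracket
    [min(values) − 10h, max(values) + 10h] contains it for any q in
    (10⁻²², 1 − 10⁻²²).  Returns x with \\|F(x) − q\\| ≤ ``tol``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    xs = model.training_values
    h = model.bandwidth
    lo = min(xs) - 10.0 * h
    hi = max(xs) + 10.0 * h
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = kde_cdf(model, mid)
        if abs(f - q) <= tol:
            return mid
        if f < q:
            lo = mid
        else:
            hi = mid
    return mid


def fit_threshold(
    values: Sequence[float], percentile: float, h_min: float = 1e-6
) -> tuple[float, KdeModel]:
    """Fit a KDE to ``values`` and return (quantile at ``percentile``, model)."""
    h = select_bandwidth(values, h_min=h_min)
    model = KdeModel(training_values=tuple(float(v) for v in values), bandwidth=h)
    return invert_cdf(model, percentile), model


# ---------------------------------------------------------------------------
# session-level training

def parameter_series(
    sessions: Sequence[MonitoringSession], parameter: Parameter
) -> tuple[list[datetime], list[float]]:
    """Extract the (timestamps, values) series of one parameter, skipping
    sessions where it is absent."""
    ts: list[datetime] = []
    vals: list[float] = []
    for s in sessions:
        if parameter is Parameter.SYMPTOM_SCORE:
            v = s.symptom_score
        elif parameter is Parameter.SPO2:
            v = s.spo2_percent
        else:
            v = s.pulse_rate_bpm
        if v is not None:
            ts.append(s.timestamp)
            vals.append(float(v))
    return ts, vals


def _robust_scale(values: Sequence[float], floor: float) -> float:
    x = np.asarray(values, dtype=float)
    mad = float(np.median(np.abs(x - np.median(x))))
    return max(1.4826 * mad, floor)


def _train_one(
    values: Sequence[float],
    spec: ThresholdSpec,
    config: ThresholdConfig,
    trained_at: datetime,
    window: tuple[int, int],
    retrain_count: int = 0,
    retrain_history: tuple[datetime, ...] = (),
) -> ParameterThreshold:
    h_min = config.h_min[spec.parameter]
    value, _model = fit_threshold(values, spec.percentile, h_min=h_min)
    return ParameterThreshold(
        value=value,
        percentile=spec.percentile,
        direction=spec.direction,
        trained_at=trained_at,
        training_window=window,
        training_median=float(np.median(np.asarray(values, dtype=float))),
        training_scale=_robust_scale(values, floor=h_min),
        retrain_count=retrain_count,
        retrain_history=retrain_history,
    )


def train_thresholds(
    sessions: Sequence[MonitoringSession],
    config: ThresholdConfig | None = None,
    parameters: Iterable[Parameter] | None = None,
) -> ThresholdSet:
    """Train per-parameter thresholds on a single patient's run-in data.

    Uses the first ``config.training_size`` non-absent values of each
    parameter.  Raises :class:`InsufficientDataError` naming the parameter
    and the available count when the history is too short.
    """
    config = config or ThresholdConfig()
    if not sessions:
        raise InsufficientDataError("no sessions provided")
    pids = {s.patient_id for s in sessions}
    if len(pids) != 1:
        raise ValueError(f"sessions must belong to a single patient, got {sorted(pids)}")
    patient_id = next(iter(pids))
    parameters = list(parameters) if parameters is not None else list(config.specs)

    thresholds: dict[Parameter, ParameterThreshold] = {}
    for p in parameters:
        ts, vals = parameter_series(sessions, p)
        n = config.training_size
        if len(vals) < n:
            raise InsufficientDataError(
                f"patient {patient_id}: parameter {p.value} has {len(vals)} values, "
                f"needs {n} for training"
            )
        thresholds[p] = _train_one(
            vals[:n], config.specs[p], config, trained_at=ts[n - 1], window=(0, n)
        )
    return ThresholdSet(patient_id=patient_id, thresholds=thresholds)


# ---------------------------------------------------------------------------
# baseline-shift detection and retraining

@dataclass(frozen=True)
class ShiftResult:
    """Outcome of the shift rule for one parameter."""

    parameter: Parameter
    shifted: bool
    recent_median: float
    training_median: float
    scale: float
    z: float  # |Δmedian| / scale


def shift_detected(
    recent_values: Sequence[float],
    training_median: float,
    training_scale: float,
    k: float = 2.0,
) -> bool:
    """Core shift rule on raw values: |median(recent) − median(train)| > k·scale."""
    recent_median = float(np.median(np.asarray(recent_values, dtype=float)))
    return abs(recent_median - training_median) > k * training_scale


def detect_baseline_shift(
    sessions: Sequence[MonitoringSession],
    thresholds: ThresholdSet,
    config: ThresholdConfig | None = None,
    parameters: Iterable[Parameter] | None = None,
) -> dict[Parameter, ShiftResult]:
    """Check each trained parameter for a significant baseline shift.

    Compares the median of the last ``shift_window`` post-training values
    against the training median on the training robust scale.  Requires at
    least ``shift_window`` post-training values per checked parameter.
    """
    config = config or ThresholdConfig()
    parameters = list(parameters) if parameters is not None else list(thresholds.thresholds)
    results: dict[Parameter, ShiftResult] = {}
    for p in parameters:
        t = thresholds[p]
        _, vals = parameter_series(sessions, p)
        post = vals[t.training_window[1] :]
        if len(post) < config.shift_window:
            raise InsufficientDataError(
                f"parameter {p.value}: {len(post)} post-training values, "
                f"needs {config.shift_window} for shift detection"
            )
        recent = post[-config.shift_window :]
        recent_median = float(np.median(np.asarray(recent)))
        z = abs(recent_median - t.training_median) / t.training_scale
        results[p] = ShiftResult(
            parameter=p,
            shifted=z > config.shift_k,
            recent_median=recent_median,
            training_median=t.training_median,
            scale=t.training_scale,
            z=z,
        )
    return results


def retrain(
    sessions: Sequence[MonitoringSession],
    thresholds: ThresholdSet,
    now: datetime,
    config: ThresholdConfig | None = None,
    shifts: Mapping[Parameter, ShiftResult] | None = None,
) -> ThresholdSet:
    """Refit thresholds for parameters whose baseline shifted.

    Refits on the most recent ``training_size`` values of the shifted
    parameter only; unshifted parameters are returned unchanged
    (bit-identical).  With no shifts the input set is returned as-is.
    """
    config = config or ThresholdConfig()
    if shifts is None:
        shifts = detect_baseline_shift(sessions, thresholds, config)
    shifted = [p for p, r in shifts.items() if r.shifted]
    if not shifted:
        return thresholds

    new_thresholds = dict(thresholds.thresholds)
    for p in shifted:
        old = thresholds[p]
        _, vals = parameter_series(sessions, p)
        n = config.training_size
        if len(vals) < n:
            raise InsufficientDataError(
                f"parameter {p.value}: {len(vals)} values, needs {n} to retrain"
            )
        window = (len(vals) - n, len(vals))
        new_thresholds[p] = _train_one(
            vals[window[0] : window[1]],
            config.specs[p],
            config,
            trained_at=now,
            window=window,
            retrain_count=old.retrain_count + 1,
            retrain_history=old.retrain_history + (now,),
        )
    return ThresholdSet(patient_id=thresholds.patient_id, thresholds=new_thresholds)
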