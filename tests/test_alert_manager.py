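"""Alert generation, clustering, priority scoring and review bookkeeping."""

import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest

from edgemonitor.alert_manager import (
    Alert,
    PatientState,
    UntrainedParameterError,
    apply_review_action,
    cluster_alerts,
    evaluate_session,
    priority_score,
    rank_patients,
)
from edgemonitor.sessions_io import QualityLabel, ReviewAction
from edgemonitor.threshold_engine import (
    Direction,
    Parameter,
    ParameterThreshold,
    ThresholdSet,
)

from conftest import make_session

T0 = datetime(2021, 3, 1, 9, 0)


def _threshold(parameter, value):
    direction = Direction.ALERT_BELOW if parameter is Parameter.SPO2 else Direction.ALERT_ABOVE
    return ParameterThreshold(
        value=value,
        percentile=0.05 if parameter is Parameter.SPO2 else 0.95,
        direction=direction,
        trained_at=T0,
        training_window=(0, 40),
        training_median=value,
        training_scale=1.0,
    )


@pytest.fixture
def thresholds():
    return ThresholdSet(
        patient_id="P001",
        thresholds={
            Parameter.SYMPTOM_SCORE: _threshold(Parameter.SYMPTOM_SCORE, 10.0),
            Parameter.SPO2: _threshold(Parameter.SPO2, 90.0),
            Parameter.PULSE_RATE: _threshold(Parameter.PULSE_RATE, 95.0),
        },
    )


def _alert(day, hour=9, parameter=Parameter.SPO2, pid="P001"):
    return Alert(
        patient_id=pid,
        timestamp=datetime(2021, 3, 1 + 0, 9, 0) + timedelta(days=day, hours=hour - 9),
        parameter=parameter,
        observed_value=85.0,
        threshold_value=90.0,
        direction=Direction.ALERT_BELOW,
    )


class TestEvaluateSession:
    def test_value_exactly_on_threshold_does_not_alert(self, thresholds):
        s = make_session(spo2=90.0, pulse=70.0, answers=(1, 1, 1, 1, 1, 1, 1, 1, 1))
        assert evaluate_session(s, thresholds) == []

    def test_spo2_below_fifth_percentile_threshold_alerts_below(self, thresholds):
        s = make_session(spo2=88.0, pulse=70.0, answers=(0,) * 9)
        alerts = evaluate_session(s, thresholds)
        assert len(alerts) == 1
        assert alerts[0].parameter is Parameter.SPO2
        assert alerts[0].direction is Direction.ALERT_BELOW

    def test_three_way_crossing_gives_three_alerts(self, thresholds):
        s = make_session(spo2=85.0, pulse=110.0, answers=(3,) * 9)  # score 27 > 10
        assert {a.parameter for a in evaluate_session(s, thresholds)} == set(Parameter)

    def test_suppression_window_silences_alerts(self, thresholds):
        state = PatientState(patient_id="P001", suppress_until=T0 + timedelta(days=3))
        s = make_session(spo2=85.0, pulse=110.0, day=1, start=T0.date())
        assert evaluate_session(s, thresholds, state) == []
        s_after = make_session(spo2=85.0, pulse=110.0, day=4, start=T0.date())
        assert evaluate_session(s_after, thresholds, state) != []

    def test_best_effort_vitals_flagged_or_excluded(self, thresholds):
        s = make_session(spo2=85.0, pulse=70.0, answers=(0,) * 9,
                         quality=QualityLabel.LOW_BEST_EFFORT, attempts=2)
        flagged = evaluate_session(s, thresholds)
        assert [a.quality_caveat for a in flagged] == [True]
        assert evaluate_session(s, thresholds, include_best_effort=False) == []

    def test_untrained_parameter_raises(self):
        partial = ThresholdSet(
            patient_id="P001",
            thresholds={Parameter.SPO2: _threshold(Parameter.SPO2, 90.0)},
        )
        s = make_session(spo2=95.0, pulse=70.0)
        with pytest.raises(UntrainedParameterError):
            evaluate_session(s, partial)

    def test_alert_invariant_is_self_checkable(self):
        with pytest.raises(ValueError, match="cross"):
            Alert(
                patient_id="P001",
                timestamp=T0,
                parameter=Parameter.SPO2,
                observed_value=95.0,
                threshold_value=90.0,
                direction=Direction.ALERT_BELOW,
            )


def brute_force_clusters(alerts, window_days=7):
    """O(n^2) reference grouping: scan left to right, re-deriving each
    cluster's membership by exhaustive comparison against its anchor."""
    clusters, used = [], set()
    for i, a in enumerate(alerts):
        if i in used:
            continue
        members = [
            j
            for j in range(i, len(alerts))
            if j not in used
            and (alerts[j].timestamp - a.timestamp) <= timedelta(days=window_days)
        ]
        # greedy window anchored at the first unused alert takes a contiguous run
        run = []
        for j in range(i, len(alerts)):
            if j in members:
                run.append(j)
            else:
                break
        used.update(run)
        clusters.append([alerts[j] for j in run])
    return clusters


class TestClustering:
    def test_alerts_within_window_form_one_cluster(self):
        alerts = [_alert(0), _alert(3), _alert(6)]
        clusters = cluster_alerts(alerts)
        assert len(clusters) == 1
        assert clusters[0].alerts == tuple(alerts)

    def test_gap_beyond_window_splits(self):
        clusters = cluster_alerts([_alert(0), _alert(8)])
        assert len(clusters) == 2

    def test_boundary_day_seven_stays_in_cluster(self):
        clusters = cluster_alerts([_alert(0), _alert(7)])
        assert len(clusters) == 1

    def test_random_streams_match_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            days = np.sort(rng.choice(365, size=42, replace=False))
            alerts = [_alert(int(d)) for d in days]
            ours = cluster_alerts(alerts)
            oracle = brute_force_clusters(alerts)
            assert [list(c.alerts) for c in ours] == oracle
            assert len(ours) <= len(alerts)

    def test_clustering_partitions_input(self):
        rng = np.random.default_rng(14)
        days = np.sort(rng.integers(0, 200, size=60))
        alerts = [_alert(int(d)) for d in days]
        clusters = cluster_alerts(alerts)
        flattened = [a for c in clusters for a in c.alerts]
        assert flattened == alerts  # union preserves order, no duplication

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cluster_alerts([_alert(5), _alert(1)])


class TestPriority:
    def test_no_alerts_scores_zero(self):
        state = PatientState(patient_id="P001")
        assert priority_score([], state, now=T0) == 0

    def test_counts_recent_alerts_since_old_review(self):
        state = PatientState(patient_id="P001", last_review=T0 - timedelta(days=20))
        alerts = [_alert(-d) for d in range(1, 6)]  # last 5 days
        now = T0 + timedelta(hours=1)
        assert priority_score(alerts, state, now) == 5

    def test_alerts_straddling_last_review_match_filter_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            offsets = sorted(rng.uniform(-30, 0, size=12))
            alerts = [_alert(0) for _ in offsets]
            alerts = [
                Alert(
                    patient_id="P001",
                    timestamp=T0 + timedelta(days=float(o)),
                    parameter=Parameter.SPO2,
                    observed_value=85.0,
                    threshold_value=90.0,
                    direction=Direction.ALERT_BELOW,
                )
                for o in offsets
            ]
            review = T0 - timedelta(days=float(rng.uniform(0, 25)))
            state = PatientState(patient_id="P001", last_review=review)
            expected = sum(
                1
                for a in alerts
                if a.timestamp > max(T0 - timedelta(days=14), review) and a.timestamp <= T0
            )
            assert priority_score(alerts, state, now=T0) == expected

    def test_monotone_in_alert_set(self):
        state = PatientState(patient_id="P001")
        alerts = [_alert(-2), _alert(-1)]
        base = priority_score(alerts, state, now=T0)
        assert priority_score(alerts + [_alert(0)], state, now=T0) >= base


class TestRanking:
    def test_all_zero_scores_fall_back_to_patient_id_order(self):
        cohort = {
            pid: ([], PatientState(patient_id=pid)) for pid in ["P003", "P001", "P002"]
        }
        assert [p for p, _ in rank_patients(cohort, now=T0)] == ["P001", "P002", "P003"]

    def test_exacerbating_patient_ranks_first(self):
        cohort = {
            "P001": ([], PatientState(patient_id="P001")),
            "P002": ([_alert(-1, pid="P002"), _alert(0, pid="P002")],
                     PatientState(patient_id="P002")),
            "P003": ([_alert(-9, pid="P003")], PatientState(patient_id="P003")),
        }
        ranking = rank_patients(cohort, now=T0 + timedelta(hours=1))
        assert ranking[0] == ("P002", 2)

    def test_input_order_never_matters(self):
        items = [
            ("P00%d" % i, ([_alert(-i, pid="P00%d" % i)], PatientState(patient_id="P00%d" % i)))
            for i in range(1, 6)
        ]
        now = T0 + timedelta(hours=1)
        for perm in itertools.permutations(items, 5):
            assert rank_patients(dict(perm), now) == rank_patients(dict(items), now)


class TestReviewActions:
    def test_sign_off_suppresses_for_three_days(self):
        state = PatientState(patient_id="P001")
        action = ReviewAction("P001", T0, "g", "tick")
        out = apply_review_action(state, action)
        assert out.suppress_until == T0 + timedelta(days=3)
        assert out.last_review == T0
        assert out.action_log == (action,)

    def test_plain_review_updates_last_review_only(self):
        state = PatientState(patient_id="P001", suppress_until=T0 + timedelta(days=1))
        out = apply_review_action(state, ReviewAction("P001", T0, "a"))
        assert out.last_review == T0
        assert out.suppress_until == state.suppress_until

    def test_later_suppressing_action_wins(self):
        state = PatientState(patient_id="P001")
        t1 = T0 + timedelta(days=1)
        out = apply_review_action(state, ReviewAction("P001", T0, "g"))
        out = apply_review_action(out, ReviewAction("P001", t1, "g"))
        assert out.suppress_until == t1 + timedelta(days=3)

    @pytest.mark.parametrize("code", sorted("abcdf"))
    def test_non_suppressing_codes_leave_suppression_alone(self, code):
        state = PatientState(patient_id="P001")
        out = apply_review_action(state, ReviewAction("P001", T0, code))
        assert out.suppress_until is None

    def test_wrong_patient_rejected(self):
        state = PatientState(patient_id="P001")
        with pytest.raises(ValueError, match="applied to"):
            apply_review_action(state, ReviewAction("P002", T0, "a"))
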