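"""Decision rules, baseline store, evaluation and coil comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coilqa.baseline import (
    BaselineStore,
    coil_verdict,
    compare_coils,
    decide,
    evaluate_measurement,
)
from coilqa.errors import CoilMismatchError

BASELINE_10 = [40.0, 41.0, 39.0, 40.5, 39.5, 40.2, 39.8, 41.2, 38.8, 40.0]


class TestDecide:
    # baseline mean 40, sample SD 1 (constructed)
    SD1 = [38.0, 39.0, 40.0, 41.0, 42.0, 40.0, 39.0, 41.0, 40.0, 40.0]

    @pytest.mark.parametrize(
        "x, expected", [(40.5, "pass"), (37.5, "warn"), (36.0, "fail"), (44.0, "fail")]
    )
    def test_sd_criterion(self, x, expected):
        baseline = np.array(self.SD1)
        baseline = 40.0 + (baseline - baseline.mean()) / baseline.std(ddof=1)  # mu=40, sd=1
        d = decide(x, baseline, criterion="sd")
        assert d.status == expected
        assert d.deviation == pytest.approx(x - 40.0, abs=1e-9)

    @pytest.mark.parametrize(
        "x, expected", [(40.0, "pass"), (42.5, "warn"), (35.0, "fail")]
    )
    def test_percent_criterion(self, x, expected):
        d = decide(x, [40.0, 40.0, 40.0], criterion="percent")
        assert d.status == expected

    def test_auto_selects_percent_for_short_baselines(self):
        short = decide(40.0, [40.0] * 9, criterion="auto")
        long = decide(40.0, BASELINE_10, criterion="auto")
        assert short.criterion == "percent"
        assert long.criterion == "sd"

    def test_insufficient_baseline_is_not_evaluable(self):
        assert decide(40.0, [], criterion="percent").status == "not-evaluable"
        assert decide(40.0, [40.0], criterion="sd").status == "not-evaluable"

    def test_criteria_agree_on_exact_mean(self):
        for criterion in ("sd", "percent"):
            assert decide(40.0, BASELINE_10 * 2, criterion=criterion).status in ("pass",)
            assert decide(np.mean(BASELINE_10), BASELINE_10, criterion=criterion).status == "pass"

    @settings(derandomize=True, max_examples=200)
    @given(
        delta1=st.floats(0, 20, allow_nan=False),
        delta2=st.floats(0, 20, allow_nan=False),
        sign=st.sampled_from([-1.0, 1.0]),
        criterion=st.sampled_from(["sd", "percent"]),
    )
    def test_status_monotone_in_deviation(self, delta1, delta2, sign, criterion):
        """For a fixed baseline the verdict never improves as the
        measurement moves further from the baseline mean."""
        order = {"pass": 0, "warn": 1, "fail": 2}
        mu = float(np.mean(BASELINE_10))
        lo, hi = sorted([delta1, delta2])
        near = decide(mu + sign * lo, BASELINE_10, criterion=criterion)
        far = decide(mu + sign * hi, BASELINE_10, criterion=criterion)
        assert order[near.status] <= order[far.status]


class TestStore:
    def test_round_trip_and_accepted_filtering(self, tmp_path):
        store = BaselineStore(tmp_path)
        store.append("torso_B1_T1", "unfiltered", "2024-01-01", {"snr@+90.0": 44.0})
        store.append("torso_B1_T1", "unfiltered", "2024-02-01", {"snr@+90.0": 43.0})
        store.append("torso_B1_T1", "unfiltered", "2024-03-01", {"snr@+90.0": 10.0}, accepted=False)
        series = store.load("torso_B1_T1", "unfiltered")
        assert len(series.entries) == 3
        np.testing.assert_allclose(series.baseline_values("snr@+90.0"), [44.0, 43.0])

    def test_duplicate_date_rejected(self, tmp_path):
        store = BaselineStore(tmp_path)
        store.append("c", "unfiltered", "2024-01-01", {"m": 1.0})
        with pytest.raises(CoilMismatchError):
            store.append("c", "unfiltered", "2024-01-01", {"m": 2.0})

    def test_evaluation_does_not_mutate_store(self, tmp_path):
        store = BaselineStore(tmp_path)
        for i, v in enumerate(BASELINE_10):
            store.append("c", "sos", f"2024-01-{i+1:02d}", {"m": v})
        before = store._series_file("c", "sos").read_bytes()
        evaluate_measurement(store, "c", "sos", {"m": 30.0}, record=False)
        assert store._series_file("c", "sos").read_bytes() == before

    def test_failed_measurement_recorded_as_not_accepted(self, tmp_path):
        store = BaselineStore(tmp_path)
        for i, v in enumerate(BASELINE_10):
            store.append("c", "sos", f"2024-01-{i+1:02d}", {"m": v})
        res = evaluate_measurement(
            store, "c", "sos", {"m": 10.0}, record=True, date="2024-02-01"
        )
        assert res.decisions["m"].status == "fail"
        series = store.load("c", "sos")
        flagged = [e for e in series.entries if e.date == "2024-02-01"]
        assert flagged and not flagged[0].accepted
        # the failed run must not enter subsequent baselines
        assert 10.0 not in store.load("c", "sos").baseline_values("m")


class TestEvaluate:
    def test_empty_store_yields_not_evaluable(self, tmp_path):
        store = BaselineStore(tmp_path)
        res = evaluate_measurement(store, "c", "unfiltered", {"a": 1.0, "b": 2.0})
        assert all(d.status == "not-evaluable" for d in res.decisions.values())
        assert res.overall == "not-evaluable"

    def test_identical_measurement_passes(self, tmp_path):
        store = BaselineStore(tmp_path)
        values = {f"snr@{z:+.1f}": 40.0 + z / 100 for z in range(-170, 171, 20)}
        for i in range(10):
            jitter = {k: v * (1 + 0.002 * ((i % 3) - 1)) for k, v in values.items()}
            store.append("c", "unfiltered", f"2024-01-{i+1:02d}", jitter)
        res = evaluate_measurement(store, "c", "unfiltered", values)
        assert res.summary["fail"] == 0
        assert res.overall in ("pass", "warn")

    def test_coil_verdict_aggregation(self):
        from coilqa.baseline import QaDecision

        ok = QaDecision("m", "pass", "sd", 0.1, 10)
        warn = QaDecision("m", "warn", "sd", 2.5, 10)
        fail = QaDecision("m", "fail", "sd", 4.0, 10)
        assert coil_verdict({"snr": {"a": ok, "b": warn}}, {"VAP1": ok}) == "warn"
        assert coil_verdict({"snr": {"a": ok}}, {"VAP1": fail}) == "fail"
        # >50% of slices failing on one combined metric fails the coil
        assert coil_verdict({"snr": {"a": fail, "b": fail, "c": ok}}, {}) == "fail"
        assert coil_verdict({"snr": {"a": fail, "b": ok, "c": ok}}, {}) == "fail"  # worst status


class TestCompare:
    def _reference_store(self, tmp_path):
        store = BaselineStore(tmp_path)
        for i in range(3):
            store.append(
                "torso_B1_T1", "unfiltered", f"2024-0{i+1}-01",
                {"snr@+90.0": 44.0 + i, "snr@-90.0": 30.0 + i},
            )
        return store

    def test_candidate_above_minima_unflagged(self, tmp_path):
        store = self._reference_store(tmp_path)
        out = compare_coils(
            {"snr@+90.0": 45.0, "snr@-90.0": 31.0}, store, "torso_B1_T1",
            "unfiltered", "torso_B9_T9",
        )
        assert not out["flagged"].any()

    def test_equal_to_minimum_is_acceptable(self, tmp_path):
        store = self._reference_store(tmp_path)
        out = compare_coils(
            {"snr@+90.0": 44.0}, store, "torso_B1_T1", "unfiltered", "torso_B9_T9"
        )
        assert out["margin"].iloc[0] == pytest.approx(0.0)
        assert not out["flagged"].iloc[0]

    def test_weaker_candidate_flagged(self, tmp_path):
        store = self._reference_store(tmp_path)
        out = compare_coils(
            {"snr@+90.0": 0.8 * 44.0}, store, "torso_B1_T1", "unfiltered", "torso_B9_T9"
        )
        assert out["flagged"].iloc[0]

    def test_type_mismatch_refused(self, tmp_path):
        store = self._reference_store(tmp_path)
        with pytest.raises(CoilMismatchError):
            compare_coils({"a": 1.0}, store, "torso_B1_T1", "unfiltered", "headneck_B2_T2")
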