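import numpy as np
import pandas as pd
import pytest

from fieldhtp.qc import (
    QcSummary,
    history_drift,
    record_balance,
    run_summary,
    threshold_check,
)


def _obs(values, sensor_id="IRT1", sensor_type="irt", arm="center"):
    n = len(values)
    return pd.DataFrame({
        "sensor_id": sensor_id, "sensor_type": sensor_type, "boom_arm": arm,
        "logger_time": pd.date_range("2015-07-30 11:00", periods=n, freq="200ms"),
        "trait": "canopy_temp", "value": values,
    })


def _summary_for(mean_value, sensor_id="IRT1"):
    per = pd.DataFrame([{"sensor_id": sensor_id, "sensor_type": "irt",
                         "n": 10, "mean": mean_value, "sd": 1.0,
                         "min": 0, "max": 1, "missing": 0,
                         "out_of_range_frac": 0.0}])
    return QcSummary("r", per)


class TestRunSummary:
    def test_constant_stream(self):
        s = run_summary(_obs([30.0] * 20), "r")
        row = s.per_sensor.iloc[0]
        assert row["sd"] == 0.0
        assert row["min"] == row["max"] == row["mean"] == 30.0

    def test_counts_match_ground_truth(self, small_sim):
        gt = small_sim.ground_truth
        obs = _obs(gt[gt["trait"] == "canopy_temp"]["value"].tolist())
        s = run_summary(obs, "r")
        assert s.per_sensor.iloc[0]["n"] == (gt["trait"] == "canopy_temp").sum()

    def test_missing_payloads_counted(self):
        vals = [30.0] * 7 + [np.nan] * 3
        s = run_summary(_obs(vals), "r")
        assert s.per_sensor.iloc[0]["missing"] == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(30, 2, 50)
        a = run_summary(_obs(list(vals)), "r").per_sensor
        b = run_summary(_obs(list(vals[::-1])), "r").per_sensor
        pd.testing.assert_frame_equal(a, b)


class TestHistoryDrift:
    def test_zero_deviation_no_flag(self):
        hist = [_summary_for(30.0) for _ in range(4)]
        out = history_drift(_summary_for(30.0), hist)
        assert not out["flagged"].iloc[0]

    def test_jump_with_degenerate_mad_flagged(self):
        """MAD = 0 histories still flag genuine jumps via the MAD floor."""
        hist = [_summary_for(30.0) for _ in range(4)]
        out = history_drift(_summary_for(45.0), hist, k=3)
        assert out["flagged"].iloc[0]

    def test_insufficient_history_no_assessment(self):
        hist = [_summary_for(30.0) for _ in range(2)]
        out = history_drift(_summary_for(99.0), hist)
        assert out["status"].iloc[0] == "no assessment"
        assert not out["flagged"].iloc[0]

    def test_current_duplicated_into_history_never_flags(self):
        cur = _summary_for(31.7)
        out = history_drift(cur, [cur] * 5)
        assert not out["flagged"].iloc[0]


class TestRecordBalance:
    def test_balanced_arms(self):
        obs = pd.concat([_obs([30.0] * 10, "IRT1", arm="left"),
                         _obs([30.0] * 10, "IRT2", arm="right")])
        out = record_balance(obs)
        assert not out["flagged"].any()

    def test_short_arm_flagged_with_deficit(self):
        obs = pd.concat([_obs([30.0] * 100, "IRT1", arm="left"),
                         _obs([30.0] * 50, "IRT2", arm="right")])
        out = record_balance(obs)
        row = out[out["boom_arm"] == "right"].iloc[0]
        assert row["flagged"] and row["deficit"] == 50

    def test_single_arm_trivially_balanced(self):
        out = record_balance(_obs([30.0] * 10))
        assert not out["flagged"].any()


class TestThresholdCheck:
    def test_all_inside(self):
        flagged, report = threshold_check(_obs([30.0] * 10))
        assert flagged["out_of_range"].sum() == 0

    def test_injected_out_of_range_counted_exactly(self):
        vals = [30.0] * 17 + [99.0, -50.0, 80.0]
        flagged, report = threshold_check(_obs(vals))
        assert flagged["out_of_range"].sum() == 3
        assert report.iloc[0]["out_of_range_frac"] == pytest.approx(3 / 20)

    def test_boundary_value_not_flagged(self):
        flagged, _ = threshold_check(_obs([60.0, -10.0]),
                                     ranges={"irt": (-10.0, 60.0)})
        assert flagged["out_of_range"].sum() == 0

    def test_monotone_in_range_width(self):
        rng = np.random.default_rng(6)
        obs = _obs(list(rng.normal(30, 20, 200)))
        narrow, _ = threshold_check(obs, ranges={"irt": (20, 40)})
        wide, _ = threshold_check(obs, ranges={"irt": (0, 60)})
        assert wide["out_of_range"].sum() <= narrow["out_of_range"].sum()

    def test_missing_range_warns_and_skips(self):
        obs = _obs([1e9] * 3, sensor_type="mystery")
        with pytest.warns(UserWarning, match="mystery"):
            flagged, _ = threshold_check(obs, ranges={"irt": (0, 1)})
        assert flagged["out_of_range"].sum() == 0
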