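import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halochrom import synthetic
from halochrom.color import CHANNELS
from halochrom.stabilization import (
    StabilizationParams,
    clean_series,
    detect_stabilization,
    numerical_gradient,
    response_time,
)


def constant_series(n=600, value=0.4):
    df = pd.DataFrame({"frame": np.arange(1, n + 1), "t_s": np.arange(n, dtype=float)})
    for ch in CHANNELS:
        df[ch] = value
    return df


def analytic_stabilization_frame(amplitude, rate, midpoint, n, threshold=0.001):
    """Closed-form oracle: last frame where the logistic |slope| is >= the
    threshold, plus one — the frame from which the analytic slope stays below.
    """
    t = np.arange(n, dtype=float)
    s = 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))
    slope = np.abs(amplitude) * rate * s * (1.0 - s)
    above = np.flatnonzero(slope >= threshold)
    return int(above[-1]) + 2 if above.size else 1  # 1-based


class TestCleanSeries:
    def test_gap_free_series_unchanged(self):
        df = constant_series(100)
        pd.testing.assert_frame_equal(clean_series(df), df)

    def test_rows_with_missing_hue_dropped(self):
        df = constant_series(600)
        df.loc[[5, 50, 100, 200, 300], "H"] = np.nan
        assert len(clean_series(df)) == 595

    def test_row_removed_iff_any_channel_missing(self):
        df = constant_series(50)
        df.loc[3, "H"] = np.nan
        df.loc[7, "a"] = np.nan
        df.loc[7, "S"] = np.nan
        cleaned = clean_series(df)
        # brute-force row scan oracle
        expected = [i for i in range(50) if not df.loc[i, list(CHANNELS)].isna().any()]
        assert cleaned["frame"].tolist() == [i + 1 for i in expected]

    def test_too_few_valid_rows_is_error(self):
        df = constant_series(3)
        df.loc[[0, 1], "H"] = np.nan
        with pytest.raises(ValueError):
            clean_series(df)


class TestNumericalGradient:
    def test_constant_gives_zero_slopes(self):
        np.testing.assert_array_equal(numerical_gradient(np.full(10, 3.3)), 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        np.testing.assert_allclose(numerical_gradient(0.7 * np.arange(20)), 0.7)

    def test_sine_slopes_match_cosine_to_second_order(self):
        t = np.arange(600, dtype=float)
        w = 2 * np.pi / 600
        grad = numerical_gradient(np.sin(w * t))
        # central differences: O(dt^2) interior accuracy
        np.testing.assert_allclose(grad[1:-1], w * np.cos(w * t)[1:-1], atol=w**3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            numerical_gradient([1.0])


class TestDetectStabilization:
    def test_constant_series_stabilizes_at_frame_one(self):
        res = detect_stabilization(constant_series(600), "H")
        assert res.stabilized and res.stabilization_frame == 1
        assert res.stabilization_time_s == 0.0

    def test_steady_ramp_never_stabilizes(self):
        df = constant_series(600)
        df["H"] = 0.01 * np.arange(600)
        res = detect_stabilization(df, "H")
        assert not res.stabilized and res.stabilization_frame is None

    @pytest.mark.parametrize("midpoint,rate", [(300.0, 0.05), (200.0, 0.03)])
    def test_noiseless_logistic_matches_analytic_slope_oracle(
        self, noiseless_kinetics, midpoint, rate
    ):
        cfg, series = noiseless_kinetics(ph=8, midpoint=midpoint, rate=rate)
        params = StabilizationParams()
        res = detect_stabilization(series, "H", params)
        amp = cfg.plateau_features["H"] - cfg.baseline_features["H"]
        expected = analytic_stabilization_frame(amp, rate, midpoint, 600)
        assert res.stabilized
        assert abs(res.stabilization_frame - expected) <= params.ma_window

    def test_noisy_logistic_detected_near_oracle(self):
        cfg = synthetic.default_kinetics_config(8, transition_midpoint_s=300.0)
        series = synthetic.generate_color_kinetics(cfg, seed=1)
        res = detect_stabilization(series, "H")
        amp = cfg.plateau_features["H"] - cfg.baseline_features["H"]
        expected = analytic_stabilization_frame(amp, 0.05, 300.0, 600)
        assert res.stabilized
        assert abs(res.stabilization_frame - expected) <= 30

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="consecutive_frames"):
            detect_stabilization(constant_series(30), "H")

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            detect_stabilization(constant_series(100).drop(columns="H"), "H")

    @pytest.mark.parametrize("thr_pair", [(0.001, 0.002), (0.0005, 0.005)])
    def test_raising_threshold_never_delays_detection(
        self, noiseless_kinetics, thr_pair
    ):
        _, series = noiseless_kinetics(ph=8, midpoint=300.0)
        lo = detect_stabilization(
            series, "H", StabilizationParams(slope_threshold=thr_pair[0])
        )
        hi = detect_stabilization(
            series, "H", StabilizationParams(slope_threshold=thr_pair[1])
        )
        if lo.stabilized:
            assert hi.stabilized
            assert hi.stabilization_frame <= lo.stabilization_frame

    def test_raising_run_length_never_hastens_detection(self, noiseless_kinetics):
        _, series = noiseless_kinetics(ph=8, midpoint=300.0)
        frames = []
        for consec in (10, 50, 150):
            res = detect_stabilization(
                series, "H", StabilizationParams(consecutive_frames=consec)
            )
            if res.stabilized:
                frames.append(res.stabilization_frame)
        assert frames == sorted(frames)

    @given(offset=st.floats(-5.0, 5.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_detection_invariant_to_additive_channel_offset(
        self, noiseless_kinetics, offset
    ):
        _, series = noiseless_kinetics(ph=8, midpoint=250.0)
        base = detect_stabilization(series, "a")
        shifted = series.copy()
        shifted["a"] = shifted["a"] + offset
        res = detect_stabilization(shifted, "a")
        assert res.stabilization_frame == base.stabilization_frame


class TestResponseTime:
    def test_constant_series_gives_earliest_admissible_time(self):
        res = response_time(constant_series(600))
        assert res.stabilized and res.stabilization_time_s == 0.0

    def test_planted_plateau_recovered(self, noiseless_kinetics):
        cfg, series = noiseless_kinetics(ph=9, midpoint=300.0, rate=0.05)
        res = response_time(series)
        amp = cfg.plateau_features["H"] - cfg.baseline_features["H"]
        expected = analytic_stabilization_frame(amp, 0.05, 300.0, 600)
        assert abs(res.stabilization_frame - expected) <= 10

    def test_missing_primary_channel_is_error(self):
        with pytest.raises(ValueError):
            response_time(constant_series(600).drop(columns="H"))

    def test_require_all_reports_latest_channel(self, noiseless_kinetics):
        _, series = noiseless_kinetics(ph=7, midpoint=250.0)
        joint = response_time(series, require_all=True)
        singles = [
            detect_stabilization(series, ch).stabilization_frame for ch in ("H", "S", "a")
        ]
        assert joint.stabilized
        assert joint.stabilization_frame == max(singles)
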