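import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from firewatch import (
    AccMagnitude,
    AltitudeTrace,
    LoppConfig,
    PipelineConfig,
    ScenarioSpec,
    classify_state,
    detect_lopp,
    generate,
    quiescence_windows,
    run_pipeline,
    smooth_altitude,
)
from helpers import brute_force_quiescent_runs

FS = 100.0


def acc_of(values):
    return AccMagnitude(acc=np.asarray(values, dtype=float), fs=FS)


def flat_altitude(n, level=20.0):
    return smooth_altitude(AltitudeTrace(h_raw=np.full(n, level)))


class TestQuiescenceWindows:
    def test_constant_rest_is_one_window_from_zero(self):
        runs = quiescence_windows(acc_of(np.ones(500)))
        assert runs == [(0, 499)]

    def test_running_band_violations_yield_no_windows(self):
        t = np.arange(1000) / FS
        a = 1.0 + 1.3 * np.sin(2 * np.pi * 3.0 * t)  # 0.4-2.5 g strides
        assert quiescence_windows(acc_of(np.abs(a))) == []

    def test_spike_splits_the_trace(self):
        a = np.ones(1000)
        a[200] = 1.5
        runs = quiescence_windows(acc_of(a))
        assert runs == [(201, 999)]  # only after the spike does 4 s accumulate

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 1.5, int(rng.integers(50, 3000)))
        cfg = LoppConfig()
        assert quiescence_windows(acc_of(a), cfg) == brute_force_quiescent_runs(a, FS, cfg)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_widening_the_band_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.6, 1.4, 2000)
        narrow = quiescence_windows(acc_of(a), LoppConfig(ll_mov=0.9, lu_mov=1.1))
        wide = quiescence_windows(acc_of(a), LoppConfig(ll_mov=0.7, lu_mov=1.3))
        for s, e in narrow:
            assert any(ws <= s and e <= we for ws, we in wide)


class TestClassifyState:
    def ramp_altitude(self, n, total):
        h = np.linspace(0.0, total, n) + 20.0
        return AltitudeTrace(h_raw=h, h_filtered=h)

    def test_flat_altitude_is_lopp(self):
        alt = self.ramp_altitude(500, 0.0)
        assert classify_state(0, alt, LoppConfig(), FS) == "lopp"

    def test_rising_altitude_is_moving_up(self):
        alt = self.ramp_altitude(500, 3.0)
        assert classify_state(0, alt, LoppConfig(), FS) == "moving_up"

    def test_falling_altitude_is_moving_down(self):
        alt = self.ramp_altitude(500, -3.0)
        assert classify_state(0, alt, LoppConfig(), FS) == "moving_down"

    @given(st.floats(min_value=-5, max_value=5))
    def test_antisymmetric_under_altitude_negation(self, total):
        alt = self.ramp_altitude(500, total)
        neg = AltitudeTrace(h_raw=-alt.h_raw, h_filtered=-alt.h_filtered)
        a, b = classify_state(0, alt, LoppConfig(), FS), classify_state(0, neg, LoppConfig(), FS)
        swap = {"moving_up": "moving_down", "moving_down": "moving_up", "lopp": "lopp"}
        assert b == swap[a]


class TestDetectLopp:
    def test_crawl_then_fall_yields_one_lopp_event(self):
        frame, truth = generate(ScenarioSpec(label="crawl_then_fall", seed=4))
        events = run_pipeline(frame, PipelineConfig()).events
        lopp = [e for e in events if e.kind == "lopp"]
        assert len(lopp) == 1
        assert abs(lopp[0].time - truth[0].time) < 2.0

    @pytest.mark.parametrize("label, kind", [("elevator_up", "moving_up"), ("elevator_down", "moving_down")])
    def test_elevator_ride_suppresses_the_alert(self, label, kind):
        frame, _ = generate(ScenarioSpec(label=label, seed=4))
        events = run_pipeline(frame, PipelineConfig()).events
        assert [e.kind for e in events] == [kind]

    def test_elevator_never_alerts_across_seeds(self):
        # the false-alarm suppression that motivates the barometric fusion
        for seed in range(6):
            frame, _ = generate(ScenarioSpec(label="elevator_up", seed=seed))
            events = run_pipeline(frame, PipelineConfig()).events
            assert all(e.kind != "lopp" for e in events)

    def test_no_quiescence_means_no_events(self):
        t = np.arange(800) / FS
        a = np.abs(1.0 + 1.3 * np.sin(2 * np.pi * 3.0 * t))
        assert detect_lopp(acc_of(a), flat_altitude(800)) == []

    def test_consecutive_lopp_windows_coalesce(self):
        events = detect_lopp(acc_of(np.ones(1200)), flat_altitude(1200))
        assert len(events) == 1 and events[0].kind == "lopp" and events[0].index == 0

    def test_missing_barometer_degrades_but_still_alerts(self):
        events = detect_lopp(acc_of(np.ones(600)), None)
        assert len(events) == 1
        assert events[0].kind == "lopp" and events[0].detail["degraded"] is True


def test_band_ordering_validated():
    with pytest.raises(ValueError):
        LoppConfig(ll_mov=1.1)
    with pytest.raises(ValueError):
        LoppConfig(alt_band=0.0)
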