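import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from firewatch import (
    AccMagnitude,
    FallConfig,
    PipelineConfig,
    ablation_variant,
    detect_falls,
    run_pipeline,
)
from helpers import brute_force_falls, make_angle_trace, make_fall_magnitude

FS = 100.0


def fall_fixture(n=1200, trigger=200, theta=60.0, pitch=50.0, roll=45.0):
    acc = make_fall_magnitude(n, FS, trigger)
    angles = make_angle_trace(n, FS, theta=theta, pitch=pitch, roll=roll)
    return acc, angles


def test_canonical_fall_trace_yields_one_event(fall_forward_run):
    frame, truth = fall_forward_run
    result = run_pipeline(frame, PipelineConfig())
    falls = [e for e in result.events if e.kind == "fall"]
    assert len(falls) == 1
    assert abs(falls[0].index - truth[0].index) <= int(0.5 * frame.fs)
    assert falls[0].detail["peak_g"] > 1.8


def test_walking_never_triggers(default_pipeline_config):
    from firewatch import ScenarioSpec, generate

    frame, _ = generate(ScenarioSpec(label="walk", seed=3))
    result = run_pipeline(frame, default_pipeline_config)
    assert [e for e in result.events if e.kind == "fall"] == []


def test_sub_threshold_trace_emits_nothing():
    n = 1000
    acc = AccMagnitude(acc=np.full(n, 1.6), fs=FS)
    angles = make_angle_trace(n, FS, theta=60, pitch=50, roll=45)
    assert detect_falls(acc, angles) == []


def test_posture_recovery_before_checks_is_non_fall():
    # post-fall rest holds but the angles drop under threshold at j+5 s
    acc, angles = fall_fixture()
    angles.theta[:] = 60.0
    angles.theta[600:] = 5.0  # recovered well before the 5 s check
    angles.pitch[600:] = 5.0
    angles.roll[600:] = 5.0
    assert detect_falls(acc, angles) == []


def test_truncated_candidate_is_non_fall():
    acc, angles = fall_fixture(n=400, trigger=200)  # recheck would be at 750
    assert detect_falls(acc, angles) == []


def test_refractory_suppresses_duplicate_triggers():
    n = 2000
    acc = make_fall_magnitude(n, FS, 200)
    acc.acc[240] = 3.0  # second spike inside the evaluation window folds in
    angles = make_angle_trace(n, FS, theta=60, pitch=50, roll=45)
    events = detect_falls(acc, angles)
    assert [e.index for e in events] == [200]


def test_two_well_separated_falls_both_detected():
    n = 2200
    acc = make_fall_magnitude(n, FS, 200)
    acc.acc[1300] = 3.0
    angles = make_angle_trace(n, FS, theta=60, pitch=50, roll=45)
    assert [e.index for e in detect_falls(acc, angles)] == [200, 1300]


class TestAblationVariants:
    def test_recheck_removed_in_algorithm2(self):
        # angles exceed at j+5 s but recover by j+5.5 s
        acc, angles = fall_fixture(trigger=200)
        k2 = 200 + 550
        angles.theta[k2:] = 5.0
        angles.pitch[k2:] = 5.0
        angles.roll[k2:] = 5.0
        assert detect_falls(acc, angles, algorithm="algorithm1") == []
        assert len(ablation_variant("algorithm2")(acc, angles)) == 1

    def test_theta_ignored_in_algorithm3(self):
        acc, angles = fall_fixture(theta=10.0, pitch=40.0, roll=40.0)
        assert detect_falls(acc, angles, algorithm="algorithm1") == []
        assert len(ablation_variant("algorithm3")(acc, angles)) == 1

    def test_pitch_roll_ignored_in_algorithm4(self):
        acc, angles = fall_fixture(theta=40.0, pitch=5.0, roll=5.0)
        assert detect_falls(acc, angles, algorithm="algorithm1") == []
        assert len(ablation_variant("algorithm4")(acc, angles)) == 1

    def test_full_cascade_detections_are_subset_of_each_variant(self):
        """algorithm1's conditions are strictly stronger than every reduction."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 800
            acc = AccMagnitude(acc=rng.uniform(0.2, 2.5, n), fs=FS)
            angles = make_angle_trace(n, FS)
            angles.theta[:] = rng.uniform(0, 60, n)
            angles.pitch[:] = rng.uniform(-60, 60, n)
            angles.roll[:] = rng.uniform(-60, 60, n)
            full = {e.index for e in detect_falls(acc, angles, algorithm="algorithm1")}
            for name in ("algorithm2", "algorithm3", "algorithm4"):
                reduced = {e.index for e in ablation_variant(name)(acc, angles)}
                assert full <= reduced

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ablation_variant("algorithm5")


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_streaming_matches_brute_force_oracle(seed):
    """Random traces <= 30 s: naive per-sample scan agrees exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(100, 3000))
    a = rng.uniform(0.2, 2.5, n)
    theta = rng.uniform(0, 90, n)
    pitch = rng.uniform(-90, 90, n)
    roll = rng.uniform(-90, 90, n)
    cfg = FallConfig()
    acc = AccMagnitude(acc=a, fs=FS)
    angles = make_angle_trace(n, FS)
    angles.theta, angles.pitch, angles.roll = theta, pitch, roll
    for algorithm in ("algorithm1", "algorithm2", "algorithm3", "algorithm4"):
        got = [e.index for e in detect_falls(acc, angles, cfg, algorithm=algorithm)]
        want = brute_force_falls(a, theta, pitch, roll, FS, cfg, algorithm)
        assert got == want


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_raising_uth_only_removes_events(seed):
    """Isolated impact spikes: a higher impact threshold detects a subset."""
    rng = np.random.default_rng(seed)
    n = 4000
    a = np.ones(n)
    spikes = np.arange(200, n - 600, 900)  # far enough apart not to interact
    a[spikes] = rng.uniform(1.9, 3.5, len(spikes))
    acc = AccMagnitude(acc=a, fs=FS)
    angles = make_angle_trace(n, FS, theta=60, pitch=50, roll=45)
    lo = {e.index for e in detect_falls(acc, angles, FallConfig(uth=1.8))}
    hi = {e.index for e in detect_falls(acc, angles, FallConfig(uth=2.4))}
    assert hi <= lo


def test_invalid_threshold_ordering_rejected():
    with pytest.raises(ValueError):
        FallConfig(uth=1.0)
    with pytest.raises(ValueError):
        FallConfig(lpt=1.3)
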