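"""Seeded synthetic scenario generator with ground-truth events.

Every activity class the detectors must separate is emulated as a
phenomenological signal model: what matters for threshold-cascade detection
is the acceleration-magnitude envelope (impact spikes, free-fall dips, rest
bands, gait oscillation), the orientation trajectory (upright vs. toppled)
and the altitude profile (flat, stair ramp, elevator ramp) -- not
biomechanically accurate body dynamics.

Each trace is built from a deterministic structural skeleton (given the
label) plus seeded Gaussian sensor noise.  The orientation channel is
synthesized by slerping the attitude quaternion along the scripted path;
the accelerometer sees gravity rotated into the device frame scaled by the
magnitude envelope, the gyroscope sees the finite-difference body rates of
the same quaternion path, and the magnetometer sees a fixed earth flux
(60 degree dip) rotated into the device frame, so the orientation filter
receives mutually consistent inputs.

Scenario labels
---------------
falls            fall_forward, fall_backward, fall_left, fall_right
quiescent risks  crawl_then_fall, stuck_narrow_path
elevator         elevator_up, elevator_down
ambulation       stand, walk, run, jog, jump, crawl, stairs_up, stairs_down
gas              co_exposure
extra (tests)    fall_recovery -- fall with posture recovery before the
                 checks; benign ground truth; not part of the default suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_signals import GRAVITY_MS2, SensorFrame, seconds_to_samples
from .events import DetectionEvent
from .orientation import (
    Quaternion,
    IDENTITY_QUATERNION,
    quat_conjugate,
    quat_multiply,
    quat_normalize,
    quat_rotate,
)

#: Labels covered by :func:`make_suite` (the experiment-style class list).
SUITE_LABELS = (
    "stand",
    "walk",
    "run",
    "jog",
    "jump",
    "crawl",
    "stairs_up",
    "stairs_down",
    "elevator_up",
    "elevator_down",
    "fall_forward",
    "fall_backward",
    "fall_left",
    "fall_right",
    "crawl_then_fall",
    "stuck_narrow_path",
    "co_exposure",
)

#: All labels :func:`generate` accepts.
ALL_LABELS = SUITE_LABELS + ("fall_recovery",)

#: Earth magnetic flux direction (unit, 60 degree downward dip).
_EARTH_FLUX = (0.5, 0.0, -math.sqrt(3.0) / 2.0)

_BASE_ALTITUDE_M = 20.0


@dataclass
class ScenarioSpec:
    """Parameters driving one synthetic trace."""

    label: str
    duration: float = 12.0
    fs: float = 100.0
    noise_sd_acc: float = 0.02        # g, per axis
    noise_sd_pressure: float = 0.02   # hPa
    noise_sd_gyro: float = 0.01       # rad/s, per axis
    noise_sd_mag: float = 0.005       # flux units, per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


@dataclass
class ScenarioRun:
    """A generated trace together with its ground truth."""

    spec: ScenarioSpec
    frame: SensorFrame
    truth: list[DetectionEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# quaternion path helpers
# ---------------------------------------------------------------------------

def _quat_from_printed_euler(yaw: float, pitch: float, roll: float) -> Quaternion:
    """Attitude quaternion whose *printed-convention* Euler angles are given.

    The printed extraction equals the aerospace Z-Y-X angles of the conjugate
    quaternion, so we build the standard quaternion and conjugate it.
    """
    cy, sy = math.cos(math.radians(yaw) / 2), math.sin(math.radians(yaw) / 2)
    cp, sp = math.cos(math.radians(pitch) / 2), math.sin(math.radians(pitch) / 2)
    cr, sr = math.cos(math.radians(roll) / 2), math.sin(math.radians(roll) / 2)
    q_std = (
        cy * cp * cr + sy * sp * sr,
        cy * cp * sr - sy * sp * cr,
        cy * sp * cr + sy * cp * sr,
        sy * cp * cr - cy * sp * sr,
    )
    return quat_conjugate(quat_normalize(q_std))


def _slerp(qa: Quaternion, qb: Quaternion, u: float) -> Quaternion:
    dot = sum(a * b for a, b in zip(qa, qb))
    if dot < 0:
        qb = tuple(-c for c in qb)  # type: ignore[assignment]
        dot = -dot
    dot = min(1.0, dot)
    ang = math.acos(dot)
    if ang < 1e-9:
        return quat_normalize(tuple(a + u * (b - a) for a, b in zip(qa, qb)))  # type: ignore[arg-type]
    sa = math.sin((1 - u) * ang) / math.sin(ang)
    sb = math.sin(u * ang) / math.sin(ang)
    return quat_normalize(tuple(sa * a + sb * b for a, b in zip(qa, qb)))  # type: ignore[arg-type]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _attitude_path(
    t: np.ndarray, keyframes: list[tuple[float, float, Quaternion]]
) -> list[Quaternion]:
    """Piecewise-constant attitude with smooth slerp transitions.

    ``keyframes`` is a list of (t_start, t_end, target) rotations; before the
    first keyframe the attitude is identity, between transitions it holds the
    last target.
    """
    quats: list[Quaternion] = []
    for ti in t:
        q_prev: Quaternion = IDENTITY_QUATERNION
        q_cur: Quaternion = IDENTITY_QUATERNION
        for t0, t1, target in keyframes:
            if ti < t0:
                break
            if ti >= t1:
                q_prev = target
                q_cur = target
            else:
                u = float(_smoothstep(np.array([(ti - t0) / (t1 - t0)]))[0])
                q_cur = _slerp(q_prev, target, u)
                break
        else:
            q_cur = q_prev
        quats.append(q_cur)
    return quats


def _gyro_from_quats(quats: list[Quaternion], fs: float) -> np.ndarray:
    """Body angular rates (rad/s) consistent with a quaternion path."""
    n = len(quats)
    g = np.zeros((n, 3))
    for i in range(n - 1):
        dq = quat_multiply(quat_conjugate(quats[i]), quats[i + 1])
        w = max(-1.0, min(1.0, dq[0]))
        vec = np.array(dq[1:])
        s = np.linalg.norm(vec)
        angle = 2.0 * math.atan2(s, w)
        if s > 1e-12:
            g[i] = vec / s * angle * fs
    if n > 1:
        g[-1] = g[-2]
    return g


# ---------------------------------------------------------------------------
# magnitude envelopes
# ---------------------------------------------------------------------------

def _gait(t: np.ndarray, freq: float, up: float, down: float) -> np.ndarray:
    """Asymmetric periodic gait envelope around 1 g."""
    s = np.sin(2 * np.pi * freq * t)
    return 1.0 + up * np.clip(s, 0, None) + down * np.clip(s, None, 0)


def _fall_envelope(t: np.ndarray, t_impact: float, peak: float = 3.0) -> np.ndarray:
    """Stand -> free-fall dip -> impact spike -> damped ripple -> rest."""
    m = np.ones_like(t)
    dip = (t >= t_impact - 0.3) & (t < t_impact)
    m[dip] = 0.3
    spike = (t >= t_impact) & (t < t_impact + 0.12)
    # triangular impact pulse
    m[spike] = 1.0 + (peak - 1.0) * (1.0 - np.abs((t[spike] - t_impact) / 0.06 - 1.0))
    ripple = (t >= t_impact + 0.12) & (t < t_impact + 2.0)
    tr = t[ripple] - t_impact - 0.12
    m[ripple] = 1.0 + 0.35 * np.exp(-tr / 0.4) * np.sin(2 * np.pi * 4.0 * tr)
    return m


def _jump_envelope(t: np.ndarray) -> np.ndarray:
    """Repeated flight dips and landing spikes; never satisfies post-fall rest."""
    m = np.ones_like(t)
    period = 1.2
    phase = np.mod(t, period)
    flight = (phase >= 0.3) & (phase < 0.6)
    m[flight] = 0.25
    landing = (phase >= 0.6) & (phase < 0.72)
    m[landing] = 1.0 + 2.2 * (1.0 - np.abs((phase[landing] - 0.6) / 0.06 - 1.0))
    push = (phase >= 0.0) & (phase < 0.3)
    m[push] = 1.0 + 0.5 * np.sin(np.pi * phase[push] / 0.3)
    return m


_FALL_ATTITUDES = {
    # printed-convention (yaw, pitch, roll) targets after the fall; all
    # exceed the 25/30/30 degree posture thresholds with direction-dependent
    # signs.
    "fall_forward": (0.0, 45.0, 40.0),
    "fall_backward": (0.0, -45.0, -40.0),
    "fall_left": (0.0, 35.0, -50.0),
    "fall_right": (0.0, -35.0, 50.0),
    "fall_recovery": (0.0, 45.0, 40.0),
}


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def generate(spec: ScenarioSpec) -> tuple[SensorFrame, list[DetectionEvent]]:
    """Build one trace and its ground truth, deterministically given the seed."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = seconds_to_samples(spec.duration, fs)
    t = np.arange(n) / fs

    altitude = np.full(n, _BASE_ALTITUDE_M)
    co: np.ndarray | None = None
    keyframes: list[tuple[float, float, Quaternion]] = []
    truth: list[DetectionEvent] = []
    label = spec.label

    if label == "stand":
        m = np.ones(n)
    elif label == "walk":
        m = _gait(t, 2.0, 0.5, 0.4)
    elif label == "jog":
        m = _gait(t, 2.5, 0.7, 0.5)
    elif label == "run":
        m = _gait(t, 3.0, 1.3, 0.55)
    elif label == "jump":
        m = _jump_envelope(t)
    elif label == "crawl":
        m = _gait(t, 1.5, 0.35, 0.3)
    elif label in ("stairs_up", "stairs_down"):
        m = _gait(t, 2.0, 0.5, 0.4)
        sign = 1.0 if label == "stairs_up" else -1.0
        altitude = altitude + sign * 3.0 * t / spec.duration
    elif label in ("elevator_up", "elevator_down"):
        ride_start, ride_end = 2.5, 9.5
        m = np.ones(n)
        walk_in = t < ride_start
        walk_out = t >= ride_end
        m[walk_in] = _gait(t[walk_in], 2.0, 0.5, 0.4)
        m[walk_out] = _gait(t[walk_out], 2.0, 0.5, 0.4)
        sign = 1.0 if label == "elevator_up" else -1.0
        ramp = np.clip((t - ride_start) / (ride_end - ride_start), 0.0, 1.0)
        altitude = altitude + sign * 3.0 * ramp
        idx = seconds_to_samples(ride_start, fs)
        kind = "moving_up" if sign > 0 else "moving_down"
        truth.append(DetectionEvent(kind=kind, index=idx, time=idx / fs))
    elif label == "stuck_narrow_path":
        t_stuck = 4.0
        m = np.where(t < t_stuck, _gait(t, 2.0, 0.5, 0.4), 1.0 + 0.05 * np.sin(2 * np.pi * 0.8 * t))
        idx = seconds_to_samples(t_stuck, fs)
        truth.append(DetectionEvent(kind="lopp", index=idx, time=idx / fs))
    elif label == "crawl_then_fall":
        t_fall = 5.0
        m = np.where(t < t_fall, _gait(t, 1.5, 0.35, 0.3), 1.0)
        slump = (t >= t_fall) & (t < t_fall + 0.2)
        m[slump] = 0.6
        idx = seconds_to_samples(t_fall + 0.2, fs)
        truth.append(DetectionEvent(kind="lopp", index=idx, time=idx / fs))
        keyframes = [(t_fall, t_fall + 0.5, _quat_from_printed_euler(0.0, 40.0, 35.0))]
    elif label in _FALL_ATTITUDES:
        t_impact = 3.3
        m = _fall_envelope(t, t_impact)
        q_down = _quat_from_printed_euler(*_FALL_ATTITUDES[label])
        keyframes = [(3.0, 3.6, q_down)]
        if label == "fall_recovery":
            # stand back up before the posture checks, then a stand-up burst
            # and walking: benign ground truth
            keyframes.append((t_impact + 3.5, t_impact + 4.5, IDENTITY_QUATERNION))
            burst = (t >= t_impact + 4.2) & (t < t_impact + 4.5)
            m[burst] = 1.6
            walking = t >= t_impact + 4.5
            m[walking] = _gait(t[walking], 2.0, 0.5, 0.4)
        else:
            idx = seconds_to_samples(t_impact, fs)
            truth.append(DetectionEvent(kind="fall", index=idx, time=idx / fs))
    elif label == "co_exposure":
        m = _gait(t, 2.0, 0.5, 0.4)
        base, plateau = 7.0, 42.0
        ramp_start, ramp_end = 5.0, 8.0
        ramp = np.clip((t - ramp_start) / (ramp_end - ramp_start), 0.0, 1.0)
        co_clean = base + (plateau - base) * ramp
        co = np.clip(co_clean + rng.normal(0.0, 0.3, n), 0.0, None)
        alert_ppm = 33.0
        t_cross = ramp_start + (ramp_end - ramp_start) * (alert_ppm - base) / (plateau - base)
        idx = seconds_to_samples(t_cross, fs)
        truth.append(DetectionEvent(kind="co_alert", index=idx, time=idx / fs))
    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise ValueError(f"unknown scenario label {label!r}")

    quats = _attitude_path(t, keyframes) if keyframes else [IDENTITY_QUATERNION] * n

    # accelerometer: gravity rotated into the device frame, scaled by the
    # magnitude envelope
    acc = np.empty((n, 3))
    for i, q in enumerate(quats):
        d = quat_rotate(quat_conjugate(q), (0.0, 0.0, 1.0))
        acc[i] = d
    acc *= m[:, None] * GRAVITY_MS2
    acc += rng.normal(0.0, spec.noise_sd_acc * GRAVITY_MS2, (n, 3))

    gyro = _gyro_from_quats(quats, fs) + rng.normal(0.0, spec.noise_sd_gyro, (n, 3))

    mag = np.empty((n, 3))
    for i, q in enumerate(quats):
        mag[i] = quat_rotate(quat_conjugate(q), _EARTH_FLUX)
    mag += rng.normal(0.0, spec.noise_sd_mag, (n, 3))

    from .baro_altimetry import BARO_SCALE_M, BARO_EXPONENT_DENOMINATOR, P0_DEFAULT_HPA

    pressure = P0_DEFAULT_HPA * (1.0 - altitude / BARO_SCALE_M) ** BARO_EXPONENT_DENOMINATOR
    pressure = pressure + rng.normal(0.0, spec.noise_sd_pressure, n)

    frame = SensorFrame(
        fs=fs,
        ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2],
        gx=gyro[:, 0], gy=gyro[:, 1], gz=gyro[:, 2],
        mx=mag[:, 0], my=mag[:, 1], mz=mag[:, 2],
        pressure=pressure,
        co=co,
    )
    return frame, truth


def make_suite(
    n_per_class: int,
    seed: int,
    labels: tuple[str, ...] = SUITE_LABELS,
    duration: float = 12.0,
    fs: float = 100.0,
    noise_sd_acc: float = 0.02,
    noise_sd_pressure: float = 0.02,
) -> list[ScenarioRun]:
    """Deterministic suite of ``n_per_class`` traces per label.

    Trace seeds are derived from ``(seed, label index, repetition)`` so the
    structural truth is identical across suite seeds while noise realizations
    differ.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    runs: list[ScenarioRun] = []
    for li, label in enumerate(labels):
        for rep in range(n_per_class):
            child = int(np.random.SeedSequence((seed, li, rep)).generate_state(1)[0]) % (2**31)
            spec = ScenarioSpec(
                label=label,
                duration=duration,
                fs=fs,
                noise_sd_acc=noise_sd_acc,
                noise_sd_pressure=noise_sd_pressure,
                seed=child,
            )
            frame, truth = generate(spec)
            runs.append(ScenarioRun(spec=spec, frame=frame, truth=truth))
    return runs
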