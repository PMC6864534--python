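"""Device orientation: tilt angle, Madgwick filter and posture decision.

Two independent posture cues feed the fall cascade:

* the tilt angle ``theta`` of the device's vertical axis from gravity,
  computed directly from the accelerometer:
  ``theta = arccos(az / |a|)`` in degrees;

* pitch and roll Euler angles extracted from the quaternion tracked by a
  Madgwick gradient-descent orientation filter fusing gyroscope with
  accelerometer (IMU variant) and, when available, magnetometer (MARG
  variant).

Euler angles are extracted with the conventions

    Y = atan2(2 q2 q3 - 2 q1 q4, 2 q1^2 + 2 q2^2 - 1)
    P = -asin(2 q2 q4 + 2 q1 q3)
    R = atan2(2 q3 q4 - 2 q1 q2, 2 q1^2 + 2 q4^2 - 1)

for a scalar-first unit quaternion (q1, q2, q3, q4).  These are the angles of
the conjugate quaternion under the usual aerospace Z-Y-X convention; the fall
decision only uses magnitudes of pitch/roll, so the sign convention does not
affect detection and is kept exactly as stated.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_signals import MissingChannelError, SensorFrame

logger = logging.getLogger(__name__)

Quaternion = tuple[float, float, float, float]

IDENTITY_QUATERNION: Quaternion = (1.0, 0.0, 0.0, 0.0)


class UndefinedOrientationError(ValueError):
    """Raised when the acceleration vector is zero and tilt is undefined."""


# ---------------------------------------------------------------------------
# Quaternion algebra (plain floats: these run per-sample in tight loops)
# ---------------------------------------------------------------------------

def quat_multiply(a: Quaternion, b: Quaternion) -> Quaternion:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def quat_conjugate(q: Quaternion) -> Quaternion:
    return (q[0], -q[1], -q[2], -q[3])


def quat_normalize(q: Quaternion) -> Quaternion:
    n = math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
    if n == 0.0:
        raise ValueError("cannot normalize zero quaternion")
    return (q[0] / n, q[1] / n, q[2] / n, q[3] / n)


def quat_rotate(q: Quaternion, v: tuple[float, float, float]) -> tuple[float, float, float]:
    """Rotate vector ``v`` by ``q`` (q v q*)."""
    p = quat_multiply(quat_multiply(q, (0.0, *v)), quat_conjugate(q))
    return (p[1], p[2], p[3])


# ---------------------------------------------------------------------------
# Tilt angle
# ---------------------------------------------------------------------------

def theta_angle(
    ax: np.ndarray | float, ay: np.ndarray | float, az: np.ndarray | float
) -> np.ndarray | float:
    """Tilt of the device's z axis from gravity: arccos(az/|a|), degrees.

    Scale-invariant in the acceleration vector; raises on a zero vector.
    """
    ax_a, ay_a, az_a = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    norm = np.sqrt(ax_a**2 + ay_a**2 + az_a**2)
    if np.any(norm == 0):
        raise UndefinedOrientationError("zero acceleration vector has no tilt")
    theta = np.degrees(np.arccos(np.clip(az_a / norm, -1.0, 1.0)))
    return float(theta) if np.isscalar(ax) else theta


# ---------------------------------------------------------------------------
# Madgwick filter
# ---------------------------------------------------------------------------

def tilt_quaternion_from_acc(ax: float, ay: float, az: float) -> Quaternion:
    """Quaternion aligning the measured gravity direction with vertical.

    Used to warm-start the filter from the first accelerometer sample; yaw is
    unobservable from gravity alone and left at zero.
    """
    n = math.sqrt(ax * ax + ay * ay + az * az)
    if n == 0.0:
        return IDENTITY_QUATERNION
    gx, gy, gz = ax / n, ay / n, az / n
    # rotation taking the measured gravity direction onto +z
    cx, cy, cz = gy * 1.0 - 0.0, 0.0 - gx * 1.0, 0.0  # g x ez = (gy, -gx, 0)
    s = math.sqrt(cx * cx + cy * cy + cz * cz)
    angle = math.atan2(s, gz)
    if s < 1e-12:
        if gz > 0:
            return IDENTITY_QUATERNION
        return (0.0, 1.0, 0.0, 0.0)  # upside down: 180 deg about x
    ux, uy, uz = cx / s, cy / s, cz / s
    h = angle / 2.0
    sh = math.sin(h)
    return quat_normalize((math.cos(h), ux * sh, uy * sh, uz * sh))


def madgwick_update(
    q: Quaternion,
    gyro: tuple[float, float, float],
    acc: tuple[float, float, float] | None,
    mag: tuple[float, float, float] | None,
    dt: float,
    beta: float = 0.1,
) -> Quaternion:
    """One gradient-descent fusion step of the Madgwick filter.

    ``q`` is the sensor-to-earth orientation estimate (scalar first).  With a
    magnetometer the MARG variant is used, otherwise the IMU variant; a zero
    accelerometer vector skips the corrective term for the step.  The output
    is renormalized to unit norm.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q0, q1, q2, q3 = q
    gx, gy, gz = gyro

    # quaternion rate from gyroscope: 0.5 * q (x) (0, omega)
    qd0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    qd1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    qd2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    qd3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)

    an = 0.0 if acc is None else math.sqrt(acc[0] ** 2 + acc[1] ** 2 + acc[2] ** 2)
    if an > 1e-12 and beta > 0.0:
        assert acc is not None
        ax, ay, az = acc[0] / an, acc[1] / an, acc[2] / an

        # gravity objective f_g = R(q)^T e_z - a and its Jacobian transpose
        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        s0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
        s1 = 2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
        s2 = -2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
        s3 = 2.0 * q1 * f1 + 2.0 * q2 * f2

        mn = 0.0 if mag is None else math.sqrt(mag[0] ** 2 + mag[1] ** 2 + mag[2] ** 2)
        if mn > 1e-12:
            assert mag is not None
            mx, my, mz = mag[0] / mn, mag[1] / mn, mag[2] / mn
            # reference flux in the earth frame, constrained to the x-z plane
            hx, hy, hz = quat_rotate((q0, q1, q2, q3), (mx, my, mz))
            dx = math.sqrt(hx * hx + hy * hy)
            dz = hz
            # flux objective f_m = R(q)^T (dx, 0, dz) - m
            fm1 = 2.0 * dx * (0.5 - q2 * q2 - q3 * q3) + 2.0 * dz * (q1 * q3 - q0 * q2) - mx
            fm2 = 2.0 * dx * (q1 * q2 - q0 * q3) + 2.0 * dz * (q0 * q1 + q2 * q3) - my
            fm3 = 2.0 * dx * (q0 * q2 + q1 * q3) + 2.0 * dz * (0.5 - q1 * q1 - q2 * q2) - mz
            s0 += (-2.0 * dz * q2) * fm1 + (-2.0 * dx * q3 + 2.0 * dz * q1) * fm2 + (2.0 * dx * q2) * fm3
            s1 += (2.0 * dz * q3) * fm1 + (2.0 * dx * q2 + 2.0 * dz * q0) * fm2 + (2.0 * dx * q3 - 4.0 * dz * q1) * fm3
            s2 += (-4.0 * dx * q2 - 2.0 * dz * q0) * fm1 + (2.0 * dx * q1 + 2.0 * dz * q3) * fm2 + (2.0 * dx * q0 - 4.0 * dz * q2) * fm3
            s3 += (-4.0 * dx * q3 + 2.0 * dz * q1) * fm1 + (-2.0 * dx * q0 + 2.0 * dz * q2) * fm2 + (2.0 * dx * q1) * fm3

        sn = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
        if sn > 0.0:
            qd0 -= beta * s0 / sn
            qd1 -= beta * s1 / sn
            qd2 -= beta * s2 / sn
            qd3 -= beta * s3 / sn

    q_new = (q0 + qd0 * dt, q1 + qd1 * dt, q2 + qd2 * dt, q3 + qd3 * dt)
    return quat_normalize(q_new)


# ---------------------------------------------------------------------------
# Euler extraction and posture decision
# ---------------------------------------------------------------------------

@dataclass
class PostureAngles:
    """Posture angles in degrees at one sample."""

    theta: float
    pitch: float
    roll: float
    yaw: float = 0.0


@dataclass
class AngleTrace:
    """Per-sample posture angle traces in degrees."""

    theta: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.theta)

    def at(self, index: int) -> PostureAngles:
        return PostureAngles(
            theta=float(self.theta[index]),
            pitch=float(self.pitch[index]),
            roll=float(self.roll[index]),
            yaw=float(self.yaw[index]),
        )


def euler_from_quaternion(q: Quaternion) -> PostureAngles:
    """Yaw/pitch/roll in degrees from a unit quaternion (theta not set).

    Near the pitch singularity the asin argument is clamped with a warning.
    """
    q1, q2, q3, q4 = q
    yaw = math.degrees(math.atan2(2 * q2 * q3 - 2 * q1 * q4, 2 * q1 * q1 + 2 * q2 * q2 - 1))
    sp = 2 * q2 * q4 + 2 * q1 * q3
    if abs(sp) > 1.0 - 1e-9:
        logger.warning("pitch extraction near gimbal singularity; clamping asin argument")
        sp = math.copysign(1.0, sp)
    pitch = -math.degrees(math.asin(sp))
    roll = math.degrees(math.atan2(2 * q3 * q4 - 2 * q1 * q2, 2 * q1 * q1 + 2 * q4 * q4 - 1))
    return PostureAngles(theta=float("nan"), pitch=pitch, roll=roll, yaw=yaw)


def track_orientation(
    frame: SensorFrame,
    beta: float = 0.1,
    theta_source: str = "raw",
) -> AngleTrace:
    """Track the quaternion over a frame and derive posture angle traces.

    The gyroscope is required; the accelerometer corrects drift and the
    magnetometer, when present, additionally anchors yaw (MARG variant).  The
    filter is warm-started from the accelerometer tilt of the first sample.
    ``theta_source`` selects whether theta comes from the raw accelerometer
    ("raw", default) or from the filtered gravity direction ("filtered").
    """
    if not frame.has_gyro:
        raise MissingChannelError("gyroscope channels are required for orientation tracking")
    if theta_source not in ("raw", "filtered"):
        raise ValueError("theta_source must be 'raw' or 'filtered'")

    n = frame.n_samples
    dt = 1.0 / frame.fs
    q = tilt_quaternion_from_acc(float(frame.ax[0]), float(frame.ay[0]), float(frame.az[0]))

    pitch = np.empty(n)
    roll = np.empty(n)
    yaw = np.empty(n)
    theta_f = np.empty(n) if theta_source == "filtered" else None

    ax, ay, az = frame.ax, frame.ay, frame.az
    gx, gy, gz = frame.gx, frame.gy, frame.gz
    has_mag = frame.has_mag
    mx = frame.mx if has_mag else None
    my = frame.my if has_mag else None
    mz = frame.mz if has_mag else None

    for i in range(n):
        acc = (float(ax[i]), float(ay[i]), float(az[i]))
        mag = (float(mx[i]), float(my[i]), float(mz[i])) if has_mag else None
        q = madgwick_update(q, (float(gx[i]), float(gy[i]), float(gz[i])), acc, mag, dt, beta)
        e = euler_from_quaternion(q)
        pitch[i] = e.pitch
        roll[i] = e.roll
        yaw[i] = e.yaw
        if theta_f is not None:
            # gravity direction in the sensor frame implied by the estimate
            gvec = quat_rotate(quat_conjugate(q), (0.0, 0.0, 1.0))
            theta_f[i] = math.degrees(math.acos(max(-1.0, min(1.0, gvec[2]))))

    if theta_f is not None:
        theta = theta_f
    else:
        theta = np.asarray(theta_angle(ax, ay, az), dtype=float)
    return AngleTrace(theta=theta, pitch=pitch, roll=roll, yaw=yaw, fs=frame.fs)


def posture_decision(
    first: PostureAngles,
    second: PostureAngles,
    theta_th_deg: float = 25.0,
    pitch_th_deg: float = 30.0,
    roll_th_deg: float = 30.0,
) -> bool:
    """Double-checked fall-posture decision.

    True iff theta > 25 deg AND |pitch| > 30 deg AND |roll| > 30 deg at BOTH
    checks (taken 0.5 s apart); strict inequalities, magnitudes for
    pitch/roll since left/right and forward/backward falls produce opposite
    signs.
    """
    def ok(a: PostureAngles) -> bool:
        return (
            a.theta > theta_th_deg
            and abs(a.pitch) > pitch_th_deg
            and abs(a.roll) > roll_th_deg
        )

    return ok(first) and ok(second)
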