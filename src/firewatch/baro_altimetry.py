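"""Barometric altimetry and the scalar Kalman smoother.

Pressure is converted to altitude with the barometric formula

    H(P) = 44330 * (1 - (P / P0) ** (1 / 5.225))   [m]

with P0 the reference sea-level pressure (1013.25 hPa by default).  The raw
altitude is then smoothed with a one-state Kalman filter whose process noise is
signal-dependent: each update inflates the estimation uncertainty by
``|x - x'| * q``, so the filter opens up when the signal actually moves and
clamps down on a flat signal.  That adaptive behaviour is what lets a single
scalar filter both kill barometric jitter at rest and track elevator ramps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Reference sea-level pressure, hPa.
P0_DEFAULT_HPA = 1013.25

#: Barometric formula scale constant, m.
BARO_SCALE_M = 44330.0

#: Default exponent denominator: H ~ 1 - (P/P0)^(1/5.225).  The conventional
#: international-standard-atmosphere value 5.255 can be configured instead.
BARO_EXPONENT_DENOMINATOR = 5.225


@dataclass(frozen=True)
class KalmanState:
    """State of the scalar Kalman smoother.

    x is the current estimate (m or ppm), p its uncertainty, r the measurement
    uncertainty and q the dimensionless process-noise multiplier applied to the
    per-step state change.
    """

    x: float
    p: float = 1.0
    r: float = 1.0
    q: float = 0.01

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be non-negative")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")

    @property
    def gain(self) -> float:
        """Kalman gain K = p / (p + r), always in [0, 1)."""
        return self.p / (self.p + self.r)


def kalman_step(state: KalmanState, z: float) -> KalmanState:
    """One measurement update of the scalar filter.

    K = p/(p+r);  x' = x (1-K) + K z;  p' = (1-K) p + |x - x'| q.
    The output estimate is a convex combination of the prior estimate and the
    measurement.
    """
    k = state.gain
    # incremental form of x(1-K) + Kz: exact when z equals the estimate
    x_new = state.x + k * (z - state.x)
    p_new = (1.0 - k) * state.p + abs(state.x - x_new) * state.q
    return replace(state, x=x_new, p=p_new)


def kalman_filter_series(
    z: np.ndarray,
    r: float = 1.0,
    q: float = 0.01,
    p_init: float = 1.0,
    x_init: float | None = None,
) -> np.ndarray:
    """Run the scalar filter over a series; seeded with ``x = z[0]`` by default."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty series")
    state = KalmanState(x=float(z[0]) if x_init is None else x_init, p=p_init, r=r, q=q)
    out = np.empty_like(z)
    # Scalar recursion; kept as an explicit loop because each gain depends on
    # the previous state change.
    x, p = state.x, state.p
    for i, zi in enumerate(z):
        k = p / (p + r)
        x_new = x + k * (zi - x)
        p = (1.0 - k) * p + abs(x - x_new) * q
        x = x_new
        out[i] = x
    return out


def pressure_to_altitude(
    pressure: np.ndarray | float,
    p0: float = P0_DEFAULT_HPA,
    exponent_denominator: float = BARO_EXPONENT_DENOMINATOR,
) -> np.ndarray | float:
    """Barometric altitude in meters; vectorized, strictly decreasing in P."""
    p = np.asarray(pressure, dtype=float)
    if np.any(p <= 0) or p0 <= 0:
        raise ValueError("pressure and p0 must be strictly positive")
    h = BARO_SCALE_M * (1.0 - (p / p0) ** (1.0 / exponent_denominator))
    return float(h) if np.isscalar(pressure) else h


@dataclass
class AltitudeTrace:
    """Raw and Kalman-smoothed altitude per sample, in meters."""

    h_raw: np.ndarray
    h_filtered: np.ndarray | None = None
    p0: float = P0_DEFAULT_HPA

    def __post_init__(self) -> None:
        self.h_raw = np.asarray(self.h_raw, dtype=float)
        if self.h_raw.size == 0:
            raise ValueError("empty altitude trace")
        if self.h_filtered is not None:
            self.h_filtered = np.asarray(self.h_filtered, dtype=float)
            if self.h_filtered.shape != self.h_raw.shape:
                raise ValueError("h_raw and h_filtered must have equal length")


def smooth_altitude(trace: AltitudeTrace, init: KalmanState | None = None) -> AltitudeTrace:
    """Return a trace with ``h_filtered`` filled by the sequential scalar filter.

    The filter is seeded with ``x = h_raw[0]`` unless ``init`` provides a
    state; a constant signal is preserved bit-exactly.
    """
    if init is None:
        init = KalmanState(x=float(trace.h_raw[0]))
    h_f = kalman_filter_series(
        trace.h_raw, r=init.r, q=init.q, p_init=init.p, x_init=init.x
    )
    return AltitudeTrace(h_raw=trace.h_raw, h_filtered=h_f, p0=trace.p0)


def altitude_from_pressure(
    pressure: np.ndarray,
    p0: float = P0_DEFAULT_HPA,
    exponent_denominator: float = BARO_EXPONENT_DENOMINATOR,
    r: float = 1.0,
    q: float = 0.01,
    p_init: float = 1.0,
) -> AltitudeTrace:
    """Convenience: pressure trace -> raw + Kalman-smoothed altitude."""
    h_raw = pressure_to_altitude(pressure, p0=p0, exponent_denominator=exponent_denominator)
    trace = AltitudeTrace(h_raw=np.asarray(h_raw, dtype=float), p0=p0)
    return smooth_altitude(trace, KalmanState(x=float(trace.h_raw[0]), p=p_init, r=r, q=q))
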