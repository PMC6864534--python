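"""Sensor data model and acceleration primitives.

The wearable streams synchronized channels at a fixed sampling rate: tri-axial
acceleration (the only mandatory channel), optional tri-axial angular rate and
magnetic field, barometric pressure and CO concentration.  Acceleration is held
internally in m/s^2; every detector works on its vector magnitude normalized to
units of g (9.81 m/s^2).
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable

import numpy as np

#: Standard gravity used for g-normalization of acceleration.
GRAVITY_MS2 = 9.81

#: Tolerance on the uniform-grid timestamp invariant, in seconds.
TIME_GRID_TOL_S = 1e-6

class MissingChannelError(ValueError):
    """A detector requires a channel the frame does not carry."""


@dataclass
class SensorFrame:
    """Synchronized multi-channel time series at sampling rate ``fs`` (Hz).

    ``ax``/``ay``/``az`` are in m/s^2, gyroscope channels in rad/s,
    magnetometer channels in any consistent unit, ``pressure`` in hPa and
    ``co`` in ppm.  All present channels must have equal length >= 1.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray | None = None
    gy: np.ndarray | None = None
    gz: np.ndarray | None = None
    mx: np.ndarray | None = None
    my: np.ndarray | None = None
    mz: np.ndarray | None = None
    pressure: np.ndarray | None = None
    co: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (list, tuple)):
                setattr(self, f.name, np.asarray(v, dtype=float))
        n = len(self.ax)
        if n < 1:
            raise ValueError("channels must have length >= 1")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray) and len(v) != n:
                raise ValueError(f"channel {f.name} length {len(v)} != {n}")
        if self.pressure is not None and np.any(self.pressure <= 0):
            raise ValueError("pressure must be strictly positive")
        if self.co is not None and np.any(self.co < 0):
            raise ValueError("CO concentration must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def t(self) -> np.ndarray:
        """Time grid in seconds, ``t[i] = i / fs``."""
        return np.arange(self.n_samples) / self.fs

    @property
    def has_gyro(self) -> bool:
        return self.gx is not None and self.gy is not None and self.gz is not None

    @property
    def has_mag(self) -> bool:
        return self.mx is not None and self.my is not None and self.mz is not None


@dataclass
class AccMagnitude:
    """Per-sample acceleration magnitude in units of g."""

    acc: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if np.any(self.acc < 0):
            raise ValueError("acceleration magnitude cannot be negative")

    def __len__(self) -> int:
        return len(self.acc)


def rms_acceleration(frame: SensorFrame) -> AccMagnitude:
    """Vector magnitude of the three acceleration axes, normalized to g.

    Computes ``sqrt(ax^2 + ay^2 + az^2) / 9.81`` per sample.  (The field
    literature often labels this quantity "RMS acceleration" although no
    averaging is involved; it is the Euclidean norm.)
    """
    if frame.ax is None or frame.ay is None or frame.az is None:
        raise MissingChannelError("accelerometer channels ax/ay/az are required")
    mag = np.sqrt(frame.ax ** 2 + frame.ay ** 2 + frame.az ** 2) / GRAVITY_MS2
    return AccMagnitude(acc=mag, fs=frame.fs)


def seconds_to_samples(duration: float, fs: float) -> int:
    """Convert a duration in seconds to a sample count, ``round(duration*fs)``.

    All detector windows are configured in seconds and converted through this
    single helper so the same configuration works at 100 Hz and 25 Hz.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return int(round(duration * fs))


def resample_linear(frame: SensorFrame, fs_new: float) -> SensorFrame:
    """Linearly resample every channel of ``frame`` onto a ``fs_new`` grid.

    Utility for fixed-rate logs recorded at a different rate (e.g. 25 Hz
    public-style data); detectors themselves never resample.
    """
    if fs_new <= 0:
        raise ValueError("fs_new must be positive")
    t_old = frame.t
    n_new = max(1, int(np.floor(t_old[-1] * fs_new)) + 1)
    t_new = np.arange(n_new) / fs_new
    kwargs: dict[str, np.ndarray | None] = {}
    for f in fields(SensorFrame):
        if f.name == "fs":
            continue
        v = getattr(frame, f.name)
        kwargs[f.name] = None if v is None else np.interp(t_new, t_old, v)
    return SensorFrame(fs=fs_new, **kwargs)  # type: ignore[arg-type]


#: Pluggable pre-filter applied to a frame before feature extraction.  The
#: default is the identity; device-specific calibration can be slotted in here.
PreFilter = Callable[[SensorFrame], SensorFrame]


def identity_prefilter(frame: SensorFrame) -> SensorFrame:
    return frame
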