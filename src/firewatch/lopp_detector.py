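"""Loss-of-physical-performance (LOPP) detection with barometric fusion.

A firefighter who is stuck or incapacitated while crawling shows a long
stretch of acceleration magnitude trapped in a narrow band around 1 g -- too
quiet for the impact-threshold fall cascade.  The quiescence gate flags any
window of at least 4 s in which every sample lies strictly inside
(Ll_mov, Lu_mov) = (0.8, 1.2) g.  Riding an elevator produces exactly the same
accelerometer signature, so the Kalman-filtered altitude change over the
window disambiguates: a change beyond +/-0.5 m classifies the window as
elevator travel (moving_up / moving_down, used for floor estimation, no
alert); otherwise the window is a LOPP alert.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .baro_altimetry import AltitudeTrace
from .core_signals import AccMagnitude, seconds_to_samples
from .events import DetectionEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoppConfig:
    """Quiescence band, window length and altitude band."""

    lu_mov: float = 1.2      # g, upper quiescence bound
    ll_mov: float = 0.8      # g, lower quiescence bound
    window: float = 4.0      # s, quiescence duration T
    alt_band: float = 0.5    # m, +/- altitude band separating elevator travel

    def __post_init__(self) -> None:
        if not (self.ll_mov < 1.0 < self.lu_mov):
            raise ValueError("band must satisfy ll_mov < 1 < lu_mov")
        if self.window <= 0 or self.alt_band <= 0:
            raise ValueError("window and alt_band must be positive")


def quiescence_windows(
    acc: AccMagnitude, cfg: LoppConfig | None = None
) -> list[tuple[int, int]]:
    """Maximal runs (start, end inclusive) strictly inside the quiescence band
    lasting at least the configured window (>= window*fs + 1 samples, closed
    endpoints)."""
    if cfg is None:
        cfg = LoppConfig()
    a = acc.acc
    if a.size == 0:
        return []
    w = seconds_to_samples(cfg.window, acc.fs)
    inside = (a > cfg.ll_mov) & (a < cfg.lu_mov)
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i, ok in enumerate(inside):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= w + 1:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(a) - start >= w + 1:
        runs.append((start, len(a) - 1))
    return runs


def classify_state(
    window_start: int,
    altitude: AltitudeTrace,
    cfg: LoppConfig,
    fs: float,
) -> str:
    """Classify one quiescent window by its filtered altitude change.

    dAltitude = h_filtered[j + window*fs] - h_filtered[j]; beyond +alt_band it
    is ``moving_up``, beyond -alt_band ``moving_down``, inside the band
    ``lopp``.
    """
    if altitude.h_filtered is None:
        raise ValueError("altitude trace must be Kalman-filtered first")
    w = seconds_to_samples(cfg.window, fs)
    j = window_start
    if j + w >= len(altitude.h_filtered):
        raise ValueError("altitude trace does not cover the window")
    delta = float(altitude.h_filtered[j + w] - altitude.h_filtered[j])
    if delta > cfg.alt_band:
        return "moving_up"
    if delta < -cfg.alt_band:
        return "moving_down"
    return "lopp"


def detect_lopp(
    acc: AccMagnitude,
    altitude: AltitudeTrace | None,
    cfg: LoppConfig | None = None,
) -> list[DetectionEvent]:
    """Quiescence scan + altitude classification, with coalescing.

    Within each maximal quiescent run the window start slides sample by
    sample; consecutive windows with the same classification coalesce into
    one event stamped at the first window start.  Without a barometric
    channel elevator travel cannot be ruled out: every qualifying run emits a
    LOPP event flagged ``degraded``.
    """
    if cfg is None:
        cfg = LoppConfig()
    fs = acc.fs
    w = seconds_to_samples(cfg.window, fs)
    events: list[DetectionEvent] = []

    if altitude is None:
        logger.warning(
            "no barometric altitude: LOPP cannot be disambiguated from "
            "elevator travel; emitting degraded-mode alerts"
        )

    for start, end in quiescence_windows(acc, cfg):
        if altitude is None:
            events.append(
                DetectionEvent(
                    kind="lopp",
                    index=start,
                    time=start / fs,
                    detail={"window_start": start, "window_end": end, "degraded": True},
                )
            )
            continue
        last_kind: str | None = None
        first_j = start
        deltas: list[float] = []
        h = altitude.h_filtered
        assert h is not None
        for j in range(start, end - w + 1):
            kind = classify_state(j, altitude, cfg, fs)
            if kind != last_kind:
                if last_kind is not None:
                    events.append(
                        _lopp_event(last_kind, first_j, j - 1 + w, fs, deltas)
                    )
                last_kind = kind
                first_j = j
                deltas = []
            deltas.append(float(h[j + w] - h[j]))
        if last_kind is not None:
            events.append(_lopp_event(last_kind, first_j, end, fs, deltas))
    return events


def _lopp_event(
    kind: str, start: int, end: int, fs: float, deltas: list[float]
) -> DetectionEvent:
    return DetectionEvent(
        kind=kind,
        index=start,
        time=start / fs,
        detail={
            "window_start": start,
            "window_end": end,
            "delta_altitude_m": deltas[0] if deltas else 0.0,
            "max_abs_delta_altitude_m": float(np.max(np.abs(deltas))) if deltas else 0.0,
            "degraded": False,
        },
    )
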