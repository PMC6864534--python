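"""Carbon-monoxide alerting.

The CO channel (ppm) is smoothed with the same scalar Kalman filter used for
barometric altitude, then compared against the alert threshold (33 ppm by
default; 35 ppm is the OSHA hazardous-work-environment reference and is kept
as documentation/configuration).  The comparison is inclusive and debounced:
an alert opens when the smoothed level stays at or above the threshold for
the hold duration, and clears (a ``co_safe`` event, e.g. "breathing apparatus
may be removed") when it stays below for the hold duration.  Alert and safe
events therefore strictly alternate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baro_altimetry import kalman_filter_series
from .core_signals import seconds_to_samples
from .events import DetectionEvent


@dataclass(frozen=True)
class CoConfig:
    alert_ppm: float = 33.0
    reference_hazard_ppm: float = 35.0   # OSHA reference, documentation only
    hold_s: float = 2.0                  # debounce duration
    kalman_r: float = 1.0
    kalman_q: float = 0.01
    kalman_p_init: float = 1.0

    def __post_init__(self) -> None:
        if self.alert_ppm <= 0:
            raise ValueError("alert_ppm must be positive")
        if self.hold_s <= 0:
            raise ValueError("hold_s must be positive")


def co_alert(co: np.ndarray, fs: float, cfg: CoConfig | None = None) -> list[DetectionEvent]:
    """Debounced alert/safe events from a CO concentration trace.

    Events are stamped at the first sample of the debounced run of the
    smoothed signal.  Runs shorter than the hold duration (including one cut
    off by the end of the trace) emit nothing.
    """
    if cfg is None:
        cfg = CoConfig()
    co = np.asarray(co, dtype=float)
    if co.size == 0:
        return []
    if np.any(co < 0):
        raise ValueError("CO concentration cannot be negative")

    smoothed = kalman_filter_series(
        co, r=cfg.kalman_r, q=cfg.kalman_q, p_init=cfg.kalman_p_init
    )
    hold = max(1, seconds_to_samples(cfg.hold_s, fs))
    above = smoothed >= cfg.alert_ppm

    events: list[DetectionEvent] = []
    alerted = False
    run_start = 0
    run_state = bool(above[0])
    n = len(above)
    for i in range(1, n + 1):
        if i < n and bool(above[i]) == run_state:
            continue
        run_len = i - run_start
        if run_state and not alerted and run_len >= hold:
            events.append(
                DetectionEvent(
                    kind="co_alert",
                    index=run_start,
                    time=run_start / fs,
                    detail={"ppm": float(smoothed[run_start]), "threshold_ppm": cfg.alert_ppm},
                )
            )
            alerted = True
        elif not run_state and alerted and run_len >= hold:
            events.append(
                DetectionEvent(
                    kind="co_safe",
                    index=run_start,
                    time=run_start / fs,
                    detail={"ppm": float(smoothed[run_start]), "threshold_ppm": cfg.alert_ppm},
                )
            )
            alerted = False
        if i < n:
            run_start = i
            run_state = bool(above[i])
    return events
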