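"""Single-pass detection pipeline dispatching the three detectors.

One pass computes the acceleration magnitude, the Kalman-filtered barometric
altitude and the posture angle traces, then runs the fall cascade, the LOPP
quiescence scan and the CO monitor, and merges their events with fall-first
precedence: a fall alert suppresses LOPP/moving events whose window overlaps
the fall's refractory span (the flowchart branches on the impact threshold
first).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .baro_altimetry import AltitudeTrace, altitude_from_pressure
from .co_monitor import co_alert
from .config import PipelineConfig
from .core_signals import (
    AccMagnitude,
    PreFilter,
    SensorFrame,
    identity_prefilter,
    rms_acceleration,
    seconds_to_samples,
)
from .events import DetectionEvent
from .fall_detector import detect_falls
from .io import read_sensor_csv
from .lopp_detector import detect_lopp
from .orientation import AngleTrace, track_orientation

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    events: list[DetectionEvent]
    acc: AccMagnitude | None = None
    altitude: AltitudeTrace | None = None
    angles: AngleTrace | None = None
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    source: SensorFrame | str | Path | None,
    cfg: PipelineConfig | None = None,
    prefilter: PreFilter = identity_prefilter,
) -> PipelineResult:
    """Run every enabled detector over a sensor log or in-memory frame.

    ``source`` may be a CSV path or a :class:`SensorFrame`; ``None`` (an
    empty log) yields an empty event list with a warning.  Identical input
    and configuration produce byte-identical outputs.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if isinstance(source, (str, Path)):
        frame = read_sensor_csv(source, acc_units=cfg.acc_units, axis_map=cfg.axis_map)
    else:
        frame = source
    if frame is None:
        msg = "empty input: no samples, no events"
        logger.warning(msg)
        return PipelineResult(events=[], warnings=[msg])

    frame = prefilter(frame)
    warnings: list[str] = []
    acc = rms_acceleration(frame)

    altitude: AltitudeTrace | None = None
    if frame.pressure is not None:
        altitude = altitude_from_pressure(
            frame.pressure,
            p0=cfg.p0_hpa,
            exponent_denominator=cfg.baro_exponent_denominator,
            r=cfg.kalman_r,
            q=cfg.kalman_q,
            p_init=cfg.kalman_p_init,
        )

    angles: AngleTrace | None = None
    fall_events: list[DetectionEvent] = []
    if cfg.detect_fall:
        if frame.has_gyro:
            angles = track_orientation(frame, beta=cfg.madgwick_beta, theta_source=cfg.theta_source)
            fall_events = detect_falls(acc, angles, cfg.fall_config(), algorithm=cfg.algorithm)
        else:
            msg = "gyroscope missing: fall posture recognition disabled"
            logger.warning(msg)
            warnings.append(msg)

    lopp_events: list[DetectionEvent] = []
    if cfg.detect_lopp:
        lopp_events = detect_lopp(acc, altitude, cfg.lopp_config())
        if altitude is None and lopp_events:
            warnings.append("barometer missing: LOPP events are degraded-mode")

    co_events: list[DetectionEvent] = []
    if cfg.detect_co and frame.co is not None:
        co_events = co_alert(frame.co, frame.fs, cfg.co_config())

    # fall-first precedence over the quiescence-scan events
    refr = seconds_to_samples(cfg.refractory_s, frame.fs)
    kept = []
    for e in lopp_events:
        span_start = e.detail.get("window_start", e.index)
        span_end = e.detail.get("window_end", e.index)
        clash = any(
            span_start <= f.index + refr and span_end >= f.index for f in fall_events
        )
        if clash:
            logger.info("suppressing %s event at sample %d (fall precedence)", e.kind, e.index)
        else:
            kept.append(e)

    events = sorted(fall_events + kept + co_events, key=lambda e: (e.index, e.kind))
    for e in events:
        logger.info("event %s at t=%.2fs (sample %d)", e.kind, e.time, e.index)
    return PipelineResult(events=events, acc=acc, altitude=altitude, angles=angles, warnings=warnings)
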