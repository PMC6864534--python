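"""Three-feature threshold-cascade fall detector.

A candidate opens when the acceleration magnitude exceeds the upper threshold
(Uth, default 1.8 g: the impact spike).  It is confirmed as a fall only if

1. **post-fall rest** -- every sample from 3 s to 5 s after the trigger lies
   strictly inside the rest band (Lpt, Upt) = (0.75, 1.25) g, and
2. **posture recognition** -- the tilt angle theta and the Madgwick
   pitch/roll all exceed their thresholds (25/30/30 deg), double-checked
   0.5 s apart (at trigger + 5 s and trigger + 5.5 s).

Reduced variants of the cascade are exposed for ablation studies:
``algorithm2`` drops the 0.5 s recheck, ``algorithm3`` additionally drops the
theta condition and ``algorithm4`` additionally drops the pitch/roll
condition.
"""
from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Callable

from .core_signals import AccMagnitude, seconds_to_samples
from .events import DetectionEvent
from .orientation import AngleTrace

logger = logging.getLogger(__name__)

ALGORITHMS = ("algorithm1", "algorithm2", "algorithm3", "algorithm4")


@dataclass(frozen=True)
class FallConfig:
    """Cascade thresholds; defaults are the standard parameter set."""

    uth: float = 1.8       # g, upper (impact) threshold
    upt: float = 1.25      # g, post-fall rest band upper bound
    lpt: float = 0.75      # g, post-fall rest band lower bound
    postfall_delay: float = 3.0    # s from trigger to start of rest check
    postfall_window: float = 2.0   # s length of the rest check
    posture_recheck: float = 0.5   # s between the two posture checks
    refractory: float = 6.0        # s trigger suppression after an emitted event
    theta_th_deg: float = 25.0
    pitch_th_deg: float = 30.0
    roll_th_deg: float = 30.0

    def __post_init__(self) -> None:
        if not (self.lpt < 1.0 < self.upt < self.uth):
            raise ValueError("thresholds must satisfy lpt < 1 < upt < uth")
        for name in ("postfall_delay", "postfall_window", "posture_recheck", "refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _posture_ok(
    angles: AngleTrace, k: int, cfg: FallConfig, use_theta: bool, use_pitch_roll: bool
) -> bool:
    ok = True
    if use_theta:
        ok = ok and float(angles.theta[k]) > cfg.theta_th_deg
    if use_pitch_roll:
        ok = ok and abs(float(angles.pitch[k])) > cfg.pitch_th_deg
        ok = ok and abs(float(angles.roll[k])) > cfg.roll_th_deg
    return ok


def detect_falls(
    acc: AccMagnitude,
    angles: AngleTrace,
    cfg: FallConfig | None = None,
    algorithm: str = "algorithm1",
) -> list[DetectionEvent]:
    """Run the threshold cascade over a trace and return fall events.

    ``acc`` and ``angles`` must share the sampling rate and length.  Super-
    threshold samples inside an open candidate's evaluation window are folded
    into that candidate; after an emitted event further triggers are
    suppressed for the refractory period.  A candidate whose evaluation
    window would run past the end of the trace is logged and treated as a
    non-fall.
    """
    if cfg is None:
        cfg = FallConfig()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if acc.fs != angles.fs:
        raise ValueError("acc and angles sampling rates differ")
    if len(acc) != len(angles):
        raise ValueError("acc and angles lengths differ")

    fs = acc.fs
    a = acc.acc
    n = len(a)
    d = seconds_to_samples(cfg.postfall_delay, fs)
    w = seconds_to_samples(cfg.postfall_window, fs)
    rc = seconds_to_samples(cfg.posture_recheck, fs)
    refr = seconds_to_samples(cfg.refractory, fs)

    events: list[DetectionEvent] = []
    skip_until = -1  # last sample index folded into a previous candidate
    j = 0
    while j < n:
        if a[j] <= cfg.uth or j <= skip_until:
            j += 1
            continue
        # candidate trigger at j
        k1 = j + d + w          # first posture check sample
        k2 = k1 + rc            # second posture check sample
        if k2 >= n:
            logger.warning(
                "fall candidate at sample %d truncated (trace ends before the "
                "posture recheck); treated as non-fall", j,
            )
            skip_until = k2
            j += 1
            continue
        window = a[j + d : j + d + w + 1]  # closed endpoints
        postfall = bool((window > cfg.lpt).all() and (window < cfg.upt).all())
        if algorithm == "algorithm1":
            posture = _posture_ok(angles, k1, cfg, True, True) and _posture_ok(
                angles, k2, cfg, True, True
            )
        elif algorithm == "algorithm2":
            posture = _posture_ok(angles, k1, cfg, True, True)
        elif algorithm == "algorithm3":
            posture = _posture_ok(angles, k1, cfg, False, True)
        else:  # algorithm4
            posture = _posture_ok(angles, k1, cfg, True, False)

        if postfall and posture:
            peak_slice = a[j : min(n, k2 + 1)]
            events.append(
                DetectionEvent(
                    kind="fall",
                    index=j,
                    time=j / fs,
                    detail={
                        "peak_g": float(peak_slice.max()),
                        "theta_deg": float(angles.theta[k1]),
                        "pitch_deg": float(angles.pitch[k1]),
                        "roll_deg": float(angles.roll[k1]),
                        "algorithm": algorithm,
                    },
                )
            )
            skip_until = max(k2, j + refr)
        else:
            skip_until = k2
        j += 1
    return events


def ablation_variant(name: str) -> Callable[..., list[DetectionEvent]]:
    """Return the cascade with the named feature set removed.

    ``algorithm1`` is the full double-checked cascade; ``algorithm2`` performs
    a single posture check; ``algorithm3`` drops theta from it;
    ``algorithm4`` drops pitch/roll from it.
    """
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; expected one of {ALGORITHMS}")
    return functools.partial(detect_falls, algorithm=name)
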