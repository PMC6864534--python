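"""Typed detection events shared by all detectors."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: Kinds that represent an alert sent to the incident commander.
ALERT_KINDS = frozenset({"fall", "lopp", "co_alert"})

#: All event kinds the detectors can emit.  ``moving_up``/``moving_down`` are
#: informational floor-direction outputs; ``co_safe`` clears a CO alert.
EVENT_KINDS = frozenset(
    {"fall", "lopp", "moving_up", "moving_down", "co_alert", "co_safe"}
)


@dataclass
class DetectionEvent:
    """A single detector decision anchored to a sample of the input trace.

    Parameters
    ----------
    kind:
        One of :data:`EVENT_KINDS`.
    index:
        Trigger sample (0-based) in the source trace.
    time:
        ``index / fs`` in seconds.
    detail:
        Per-kind diagnostics (peak g, posture angles, altitude change,
        CO level, degraded-mode flags ...).
    """

    kind: str
    index: int
    time: float
    detail: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.index < 0:
            raise ValueError("event index must be non-negative")

    @property
    def is_alert(self) -> bool:
        return self.kind in ALERT_KINDS
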