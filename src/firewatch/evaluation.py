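"""Trial-level scoring and sensitivity/specificity/accuracy metrics.

Each trace is one trial: a trial whose ground truth contains an alert counts
as a true positive if a detection of the matching kind lies within the time
tolerance, otherwise a false negative; a trial without a truth alert counts
as a false positive if any alert fired, otherwise a true negative.  Metrics:

    Sen = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)

reported as percentages rounded to two decimals (exact rationals are kept
internally; a zero denominator yields None, not 0).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, NamedTuple

from .events import DetectionEvent

#: Alert kinds pooled for the combined fall + LOPP detection claim.
DEFAULT_SCORED_KINDS = frozenset({"fall", "lopp"})


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Metrics(NamedTuple):
    sen: float | None
    spec: float | None
    acc: float | None


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return round(float(Fraction(num, den) * 100), 2)


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy in percent (None if undefined)."""
    return Metrics(
        sen=_pct(c.tp, c.tp + c.fn),
        spec=_pct(c.tn, c.tn + c.fp),
        acc=_pct(c.tp + c.tn, c.total),
    )


def scored_kinds(label: str) -> frozenset[str]:
    """Alert kinds scored for a scenario class.

    Quiet standing legitimately sits inside the quiescence band with flat
    altitude, so standing trials are scored on the fall detector only (the
    documented standing exemption); CO-exposure trials are scored on the CO
    alert; everything else on the combined fall + LOPP alerts.
    """
    if label == "stand":
        return frozenset({"fall"})
    if label == "co_exposure":
        return frozenset({"co_alert"})
    return DEFAULT_SCORED_KINDS


def score_trace(
    truth: Iterable[DetectionEvent],
    events: Iterable[DetectionEvent],
    tolerance: float = 2.0,
    kinds: frozenset[str] = DEFAULT_SCORED_KINDS,
) -> ConfusionCounts:
    """Score one trial against its ground truth with a time tolerance (s)."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    truth_alerts = [e for e in truth if e.kind in kinds]
    det_alerts = [e for e in events if e.kind in kinds]
    if truth_alerts:
        hit = all(
            any(d.kind == g.kind and abs(d.time - g.time) <= tolerance for d in det_alerts)
            for g in truth_alerts
        )
        return ConfusionCounts(tp=1) if hit else ConfusionCounts(fn=1)
    return ConfusionCounts(fp=1) if det_alerts else ConfusionCounts(tn=1)


def evaluate_runs(
    runs: Iterable[tuple[str, list[DetectionEvent], list[DetectionEvent]]],
    tolerance: float = 2.0,
) -> dict:
    """Aggregate per-class and pooled scores.

    ``runs`` yields (label, truth, detected) triples; the scoring kinds for
    each trial follow :func:`scored_kinds`.
    """
    per_class: dict[str, ConfusionCounts] = {}
    pooled = ConfusionCounts()
    for label, truth, detected in runs:
        c = score_trace(truth, detected, tolerance=tolerance, kinds=scored_kinds(label))
        per_class[label] = per_class.get(label, ConfusionCounts()) + c
        pooled = pooled + c
    report = {
        "per_class": {
            label: {"counts": vars(c), "metrics": metrics(c)._asdict()}
            for label, c in sorted(per_class.items())
        },
        "pooled": {"counts": vars(pooled), "metrics": metrics(pooled)._asdict()},
    }
    return report
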