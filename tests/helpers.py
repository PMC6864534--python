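"""Independent brute-force oracles and fixture builders used across tests.

The oracles re-derive the detector semantics with naive per-sample loops and
no shared code paths with the streaming implementations they check.
"""
from __future__ import annotations

import numpy as np

from firewatch import AccMagnitude, AngleTrace, FallConfig, LoppConfig


def brute_force_falls(
    acc: np.ndarray,
    theta: np.ndarray,
    pitch: np.ndarray,
    roll: np.ndarray,
    fs: float,
    cfg: FallConfig,
    algorithm: str = "algorithm1",
) -> list[int]:
    """Naive scan of the fall cascade; returns trigger indices."""
    n = len(acc)
    d = int(round(cfg.postfall_delay * fs))
    w = int(round(cfg.postfall_window * fs))
    rc = int(round(cfg.posture_recheck * fs))
    refr = int(round(cfg.refractory * fs))

    def angle_ok(k: int, with_theta: bool, with_pr: bool) -> bool:
        good = True
        if with_theta:
            good = good and theta[k] > cfg.theta_th_deg
        if with_pr:
            good = good and abs(pitch[k]) > cfg.pitch_th_deg and abs(roll[k]) > cfg.roll_th_deg
        return good

    hits = []
    skip_until = -1
    for j in range(n):
        if acc[j] <= cfg.uth or j <= skip_until:
            continue
        k1, k2 = j + d + w, j + d + w + rc
        if k2 >= n:
            skip_until = k2
            continue
        rest = True
        for i in range(j + d, j + d + w + 1):
            if not (cfg.lpt < acc[i] < cfg.upt):
                rest = False
                break
        if algorithm == "algorithm1":
            posture = angle_ok(k1, True, True) and angle_ok(k2, True, True)
        elif algorithm == "algorithm2":
            posture = angle_ok(k1, True, True)
        elif algorithm == "algorithm3":
            posture = angle_ok(k1, False, True)
        else:
            posture = angle_ok(k1, True, False)
        if rest and posture:
            hits.append(j)
            skip_until = max(k2, j + refr)
        else:
            skip_until = k2
    return hits


def brute_force_quiescent_runs(acc: np.ndarray, fs: float, cfg: LoppConfig) -> list[tuple[int, int]]:
    """Naive maximal-run scan of the quiescence band."""
    w = int(round(cfg.window * fs))
    inside = [(cfg.ll_mov < a < cfg.lu_mov) for a in acc]
    runs = []
    i = 0
    n = len(acc)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        if j - i >= w + 1:
            runs.append((i, j - 1))
        i = j
    return runs


def make_angle_trace(
    n: int,
    fs: float,
    theta: float = 0.0,
    pitch: float = 0.0,
    roll: float = 0.0,
) -> AngleTrace:
    """Constant posture-angle trace for hand-built cascade fixtures."""
    return AngleTrace(
        theta=np.full(n, theta),
        pitch=np.full(n, pitch),
        roll=np.full(n, roll),
        yaw=np.zeros(n),
        fs=fs,
    )


def make_fall_magnitude(
    n: int,
    fs: float,
    trigger: int,
    rest: float = 1.0,
    peak: float = 3.0,
) -> AccMagnitude:
    """Rest-spike-rest magnitude trace whose only trigger is at ``trigger``."""
    a = np.full(n, rest)
    a[trigger] = peak
    return AccMagnitude(acc=a, fs=fs)
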