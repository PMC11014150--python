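"""Independent brute-force reference implementations used as test oracles.

These are written as plain per-element loops, deliberately avoiding the
vectorized/event-driven code paths of the package, so that agreement between
the two is informative.
"""

from __future__ import annotations

import math

import numpy as np


def mad_oracle(block) -> float:
    """Mean absolute deviation of resultant magnitudes, double loop, in mg."""
    block = np.asarray(block, dtype=float)
    n = len(block)
    resultants = []
    for i in range(n):
        x, y, z = block[i]
        resultants.append(math.sqrt(x * x + y * y + z * z))
    mean = sum(resultants) / n
    total = 0.0
    for r in resultants:
        total += abs(r - mean)
    return total / n * 1000.0


def madxyz_oracle(block) -> float:
    """Sum of axis-wise mean absolute deviations, explicit loops, in mg."""
    block = np.asarray(block, dtype=float)
    n = len(block)
    total = 0.0
    for axis in range(3):
        mean = sum(block[i][axis] for i in range(n)) / n
        for i in range(n):
            total += abs(block[i][axis] - mean)
    return total / n * 1000.0


def trigger_oracle(samples, fs, arm_mg=187.5, confirm_mg=500.0, window_s=5.0) -> np.ndarray:
    """Per-sample simulation of the trigger state machine.

    Semantics: reference starts at the first sample and updates with the
    coincident values on every threshold exceedance; a confirmed arming marks
    samples active from the arming sample; an unconfirmed window stays
    quiescent; an active bout extends while arm-level exceedances occur
    within one window of the last, and the waiting tail of the window stays
    active.
    """
    s = np.asarray(samples, dtype=float)
    n = len(s)
    arm = arm_mg / 1000.0
    confirm = confirm_mg / 1000.0
    w = int(round(window_s * fs))
    quiescent = [True] * n
    state = "Q"
    ref = s[0].copy()
    arm_i = -1
    last_exc = -1
    i = 1
    while i < n:
        d = float(np.max(np.abs(s[i] - ref)))
        if state == "Q":
            if d > arm:
                state = "ARMED"
                arm_i = i
                ref = s[i].copy()
        elif state == "ARMED":
            if i > arm_i + w:
                state = "Q"
                continue  # re-examine this sample as quiescent
            if d > confirm:
                state = "ACTIVE"
                ref = s[i].copy()
                last_exc = i
            elif d > arm:
                ref = s[i].copy()
        else:  # ACTIVE
            if i > last_exc + w:
                for k in range(arm_i, min(n, last_exc + w + 1)):
                    quiescent[k] = False
                state = "Q"
                continue  # re-examine this sample as quiescent
            if d > arm:
                ref = s[i].copy()
                last_exc = i
        i += 1
    if state == "ACTIVE":
        for k in range(arm_i, min(n, last_exc + w + 1)):
            quiescent[k] = False
    return np.array(quiescent)


def _ranks_with_ties(v) -> list[float]:
    """Average ranks, computed by sorting (no library rank routine)."""
    v = list(map(float, v))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def partial_spearman_oracle(x, y, age, sex_indicator, weights=None) -> float:
    """Rank -> residualize on (1, sex, age_c, age_c^2) -> correlate, by hand.

    Residualization solves the weighted normal equations directly.
    """
    n = len(x)
    w = [1.0] * n if weights is None else list(map(float, weights))
    rx = _ranks_with_ties(x)
    ry = _ranks_with_ties(y)
    wsum = sum(w)
    age_mean = sum(wi * ai for wi, ai in zip(w, age)) / wsum
    design = [[1.0, float(s), a - age_mean, (a - age_mean) ** 2] for s, a in zip(sex_indicator, age)]

    def residualize(v):
        k = 4
        ata = [[sum(w[i] * design[i][p] * design[i][q] for i in range(n)) for q in range(k)] for p in range(k)]
        atv = [sum(w[i] * design[i][p] * v[i] for i in range(n)) for p in range(k)]
        beta = np.linalg.solve(np.array(ata), np.array(atv))
        return [v[i] - sum(beta[p] * design[i][p] for p in range(4)) for i in range(n)]

    ex = residualize(rx)
    ey = residualize(ry)
    mx = sum(wi * e for wi, e in zip(w, ex)) / wsum
    my = sum(wi * e for wi, e in zip(w, ey)) / wsum
    cov = sum(wi * (a - mx) * (b - my) for wi, a, b in zip(w, ex, ey)) / wsum
    vx = sum(wi * (a - mx) ** 2 for wi, a in zip(w, ex)) / wsum
    vy = sum(wi * (b - my) ** 2 for wi, b in zip(w, ey)) / wsum
    return cov / math.sqrt(vx * vy)
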