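"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive — O(m*n) pairwise loops and explicit
enumeration — and shares no code with the package internals.
"""

import math

import numpy as np


def mann_whitney_auc(cases, controls) -> float:
    """Pairwise Mann-Whitney probability with ties counted 1/2."""
    total = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(cases) * len(controls))


def naive_delong_variance(cases, controls) -> float:
    """DeLong variance from explicitly enumerated placement values."""
    m, n = len(cases), len(controls)
    v10 = []
    for x in cases:
        v10.append(sum(1.0 if x > y else 0.5 if x == y else 0.0 for y in controls) / n)
    v01 = []
    for y in controls:
        v01.append(sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in cases) / m)
    s10 = sum((v - np.mean(v10)) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - np.mean(v01)) ** 2 for v in v01) / (n - 1)
    return s10 / m + s01 / n


def count_se_sp(scores, labels, threshold, higher_is_positive=True):
    """Se/Sp at a threshold by explicit counting (positive = strictly beyond)."""
    tp = fp = fn = tn = 0
    for s, y in zip(scores, labels):
        positive = s > threshold if higher_is_positive else s < threshold
        if y == 1:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return tp / (tp + fn), tn / (tn + fp)


def brute_force_cutoff(scores, labels, higher_is_positive=True):
    """Exhaustive closest-to-top-left minimisation over midpoint thresholds.

    Tie-break: smallest distance, then highest Se, then smallest threshold.
    """
    vals = sorted(set(scores))
    thresholds = [(a + b) / 2.0 for a, b in zip(vals[:-1], vals[1:])]
    best = None
    for t in thresholds:
        se, sp = count_se_sp(scores, labels, t, higher_is_positive)
        d = math.sqrt((1.0 - se) ** 2 + (1.0 - sp) ** 2)
        key = (d, -se, t)
        if best is None or key < best[0]:
            best = (key, t, se, sp, d)
    if best is None:
        return None
    _, t, se, sp, d = best
    return {"threshold": t, "se": se, "sp": sp, "distance": d}
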