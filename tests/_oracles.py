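"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (double loops, direct formulas) and
shares no code with the package internals it checks.
"""

import math

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Template-counting sample entropy with explicit double loops."""
    x = list(map(float, x))
    n = len(x)
    b = 0
    a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def auroc_pair_counting(scores, labels) -> float:
    """AUROC as the concordant-pair fraction (ties count half), percent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return 100.0 * total / (pos.size * neg.size)


def best_f1_sweep(scores, labels):
    """Exhaustive threshold sweep for the F1-maximizing operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for th in sorted(set(scores)):
        pred = scores >= th
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        se = tp / n_pos
        sp = (n_neg - fp) / n_neg
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * se / (prec + se) if prec + se else 0.0
        if best is None or (f1, sp) > (best[0], best[1]):
            best = (f1, sp, prec, se, th)
    return {
        "f1": best[0] * 100, "sp": best[1] * 100, "precision": best[2] * 100,
        "se": best[3] * 100, "threshold": best[4],
    }


def mann_whitney_u_bruteforce(a, b) -> float:
    """U statistic for sample a by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def match_beats(detected, truth, tol_samples: int):
    """(n true detected, n detections that are true) at the given tolerance."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0 or truth.size == 0:
        return 0, 0
    d = np.abs(detected[:, None] - truth[None, :])
    n_found = int((d.min(axis=0) <= tol_samples).sum())
    n_true_det = int((d.min(axis=1) <= tol_samples).sum())
    return n_found, n_true_det
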