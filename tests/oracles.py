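"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain Python
loops, explicit pairwise sums and naive enumeration, so they can serve as
independent references for the optimised implementations.
"""

from __future__ import annotations

import math


def gini_pairwise(values) -> float:
    """Bias-corrected Gini via the O(n^2) pairwise absolute-difference sum."""
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    if mean == 0:
        return 0.0
    total = 0.0
    for a in xs:
        for b in xs:
            total += abs(a - b)
    raw = total / (2.0 * n * n * mean)
    return raw * n / (n - 1)


def pearson_naive(a, b) -> float:
    xs = [float(v) for v in a]
    ys = [float(v) for v in b]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = sum((x - mx) ** 2 for x in xs)
    dy = sum((y - my) ** 2 for y in ys)
    if dx == 0 or dy == 0:
        return 0.0
    return num / math.sqrt(dx * dy)


def iws_naive(col_a, col_b) -> float:
    return pearson_naive(col_a, col_b) * gini_pairwise(col_a) * gini_pairwise(col_b)


def iwd_naive(query_col, comparison_col) -> float:
    mae = sum(abs(float(q) - float(c)) for q, c in zip(query_col, comparison_col)) / 20.0
    return mae * gini_pairwise(query_col)


def iws_p_naive(value, samples) -> float:
    count = sum(1 for s in samples if s >= value)
    return (count + 1) / (len(samples) + 1)


def udf_naive(p: float, n: int) -> float:
    """Direct series evaluation of P(product of n uniforms <= p)."""
    t = -math.log(p)
    return min(1.0, p * sum(t**k / math.factorial(k) for k in range(n)))


def enumerate_best_window(query_weights, comparison_weights, samples):
    """Naive sliding-window comparison returning per-window stats.

    ``query_weights`` / ``comparison_weights`` are 20 x L lists or arrays of
    normalised values; ``samples`` is the background sample list.  Returns a
    list of dicts (offset, sig, p_win, max_iwd) and the best window index by
    (sig, offset).
    """
    lq = len(query_weights[0])
    lc = len(comparison_weights[0])
    n = min(lq, lc)
    n_windows = abs(lq - lc) + 1
    windows = []
    for offset in range(n_windows):
        p_win = 1.0
        max_iwd = 0.0
        for j in range(n):
            if lq >= lc:
                qcol = [query_weights[a][offset + j] for a in range(20)]
                ccol = [comparison_weights[a][j] for a in range(20)]
            else:
                qcol = [query_weights[a][j] for a in range(20)]
                ccol = [comparison_weights[a][offset + j] for a in range(20)]
            p_win *= iws_p_naive(iws_naive(qcol, ccol), samples)
            max_iwd = max(max_iwd, iwd_naive(qcol, ccol))
        windows.append(
            {
                "offset": offset,
                "p_win": p_win,
                "sig": udf_naive(p_win, n),
                "max_iwd": max_iwd,
            }
        )
    best = min(range(n_windows), key=lambda i: (windows[i]["sig"], i))
    return windows, best


def roc_auc_pairs(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant pair counting (ties = 0.5)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
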