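"""Column-level scores: Gini importance, Pearson similarity, IWS and IWD.

The importance-weighted similarity (IWS) of two PSSM columns is

    IWS = pearson(A_i, B_i) * gini(A_i) * gini(B_i)

so a pair only scores highly when the columns are both similar and both
informative.  The importance-weighted dissimilarity (IWD) of a query column
against a comparison column is the mean absolute difference over the 20
residues weighted by the *query* column's Gini importance only, making it
directional: it flags determinants required by the query that the comparison
lacks.
"""

from __future__ import annotations

import numpy as np

_N = 20


def _as_column(x, name: str = "column") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size != _N:
        raise ValueError(f"{name} must have exactly {_N} entries, got {arr.size}")
    return arr


def gini_rows(X: np.ndarray) -> np.ndarray:
    """Bias-corrected Gini coefficient of each row of ``X`` (shape (m, 20)).

    Uses the sorted-value identity
    ``G_raw = 2 * sum(i * x_(i)) / (n * sum(x)) - (n + 1) / n`` followed by
    the small-sample correction ``n / (n - 1)``, under which a one-hot column
    scores exactly 1.  All-zero rows score 0.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    xs = np.sort(X, axis=1)
    totals = xs.sum(axis=1)
    idx = np.arange(1, n + 1, dtype=float)
    safe = np.where(totals > 0, totals, 1.0)
    raw = 2.0 * (xs * idx).sum(axis=1) / (n * safe) - (n + 1.0) / n
    g = (raw * n) / (n - 1.0)
    g = np.where(totals > 0, g, 0.0)
    return np.clip(g, 0.0, 1.0)


def gini(column) -> float:
    """Bias-corrected Gini importance of one normalised 20-entry column."""
    return float(gini_rows(_as_column(column)[None, :])[0])


def pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (m, 20) arrays.

    A zero-variance row on either side yields 0 by convention (a constant
    column encodes no preference).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    # exact constancy, not a variance epsilon: the convention only applies
    # to columns that encode no preference at all
    ok = (A.max(axis=1) > A.min(axis=1)) & (B.max(axis=1) > B.min(axis=1))
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den2 = (Ac * Ac).sum(axis=1) * (Bc * Bc).sum(axis=1)
    den = np.sqrt(np.where(den2 > 0, den2, 1.0))
    r = np.where(ok & (den2 > 0), num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def pearson_similarity(col_a, col_b) -> float:
    a = _as_column(col_a, "col_a")
    b = _as_column(col_b, "col_b")
    return float(pearson_rows(a[None, :], b[None, :])[0])


def iws(col_a, col_b) -> float:
    """Importance-weighted similarity of two normalised columns."""
    a = _as_column(col_a, "col_a")
    b = _as_column(col_b, "col_b")
    # gini product first: commutative, so iws(a, b) == iws(b, a) bit-exactly
    return float(
        pearson_rows(a[None, :], b[None, :])[0]
        * (gini_rows(a[None, :])[0] * gini_rows(b[None, :])[0])
    )


def iws_window(pssm_a_window, pssm_b_window) -> float:
    """Sum of per-column IWS scores over two equal-length windows (20 x k)."""
    A = np.asarray(pssm_a_window, dtype=float)
    B = np.asarray(pssm_b_window, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"window shapes differ: {A.shape} vs {B.shape}")
    if A.shape[0] != _N:
        raise ValueError(f"windows must be {_N} x k matrices")
    cols_a, cols_b = A.T, B.T
    return float(
        (pearson_rows(cols_a, cols_b) * (gini_rows(cols_a) * gini_rows(cols_b))).sum()
    )


def iwd(query_col, comparison_col) -> float:
    """Importance-weighted dissimilarity of a query column vs a comparison.

    Mean absolute difference over the 20 residues, weighted by the query
    column's Gini importance; asymmetric in its arguments.
    """
    q = _as_column(query_col, "query_col")
    c = _as_column(comparison_col, "comparison_col")
    return float(np.abs(q - c).mean() * gini_rows(q[None, :])[0])
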