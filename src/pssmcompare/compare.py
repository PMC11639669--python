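"""Sliding-window PSSM-PSSM alignment and significance.

The smaller PSSM is slid across the larger one column at a time (full
containment, no overhangs).  For each window the per-column IWS scores are
converted to empirical probabilities against the background null, their
product is the window probability, and the uniform product distribution
(UDF) corrects that product for the number of columns compared:

    udf_correct(p, n) = P(U_1 * ... * U_n <= p)   with U_i ~ Uniform(0, 1)
                      = p * sum_{k=0}^{n-1} (-ln p)^k / k!

The most significant window is the optimal alignment; its probability is
Bonferroni-corrected for the number of windows.  The window's maximum
per-column IWD is reported as the dissimilarity score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .background import BackgroundDistribution, iws_p
from .errors import ConfigError
from .metrics import gini_rows, pearson_rows
from .pssm import PSSM

DEFAULT_P_CUTOFF = 0.001
DEFAULT_D_CUTOFF = 1.0


@dataclass
class ColumnPairScore:
    """Scores for one aligned column pair (query column vs comparison column)."""

    similarity: float
    importance_query: float
    importance_comparison: float
    iws: float
    iws_p: float
    iwd: float


@dataclass
class WindowComparison:
    """One alignment offset of the smaller PSSM within the larger."""

    offset: int
    window_length: int
    per_column: list[ColumnPairScore]
    iws_p_win: float
    iws_sig_win: float
    max_iwd: float


@dataclass
class ComparisonResult:
    """Best window of a query-comparison pair plus ranking metadata."""

    query_name: str
    comparison_name: str
    best_window: WindowComparison
    corrected_p: float
    n_windows: int
    dissimilarity: float
    significant: bool
    passes_dissimilarity_filter: bool
    rank: int | None = None


def udf_correct(p: float, n: int) -> float:
    """CDF of a product of ``n`` independent Uniform(0,1) variables at ``p``.

    Evaluated as the upper regularised incomplete gamma function
    ``Q(n, -ln p)`` (equivalently a Poisson CDF), which is numerically stable
    for very small ``p``.  Monotone increasing in ``p`` for fixed ``n``.
    """
    if not (0.0 < p <= 1.0):
        raise ConfigError(f"p must be in (0, 1], got {p}")
    if int(n) != n or n < 1:
        raise ConfigError(f"n must be a positive integer, got {n}")
    if n == 1 or p == 1.0:
        return float(p) if n == 1 else 1.0
    return float(min(1.0, special.gammaincc(int(n), -math.log(p))))


def _check_comparable(query: PSSM, comparison: PSSM) -> None:
    if not query.normalised or not comparison.normalised:
        raise ConfigError(
            "both PSSMs must be min-max normalised before comparison; "
            "apply pssmcompare.normalise first"
        )


def compare_windows(
    query: PSSM,
    comparison: PSSM,
    dist: BackgroundDistribution,
) -> list[WindowComparison]:
    """Score every full-containment alignment of the smaller PSSM in the larger.

    The offset is the 0-based start of the window in the larger PSSM.  IWD
    direction is always query -> comparison, whichever PSSM is smaller.
    """
    _check_comparable(query, comparison)
    n = min(query.length, comparison.length)
    n_windows = abs(query.length - comparison.length) + 1
    query_larger = query.length >= comparison.length

    windows: list[WindowComparison] = []
    for offset in range(n_windows):
        if query_larger:
            qw = query.weights[:, offset : offset + n]
            cw = comparison.weights
        else:
            qw = query.weights
            cw = comparison.weights[:, offset : offset + n]
        q_cols, c_cols = qw.T, cw.T
        sims = pearson_rows(q_cols, c_cols)
        g_q = gini_rows(q_cols)
        g_c = gini_rows(c_cols)
        iws_vals = sims * (g_q * g_c)  # gini product first: swap-exact
        p_vals = iws_p(iws_vals, dist)
        iwd_vals = np.abs(q_cols - c_cols).mean(axis=1) * g_q
        p_win = float(np.prod(p_vals))
        per_column = [
            ColumnPairScore(
                similarity=float(sims[j]),
                importance_query=float(g_q[j]),
                importance_comparison=float(g_c[j]),
                iws=float(iws_vals[j]),
                iws_p=float(p_vals[j]),
                iwd=float(iwd_vals[j]),
            )
            for j in range(n)
        ]
        windows.append(
            WindowComparison(
                offset=offset,
                window_length=n,
                per_column=per_column,
                iws_p_win=p_win,
                iws_sig_win=udf_correct(p_win, n),
                max_iwd=float(iwd_vals.max()),
            )
        )
    return windows


def compare_pssms(
    query: PSSM,
    comparison: PSSM,
    dist: BackgroundDistribution,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    d_cutoff: float = DEFAULT_D_CUTOFF,
) -> ComparisonResult:
    """Best alignment of a PSSM pair with Bonferroni-corrected significance.

    The window with the smallest ``iws_sig_win`` wins (ties: leftmost
    offset); its probability is multiplied by the number of windows compared
    (capped at 1).
    """
    windows = compare_windows(query, comparison, dist)
    best = min(windows, key=lambda w: (w.iws_sig_win, w.offset))
    n_windows = len(windows)
    corrected = min(1.0, best.iws_sig_win * n_windows)
    return ComparisonResult(
        query_name=query.name,
        comparison_name=comparison.name,
        best_window=best,
        corrected_p=corrected,
        n_windows=n_windows,
        dissimilarity=best.max_iwd,
        significant=corrected <= p_cutoff,
        passes_dissimilarity_filter=best.max_iwd < d_cutoff,
    )


def compare_pssm_set(
    query: PSSM,
    comparisons: Sequence[PSSM],
    dist: BackgroundDistribution,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    d_cutoff: float = DEFAULT_D_CUTOFF,
) -> list[ComparisonResult]:
    """Compare a query against a PSSM set; return the ranked result list.

    Sorted ascending by corrected p (ties: ascending dissimilarity, then
    comparison name); 1-based ranks recorded on each result.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ConfigError("comparison set is empty")
    results = [
        compare_pssms(query, c, dist, p_cutoff=p_cutoff, d_cutoff=d_cutoff)
        for c in comparisons
    ]
    results.sort(key=lambda r: (r.corrected_p, r.dissimilarity, r.comparison_name))
    for rank, res in enumerate(results, start=1):
        res.rank = rank
    return results


def all_vs_all_matrix(
    pssms: Sequence[PSSM],
    dist: BackgroundDistribution,
) -> pd.DataFrame:
    """Square matrix of corrected p-values over a PSSM set.

    Entry (i, j) is the corrected p of comparing query i against comparison
    j; the diagonal is computed like any other pair.  Suitable as a distance
    matrix for downstream clustering.
    """
    pssms = list(pssms)
    if len(pssms) < 2:
        raise ConfigError("all-vs-all requires at least 2 PSSMs")
    names = [p.name for p in pssms]
    mat = np.zeros((len(pssms), len(pssms)))
    for i, q in enumerate(pssms):
        for j, c in enumerate(pssms):
            mat[i, j] = compare_pssms(q, c, dist).corrected_p
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Serialisation


def window_to_dict(win: WindowComparison) -> dict:
    return {
        "offset": win.offset,
        "window_length": win.window_length,
        "iws_p_win": win.iws_p_win,
        "iws_sig_win": win.iws_sig_win,
        "max_iwd": win.max_iwd,
        "per_column": [vars(c).copy() for c in win.per_column],
    }


def result_to_dict(res: ComparisonResult) -> dict:
    return {
        "query": res.query_name,
        "comparison": res.comparison_name,
        "offset": res.best_window.offset,
        "window_length": res.best_window.window_length,
        "iws_p_win": res.best_window.iws_p_win,
        "iws_sig_win": res.best_window.iws_sig_win,
        "corrected_p": res.corrected_p,
        "n_windows": res.n_windows,
        "dissimilarity": res.dissimilarity,
        "rank": res.rank,
        "significant": res.significant,
        "passes_dissimilarity_filter": res.passes_dissimilarity_filter,
        "per_column": [vars(c).copy() for c in res.best_window.per_column],
    }


def results_to_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """One-row-per-comparison TSV-ready summary."""
    rows = []
    for r in results:
        d = result_to_dict(r)
        d.pop("per_column")
        rows.append(d)
    return pd.DataFrame(rows)
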