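"""Spearman correlation and Benjamini-Hochberg FDR control.

Spearman's rho is the Pearson correlation of average ranks (ties
averaged).  Two-sided p-values use the t approximation for n >= 10 and
exact enumeration of the permutation distribution below that.  Missing
values are handled pairwise-complete by the callers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

__all__ = ["spearman", "bh_fdr", "behavioral_correlation_matrix"]


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    NaN pairs are dropped (pairwise-complete).  Requires >= 4 complete
    pairs.  Exact permutation p for n <= 9, t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= 9:
        # exact: enumerate all permutations of one rank vector (vectorized)
        perms = np.array(list(itertools.permutations(ry)), dtype=float)
        pc = perms - perms.mean(axis=1, keepdims=True)
        xc = rx - rx.mean()
        denom = np.sqrt((xc**2).sum() * (pc**2).sum(axis=1))
        rhos = pc @ xc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone
    non-decreasing in raw-p order.  Empty input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    # step-up rejection: largest k with p_(k) <= k/m * q, reject all smaller
    thresh = np.arange(1, m + 1) / m * q
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject, p_adj


def behavioral_correlation_matrix(
    table, measures: list[str] | None = None, q: float = 0.05, flip: tuple[str, ...] = ("ran",)
):
    """All-pairs Spearman correlations among cognitive measures with FDR.

    Measures listed in ``flip`` (timed scores where higher = worse, e.g.
    RAN completion time) are multiplied by -1 first so every measure reads
    higher = better.  Returns ``(rho_df, p_df, reject_df)`` DataFrames.
    """
    import pandas as pd

    df = table.copy()
    if measures is None:
        measures = [c for c in df.columns if df[c].dtype.kind in "fc"]
    for name in flip:
        if name in measures:
            df[name] = -df[name]
    k = len(measures)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvals = []
    for i, j in pairs:
        r, p = spearman(df[measures[i]], df[measures[j]])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
        pvals.append(p)
    reject, _ = bh_fdr(pvals, q=q)
    rej = np.zeros((k, k), dtype=bool)
    for (i, j), rj in zip(pairs, reject):
        rej[i, j] = rej[j, i] = rj
    mk = pd.Index(measures)
    return (
        pd.DataFrame(rho, index=mk, columns=mk),
        pd.DataFrame(pmat, index=mk, columns=mk),
        pd.DataFrame(rej, index=mk, columns=mk),
    )
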