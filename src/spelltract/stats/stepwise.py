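"""Forward/backward stepwise linear regression with p-Enter / p-Remove.

Starting from an intercept-only model, each cycle adds the candidate whose
partial F-test (equivalently, the t-test of its coefficient in the
augmented model) has the smallest p-value below ``p_enter``, then removes
any included term whose p-value exceeds ``p_remove`` (worst first), until
a fixpoint.  Ties break deterministically by candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regression import RegressionReport, ols_report

__all__ = ["StepwiseResult", "stepwise_regression"]


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    report: RegressionReport | None
    history: tuple[str, ...]  # "+term" / "-term" events in order


def _coef_pvalues(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return model.pvalues.drop("const")


def stepwise_regression(
    candidates: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Select predictors of ``y`` among the columns of ``candidates``.

    Requires n > k + 1 and no zero-variance or collinear candidates (a
    rank-deficient candidate matrix raises with the offending columns).
    Missing values must be handled by the caller (pairwise-complete).
    """
    X = candidates.astype(float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n != len(y):
        raise ValueError("candidates and y differ in length")
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations for {k} candidates")
    variances = X.var(axis=0)
    dead = list(variances.index[variances == 0])
    if dead:
        raise ValueError(f"zero-variance candidates: {dead}")
    mat = np.column_stack([np.ones(n), X.to_numpy()])
    if np.linalg.matrix_rank(mat) < k + 1:
        # name a minimal dependent set by greedy inspection
        dep = []
        cols = [np.ones(n)]
        for name in X.columns:
            trial = np.column_stack(cols + [X[name].to_numpy()])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                dep.append(name)
            else:
                cols.append(X[name].to_numpy())
        raise ValueError(f"collinear candidate set; dependent columns: {dep}")

    included: list[str] = []
    history: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward step
        best_name, best_p = None, p_enter
        for name in X.columns:  # candidate order breaks ties
            if name in included:
                continue
            p = _coef_pvalues(X[included + [name]], y)[name]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None:
            included.append(best_name)
            history.append(f"+{best_name}")
            changed = True
        # backward steps
        while included:
            pvals = _coef_pvalues(X[included], y)
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                history.append(f"-{worst}")
                changed = True
            else:
                break
        if not changed:
            break
    report = ols_report(X[included], y) if included else None
    return StepwiseResult(tuple(included), report, tuple(history))
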