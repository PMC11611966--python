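"""Gaussian-mixture bimodality analysis of spelling accuracy scores.

A one- and a two-component univariate Gaussian mixture are fitted by EM
(multi-start, variance floor against collapse) and compared by AIC with
3k - 1 free parameters per k-component model (k means, k variances, k - 1
free weights).  When the two-component density is bimodal, the score at
its local minimum between the component means is the criterion used to
split the cohort into low- and high-performing groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.mixture import GaussianMixture

__all__ = [
    "GmmFit",
    "fit_gmm",
    "compare_gmm_aic",
    "mixture_local_minimum",
    "split_groups",
    "normality_test",
]


@dataclass(frozen=True)
class GmmFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    aic: float
    local_min: float | None = None

    @property
    def n_parameters(self) -> int:
        return 3 * self.k - 1

    def density(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for w, m, v in zip(self.weights, self.means, self.variances):
            out += w * sps.norm.pdf(x, m, np.sqrt(v))
        return out


def fit_gmm(scores, k: int, restarts: int = 20, seed: int = 0) -> GmmFit:
    """Fit a k in {1, 2} component Gaussian mixture by multi-start EM.

    Components are sorted by mean.  The variance floor (1e-6) prevents a
    component collapsing onto a repeated score value.  AIC uses
    2 * (3k - 1) - 2 * loglik.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        tol=1e-8,
        max_iter=10_000,
        n_init=restarts if k > 1 else 1,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)
    if not gm.converged_:
        raise RuntimeError(
            f"EM failed to converge in all {restarts} restarts "
            f"(lower bound {gm.lower_bound_:.6g})"
        )
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.reshape(k)[order]
    loglik = float(gm.score(x) * len(x))
    aic = float(2 * (3 * k - 1) - 2 * loglik)
    fit = GmmFit(k, weights, means, variances, loglik, aic)
    if k == 2:
        fit = GmmFit(k, weights, means, variances, loglik, aic,
                     local_min=mixture_local_minimum(fit, strict=False))
    return fit


def compare_gmm_aic(scores, restarts: int = 20, seed: int = 0) -> tuple[GmmFit, GmmFit]:
    """Fit k=1 and k=2 models; returns (fit1, fit2) for AIC comparison."""
    return fit_gmm(scores, 1, restarts, seed), fit_gmm(scores, 2, restarts, seed)


def mixture_local_minimum(fit: GmmFit, strict: bool = True) -> float | None:
    """Location of the density's local minimum between the component means.

    Found by a fine grid scan between the means followed by bounded
    refinement.  Returns ``None`` when the density is unimodal between the
    means (no interior minimum) — with ``strict=True`` that is still a
    valid return; a k=1 fit raises.
    """
    if fit.k != 2:
        raise ValueError("local minimum requires a two-component fit")
    m1, m2 = sorted(fit.means)
    if m2 - m1 < 1e-12:
        raise ValueError("component means are not distinct")
    grid = np.linspace(m1, m2, 2001)
    dens = fit.density(grid)
    i = int(np.argmin(dens))
    if i == 0 or i == len(grid) - 1:
        return None  # unimodal: minimum sits at a mean, not between
    lo, hi = grid[i - 1], grid[i + 1]
    res = optimize.minimize_scalar(
        lambda x: fit.density(x)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def split_groups(scores: pd.DataFrame | np.ndarray, criterion: float):
    """Label participants low (< criterion) / high (>= criterion).

    Accepts a cohort table with a ``score`` column or a plain array.
    Returns ``(labels, counts)`` where labels is a pandas Series of
    "low"/"high" and counts a dict.  Warns if a group is empty.
    """
    if not 0 < criterion < 1:
        raise ValueError("criterion must lie in (0, 1)")
    s = scores["score"] if hasattr(scores, "columns") else pd.Series(np.asarray(scores))
    labels = pd.Series(np.where(s < criterion, "low", "high"), index=s.index, name="group")
    counts = {"low": int((labels == "low").sum()), "high": int((labels == "high").sum())}
    if 0 in counts.values():
        warnings.warn(
            f"group split at {criterion} left an empty group {counts}; "
            "group analyses will be skipped",
            stacklevel=2,
        )
    return labels, counts


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p; valid for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
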