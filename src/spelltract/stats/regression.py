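"""Ordinary least squares with the diagnostics the specificity analysis
reports: unstandardized B, SE, standardized beta, t, p, per-predictor VIF,
and the overall R^2 / F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = ["RegressionReport", "ols_report", "specificity_regression"]


@dataclass(frozen=True)
class RegressionReport:
    terms: tuple[str, ...]  # includes "const"
    coef: np.ndarray  # unstandardized B
    se: np.ndarray
    beta: np.ndarray  # standardized (NaN for the intercept)
    t: np.ndarray
    p: np.ndarray
    vif: np.ndarray  # NaN for the intercept
    r2: float
    f_stat: tuple[float, float, float, float]  # (F, df1, df2, p)
    nobs: int

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "B": self.coef,
                "SE": self.se,
                "beta": self.beta,
                "t": self.t,
                "p": self.p,
                "VIF": self.vif,
            },
            index=list(self.terms),
        )
        df.attrs["r2"] = self.r2
        df.attrs["f_stat"] = self.f_stat
        return df


def ols_report(X: pd.DataFrame, y) -> RegressionReport:
    """Fit y ~ X with intercept and package the report."""
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("perfectly collinear design matrix")
    fit = sm.OLS(y, Xc).fit()
    terms = tuple(Xc.columns)
    sd_y = y.std(ddof=1)
    beta = np.full(len(terms), np.nan)
    vif = np.full(len(terms), np.nan)
    for i, name in enumerate(terms):
        if name == "const":
            continue
        beta[i] = fit.params[name] * X[name].std(ddof=1) / sd_y
        if X.shape[1] > 1:
            vif[i] = variance_inflation_factor(Xc.to_numpy(), list(Xc.columns).index(name))
        else:
            vif[i] = 1.0
    return RegressionReport(
        terms=terms,
        coef=fit.params.to_numpy(),
        se=fit.bse.to_numpy(),
        beta=beta,
        t=fit.tvalues.to_numpy(),
        p=fit.pvalues.to_numpy(),
        vif=vif,
        r2=float(fit.rsquared),
        f_stat=(float(fit.fvalue), float(fit.df_model), float(fit.df_resid), float(fit.f_pvalue)),
        nobs=int(fit.nobs),
    )


def specificity_regression(
    cluster_fa, spelling, vocabulary, spoonerisms, swe
) -> RegressionReport:
    """Does anything beyond spelling explain cluster-FA?

    OLS of cluster-FA on spelling, vocabulary (lexical-semantic), spoonerisms
    (phonological awareness) and sight-word-efficiency (reading) scores,
    with VIF as the collinearity diagnostic.  Rows with missing values are
    dropped listwise first.
    """
    df = pd.DataFrame(
        {
            "spelling": np.asarray(spelling, dtype=float),
            "vocabulary": np.asarray(vocabulary, dtype=float),
            "spoonerisms": np.asarray(spoonerisms, dtype=float),
            "towre_swe": np.asarray(swe, dtype=float),
            "_y": np.asarray(cluster_fa, dtype=float),
        }
    ).dropna()
    if len(df) <= 6:
        raise ValueError("need more than 6 complete observations")
    return ols_report(df.drop(columns="_y"), df["_y"].to_numpy())
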