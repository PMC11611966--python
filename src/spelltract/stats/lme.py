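"""Error-type linear mixed-effects analysis.

Do low and high performers differ more in the orthographic than in the
phonological deviation of their spelling errors?  Per-response distance
values are modelled with fixed effects Group, ErrorType and their
interaction, and crossed random intercepts for subject and item.  Models
are fitted by maximum likelihood (not REML) so the interaction is testable
by a likelihood-ratio test of the full against the no-interaction model.
Outlier participants (mean distance beyond 2.5 SD of their group x
error-type cell) are excluded first.  Simple group effects per error type
use two-sample t-tests on participant means, Bonferroni-corrected for the
two tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = ["LmeResult", "exclude_distance_outliers", "error_type_lme"]

REQUIRED = {"distance", "group", "error_type", "subject", "item"}


@dataclass(frozen=True)
class LmeResult:
    chi2: float
    df: int
    p: float
    fixed_effects: pd.Series
    n_excluded_subjects: int
    simple_effects: pd.DataFrame  # per error type: t, df, p_bonferroni
    loglik_full: float
    loglik_reduced: float


def exclude_distance_outliers(df: pd.DataFrame, sd_threshold: float = 2.5):
    """Drop participants whose mean distance deviates > ``sd_threshold`` SD
    from their group x error-type cell mean (computed over participant
    means).  Returns (filtered_df, excluded_subject_ids)."""
    means = (
        df.groupby(["group", "error_type", "subject"], observed=True)["distance"]
        .mean()
        .reset_index()
    )
    excluded: set = set()
    for (_, _), cell in means.groupby(["group", "error_type"], observed=True):
        mu = cell["distance"].mean()
        sd = cell["distance"].std(ddof=1)
        if not sd or np.isnan(sd):
            continue
        bad = cell.loc[(cell["distance"] - mu).abs() > sd_threshold * sd, "subject"]
        excluded.update(bad)
    return df[~df["subject"].isin(excluded)].copy(), sorted(excluded)


def error_type_lme(data: pd.DataFrame, sd_threshold: float = 2.5) -> LmeResult:
    """Fit the Group x ErrorType mixed model and test the interaction.

    ``data`` is long-format with columns ``distance, group, error_type,
    subject, item`` (two groups, two error types, subjects and items
    crossed).  Raises on non-convergence with the optimizer's message.
    """
    missing = REQUIRED - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = data.dropna(subset=["distance"]).copy()
    if df["group"].nunique() != 2 or df["error_type"].nunique() != 2:
        raise ValueError("need exactly 2 groups and 2 error types")
    df, excluded = exclude_distance_outliers(df, sd_threshold)

    vc = {"subject": "0 + C(subject)", "item": "0 + C(item)"}
    df["_one"] = 1
    kwargs = dict(groups="_one", vc_formula=vc, re_formula="0", data=df)

    def _fit_ml(formula):
        # variance components near a boundary often defeat one optimizer but
        # not another; try a small cascade before giving up
        last = None
        for method in ("lbfgs", "cg", "powell"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, **kwargs).fit(reml=False, method=method)
            last = fit
            if fit.converged:
                return fit
        raise RuntimeError(
            f"mixed model did not converge under any optimizer: {last.summary()}"
        )

    full = _fit_ml("distance ~ group * error_type")
    reduced = _fit_ml("distance ~ group + error_type")
    chi2 = 2 * (full.llf - reduced.llf)
    chi2 = max(float(chi2), 0.0)
    p = float(sps.chi2.sf(chi2, df=1))

    rows = []
    for etype, sub in df.groupby("error_type", observed=True):
        means = sub.groupby(["group", "subject"], observed=True)["distance"].mean()
        groups = sorted(means.index.get_level_values("group").unique())
        a = means.loc[groups[0]].to_numpy()
        b = means.loc[groups[1]].to_numpy()
        t, praw = sps.ttest_ind(a, b)
        rows.append(
            {
                "error_type": etype,
                "t": float(t),
                "df": len(a) + len(b) - 2,
                "p_bonferroni": float(min(praw * 2, 1.0)),
            }
        )
    return LmeResult(
        chi2=chi2,
        df=1,
        p=p,
        fixed_effects=full.fe_params,
        n_excluded_subjects=len(excluded),
        simple_effects=pd.DataFrame(rows),
        loglik_full=float(full.llf),
        loglik_reduced=float(reduced.llf),
    )
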