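"""Lateralization-index inference.

Per tract: a two-tailed one-sample t-test of LI against 0 at a
Bonferroni-adjusted alpha (0.05 / n_tracts); Spearman correlations of LI
with spelling scores and two-sample group comparisons of LI, each
FDR-controlled at 5% across tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .correlation import bh_fdr, spearman

__all__ = ["LiTestReport", "li_tests"]


@dataclass(frozen=True)
class LiTestReport:
    one_sample: pd.DataFrame  # per tract: mean, sd, t, df, p, significant (Bonferroni)
    score_correlation: pd.DataFrame | None  # per tract: rho, p, p_fdr, significant
    group_comparison: pd.DataFrame | None  # per tract: t, df, p, p_fdr, significant
    bonferroni_alpha: float


def li_tests(
    li_table: pd.DataFrame,
    scores=None,
    groups=None,
    alpha: float = 0.05,
    q: float = 0.05,
) -> LiTestReport:
    """Run the lateralization inference battery.

    ``li_table``: participants x tracts LI values (NaN allowed, dropped
    pairwise).  ``scores``/``groups`` are aligned per-participant arrays;
    the corresponding analyses are skipped when absent.
    """
    tracts = list(li_table.columns)
    adj_alpha = alpha / len(tracts)
    rows = []
    for tr in tracts:
        li = li_table[tr].dropna().to_numpy(dtype=float)
        if len(li) < 3:
            raise ValueError(f"tract {tr}: need >= 3 participants")
        if li.std(ddof=1) == 0:
            raise ValueError(f"tract {tr}: zero-variance LI, t-test undefined")
        t, p = sps.ttest_1samp(li, 0.0)
        rows.append(
            {
                "tract": tr,
                "mean_li": li.mean(),
                "sd_li": li.std(ddof=1),
                "t": float(t),
                "df": len(li) - 1,
                "p": float(p),
                "significant": bool(p < adj_alpha),
            }
        )
    one_sample = pd.DataFrame(rows).set_index("tract")

    corr = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        rows = []
        for tr in tracts:
            rho, p = spearman(li_table[tr].to_numpy(dtype=float), s)
            rows.append({"tract": tr, "rho": rho, "p": p})
        corr = pd.DataFrame(rows).set_index("tract")
        reject, p_adj = bh_fdr(corr["p"].to_numpy(), q=q)
        corr["p_fdr"] = p_adj
        corr["significant"] = reject

    comp = None
    if groups is not None:
        g = np.asarray(groups)
        labels = sorted(pd.unique(g[~pd.isna(g)]))
        if len(labels) == 2:
            rows = []
            for tr in tracts:
                li = li_table[tr].to_numpy(dtype=float)
                ok = ~np.isnan(li)
                a = li[ok & (g == labels[0])]
                b = li[ok & (g == labels[1])]
                t, p = sps.ttest_ind(a, b)  # pooled-variance two-sample t
                rows.append(
                    {"tract": tr, "t": float(t), "df": len(a) + len(b) - 2, "p": float(p)}
                )
            comp = pd.DataFrame(rows).set_index("tract")
            reject, p_adj = bh_fdr(comp["p"].to_numpy(), q=q)
            comp["p_fdr"] = p_adj
            comp["significant"] = reject

    return LiTestReport(one_sample, corr, comp, adj_alpha)
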