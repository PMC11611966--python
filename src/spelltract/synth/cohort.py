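"""Synthetic cohort of spelling scores and cognitive covariates.

Emulates the behavioral structure of a difficult 40-item spelling-to-
dictation test administered to neurotypical adults: accuracy scores follow
a two-component Gaussian mixture (a lower-scoring and a higher-scoring
subpopulation), and covariate test scores correlate with spelling to
configurable degrees.  Defaults reproduce the reference study conditions:
73 participants, mixture components (mu, var) = (0.22, 0.008) and
(0.55, 0.041) with weight 41/73 on the low component, scores quantized to
multiples of 1/40.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MixtureSpec", "CohortConfig", "simulate_scores"]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component Gaussian mixture of accuracy scores (variances, not SDs)."""

    w1: float = 41 / 73
    mu1: float = 0.22
    var1: float = 0.008
    mu2: float = 0.55
    var2: float = 0.041

    def __post_init__(self):
        if not 0 < self.w1 < 1:
            raise ValueError("w1 must lie strictly in (0, 1)")
        if self.var1 <= 0 or self.var2 <= 0:
            raise ValueError("component variances must be positive")
        if self.mu1 == self.mu2 and self.var1 == self.var2:
            raise ValueError("degenerate mixture: identical components")

    @property
    def mean(self) -> float:
        return self.w1 * self.mu1 + (1 - self.w1) * self.mu2


# Default covariate loadings: spelling correlates with vocabulary and the
# phonologically reliant tests, but not with sight-word reading; RAN is a
# completion time (higher = slower), hence the negative loading.
DEFAULT_COVARIATES: dict[str, float] = {
    "vocabulary": 0.55,
    "spoonerisms": 0.50,
    "towre_pde": 0.45,
    "nonword_rep": 0.40,
    "towre_swe": 0.10,
    "ran": -0.10,
}


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_participants: int = 73
    n_items: int = 40
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    covariate_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    quantize: bool = True  # round scores to multiples of 1/n_items

    def __post_init__(self):
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        for name, r in self.covariate_loadings.items():
            if not -1 < r < 1:
                raise ValueError(f"covariate loading {name}={r} must lie in (-1, 1)")


def _truncated_normal(rng, mu, sd, size):
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_scores(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table of spelling scores and covariates.

    Returns a DataFrame with columns ``participant_id``, ``score``,
    ``component`` (the true generating mixture component, 1 = low), and one
    column per covariate.  The generating configuration is stored in
    ``DataFrame.attrs["config"]``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    m = config.mixture
    n = config.n_participants
    comp = rng.random(n) < m.w1
    scores = np.where(
        comp,
        _truncated_normal(rng, m.mu1, np.sqrt(m.var1), n),
        _truncated_normal(rng, m.mu2, np.sqrt(m.var2), n),
    )
    if config.quantize:
        scores = np.round(scores * config.n_items) / config.n_items
    z = (scores - scores.mean()) / scores.std()
    data = {
        "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
        "score": scores,
        "component": np.where(comp, 1, 2),
    }
    for name, r in config.covariate_loadings.items():
        noise = rng.standard_normal(n)
        data[name] = r * z + np.sqrt(1 - r**2) * noise
    df = pd.DataFrame(data)
    df.attrs["config"] = asdict(config)
    return df
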