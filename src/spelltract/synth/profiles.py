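"""Synthetic 100-node FA tract profiles with planted score-FA correlations.

Each participant's profile is a smooth baseline FA curve plus smooth
(node-correlated) noise; inside a chosen contiguous node window, FA is
additionally shifted in proportion to the participant's standardized
spelling score, planting a score-FA correlation of a target magnitude in
exactly those nodes.  The effect may be restricted to one performance
group, reproducing the group-specific association structure that the
along-tract analysis is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TractEffectSpec", "default_baseline", "simulate_profiles"]

N_NODES = 100


def default_baseline(n_nodes: int = N_NODES) -> np.ndarray:
    """A smooth, realistic FA curve: higher mid-tract, lower near endpoints."""
    x = np.linspace(0, np.pi, n_nodes)
    return 0.42 + 0.08 * np.sin(x) + 0.02 * np.sin(3 * x)


@dataclass(frozen=True)
class TractEffectSpec:
    """What to plant in one tract's profiles."""

    tract_name: str
    baseline_profile: np.ndarray = field(default_factory=default_baseline)
    noise_sd: float = 0.04
    cluster_nodes: tuple[int, int] | None = None  # 1-based inclusive window
    effect_r: float = 0.0  # signed target score-FA correlation inside window
    group_restriction: str = "all"  # all | high | low
    # additional association across the whole sample in the same window
    # (a tract can predict scores cohort-wide while its node-level cluster
    # is carried by one performance group, as in the study design)
    full_sample_r: float = 0.0

    def __post_init__(self):
        base = np.asarray(self.baseline_profile, dtype=float)
        object.__setattr__(self, "baseline_profile", base)
        if base.ndim != 1 or len(base) != N_NODES:
            raise ValueError(f"baseline profile must have {N_NODES} nodes")
        if not np.all((base > 0) & (base < 1)):
            raise ValueError("baseline FA must lie in (0, 1)")
        if abs(self.effect_r) >= 1 or abs(self.full_sample_r) >= 1:
            raise ValueError("|effect_r| must be < 1")
        if self.cluster_nodes is not None:
            lo, hi = self.cluster_nodes
            if not (1 <= lo <= hi <= N_NODES):
                raise ValueError("cluster_nodes must lie within [1, 100]")
        if self.group_restriction not in ("all", "high", "low"):
            raise ValueError("group_restriction must be all|high|low")


def _smooth_noise(rng, n, n_nodes, sd, window=7):
    """Moving-average noise: adjacent-node FA is correlated in real tracts."""
    if sd == 0:
        return np.zeros((n, n_nodes))
    pad = window // 2
    white = rng.standard_normal((n, n_nodes + 2 * pad))
    kernel = np.ones(window) / window
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, white)
    sm *= np.sqrt(window)  # restore unit variance after averaging
    return sd * sm


def simulate_profiles(
    scores: pd.DataFrame,
    spec: TractEffectSpec,
    seed: int = 0,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate per-participant 100-node FA profiles for one tract.

    ``groups`` (values "high"/"low", indexed like ``scores``) is required
    when the effect is group-restricted; the planted slope is chosen so the
    in-window score-FA correlation has expectation ``effect_r`` within the
    affected subsample.  Returns a participants x 100 DataFrame indexed by
    ``participant_id`` with ``attrs["spec"]`` set.  FA values leaving (0, 1)
    are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n = len(scores)
    s = scores["score"].to_numpy(dtype=float)
    noise = _smooth_noise(rng, n, N_NODES, spec.noise_sd)
    fa = spec.baseline_profile[None, :] + noise

    if spec.cluster_nodes is not None and (spec.effect_r or spec.full_sample_r):
        lo, hi = spec.cluster_nodes
        window = np.arange(lo - 1, hi)

        def _slope(r):
            if spec.noise_sd == 0:
                return np.sign(r) * 0.05
            return spec.noise_sd * r / np.sqrt(1 - r**2)

        if spec.effect_r:
            mask = np.ones(n, dtype=bool)
            if spec.group_restriction != "all":
                if groups is None:
                    raise ValueError("group_restriction set but no groups provided")
                mask = np.asarray(groups) == spec.group_restriction
            z = s[mask]
            z = (z - z.mean()) / (z.std() or 1.0)
            fa[np.ix_(mask, window)] += (_slope(spec.effect_r) * z)[:, None]
        if spec.full_sample_r:
            z_all = (s - s.mean()) / (s.std() or 1.0)
            fa[:, window] += (_slope(spec.full_sample_r) * z_all)[:, None]

    if (fa <= 0).any() or (fa >= 1).any():
        warnings.warn("simulated FA left (0, 1); clipping", stacklevel=2)
        fa = np.clip(fa, 1e-3, 1 - 1e-3)

    df = pd.DataFrame(
        fa,
        index=pd.Index(scores["participant_id"], name="participant_id"),
        columns=[f"node{j + 1:03d}" for j in range(N_NODES)],
    )
    df.attrs["spec"] = spec
    return df
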