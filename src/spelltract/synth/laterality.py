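"""Synthetic per-participant lateralization indices.

Draws participant LI values per tract from normal distributions around
target asymmetries (clipped to [-1, 1]).  Defaults reproduce the
reference cohort-level pattern: right-lateralized SLF-III and ILF,
left-lateralized arcuate and SLF-I, symmetric SLF-II.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_LI_TARGETS", "simulate_laterality"]

# tract -> (mean LI, SD) across participants
DEFAULT_LI_TARGETS: dict[str, tuple[float, float]] = {
    "SLF-I": (-0.19, 0.37),
    "SLF-II": (0.03, 0.18),
    "SLF-III": (0.24, 0.14),
    "Arcuate": (-0.27, 0.18),
    "ILF": (0.46, 0.22),
}


def simulate_laterality(
    participant_ids,
    targets: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    score_loading: dict[str, float] | None = None,
    scores=None,
) -> pd.DataFrame:
    """Participants x tracts LI table.

    ``score_loading`` optionally correlates a tract's LI with standardized
    spelling scores (e.g. a weak positive loading on the SLF-III).
    """
    targets = targets or DEFAULT_LI_TARGETS
    rng = np.random.default_rng(seed)
    n = len(participant_ids)
    z = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        z = (s - s.mean()) / (s.std() or 1.0)
    data = {}
    for tract, (mu, sd) in targets.items():
        vals = rng.normal(mu, sd, size=n)
        r = (score_loading or {}).get(tract, 0.0)
        if r and z is not None:
            vals = mu + sd * (r * z + np.sqrt(1 - r**2) * (vals - mu) / sd)
        data[tract] = np.clip(vals, -1.0, 1.0)
    return pd.DataFrame(data, index=pd.Index(participant_ids, name="participant_id"))
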