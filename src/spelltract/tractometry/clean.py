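"""Tract screening: iterative outlier-streamline removal.

Two rules, applied simultaneously each iteration against the statistics of
the current surviving set, until a fixpoint (or an iteration cap):

* length rule (one-sided): drop streamlines *longer* than
  ``mean + length_sd * SD`` of tract length;
* spatial rule: drop streamlines whose maximum node-wise deviation from
  the tract core exceeds ``spatial_sd`` standard deviations, where the
  core is the node-wise mean coordinate and deviation is Mahalanobis under
  the node-wise position covariance (Euclidean, scaled by the node-wise
  RMS spread, behind a flag).

Removing all violators of the current iteration at once makes the result
independent of streamline order.
"""

from __future__ import annotations

import numpy as np

from .geometry import CleaningParams
from .segment import Tract
from .streamlines import resample_streamline, streamline_length

__all__ = ["CleaningError", "clean_tract", "tract_core"]

N_NODES_CLEAN = 100


class CleaningError(RuntimeError):
    def __init__(self, rule: str):
        self.rule = rule
        super().__init__(f"cleaning removed every streamline (rule: {rule})")


def tract_core(streamlines: list[np.ndarray] | Tract) -> np.ndarray:
    """Node-wise mean coordinate of a resampled, co-oriented bundle."""
    sls = streamlines.streamlines if isinstance(streamlines, Tract) else streamlines
    if not sls:
        raise ValueError("cannot take the core of an empty bundle")
    lengths = {len(s) for s in sls}
    if len(lengths) != 1:
        raise ValueError("streamlines must be resampled to a common node count")
    return np.mean(np.stack(sls), axis=0)


def _node_deviations(stack: np.ndarray, metric: str) -> np.ndarray:
    """Per-streamline max node deviation from the core, in SD units.

    stack: (n_streamlines, n_nodes, 3).
    """
    core = stack.mean(axis=0)
    diff = stack - core[None, :, :]
    n_sl, n_nodes, _ = stack.shape
    dev = np.empty((n_sl, n_nodes))
    for j in range(n_nodes):
        d = diff[:, j, :]
        if metric == "mahalanobis" and n_sl > 3:
            cov = np.cov(d.T)
            try:
                prec = np.linalg.pinv(cov)
            except np.linalg.LinAlgError:
                prec = None
            if prec is not None and np.isfinite(prec).all():
                dev[:, j] = np.sqrt(np.maximum(np.einsum("ni,ij,nj->n", d, prec, d), 0))
                continue
        # Euclidean fallback: distance over RMS radial spread
        scale = np.sqrt(np.mean(np.sum(d**2, axis=1))) or 1.0
        dev[:, j] = np.linalg.norm(d, axis=1) / scale
    return dev.max(axis=1)


def clean_tract(tract: Tract, params: CleaningParams | None = None) -> Tract:
    """Iteratively screen a tract's streamlines; returns a new Tract."""
    params = params or tract.definition.cleaning
    sls = list(tract.streamlines)
    if len(sls) < 3:
        raise ValueError("cleaning needs at least 3 streamlines")
    keep_idx = np.arange(len(sls))
    resampled = np.stack([resample_streamline(s, N_NODES_CLEAN) for s in sls])
    lengths = np.array([streamline_length(s) for s in sls])

    n_removed_total = 0
    for _ in range(params.max_iterations):
        cur_len = lengths[keep_idx]
        sd = cur_len.std(ddof=1) if len(cur_len) > 1 else 0.0
        too_long = (
            cur_len > cur_len.mean() + params.length_sd * sd
            if sd > 0
            else np.zeros(len(cur_len), dtype=bool)
        )
        dev = _node_deviations(resampled[keep_idx], params.distance_metric)
        # deviations are already in SD-like units; threshold directly
        too_far = dev > params.spatial_sd
        bad = too_long | too_far
        if not bad.any():
            break
        if bad.all():
            rule = "length" if too_long.all() else "spatial"
            raise CleaningError(rule)
        n_removed_total += int(bad.sum())
        keep_idx = keep_idx[~bad]
    kept = [sls[i] for i in keep_idx]
    meta = dict(tract.metadata)
    meta["n_removed"] = n_removed_total
    return Tract(tract.definition, kept, metadata=meta)
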