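"""Waypoint-ROI tract segmentation.

A streamline belongs to a tract when it intersects every AND ROI and no
NOT ROI.  Kept streamlines are reoriented so that traversal runs from the
first AND ROI to the last (e.g. frontal -> parietal), making node numbering
comparable across streamlines, participants and hemispheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import TractDefinition
from .streamlines import Tractogram

__all__ = ["Tract", "segment_tract"]


@dataclass
class Tract:
    """Streamlines assigned to one named tract, co-oriented."""

    definition: TractDefinition
    streamlines: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def hemisphere(self) -> str:
        return self.definition.hemisphere

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def segment_tract(tractogram: Tractogram, definition: TractDefinition) -> Tract:
    """Select and co-orient the streamlines matching a tract definition.

    An empty result is allowed; it is flagged in ``metadata["empty"]`` and
    warned about (mirrors tracts that cannot be identified in a
    participant — downstream analyses then drop that participant pairwise).
    """
    if len(tractogram) == 0:
        raise ValueError("tractogram is empty")
    and_rois = definition.and_rois
    not_rois = definition.not_rois
    first_roi, last_roi = and_rois[0], and_rois[-1]
    kept: list[np.ndarray] = []
    for s in tractogram:
        if not all(r.intersects(s) for r in and_rois):
            continue
        if any(r.intersects(s) for r in not_rois):
            continue
        i_first = first_roi.crossing_arc_index(s)
        i_last = last_roi.crossing_arc_index(s)
        if i_first is not None and i_last is not None and i_first > i_last:
            s = s[::-1].copy()
        kept.append(np.asarray(s, dtype=float))
    tract = Tract(definition, kept, metadata={"empty": len(kept) == 0})
    if not kept:
        warnings.warn(
            f"no streamlines matched {definition.name} ({definition.hemisphere})",
            stacklevel=2,
        )
    return tract
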