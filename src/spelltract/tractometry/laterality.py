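"""Hemispheric lateralization of streamline counts.

LI = (right - left) / (right + left); positive values indicate right
lateralization, negative left.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LateralityRecord", "lateralization_index"]


def lateralization_index(n_right: int, n_left: int) -> float:
    """Streamline-count lateralization index in [-1, 1]."""
    if n_right < 0 or n_left < 0:
        raise ValueError("streamline counts must be non-negative")
    total = n_right + n_left
    if total == 0:
        raise ValueError("LI is undefined when both hemispheres have 0 streamlines")
    return (n_right - n_left) / total


@dataclass(frozen=True)
class LateralityRecord:
    tract: str
    n_right: int
    n_left: int

    @property
    def li(self) -> float:
        return lateralization_index(self.n_right, self.n_left)
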