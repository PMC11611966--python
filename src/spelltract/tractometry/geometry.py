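"""Waypoint ROI geometry and tract definitions.

A tract is defined by ordered waypoint ROIs: streamlines must pass through
every AND region and avoid every NOT region.  ROIs are axis-aligned plane
segments (a plane at a fixed coordinate, with finite extent in the other
two axes) or boxes.  The 3-branch SLF scheme uses three ROIs per branch:
a branch-specific frontal AND plane, a shared parietal AND plane, and a
temporal NOT box excluding arcuate fibres.

Real template-space ROIs are study-specific inputs; the presets here live
in a synthetic toy coordinate frame (x: left-/right+, y: posterior-/
anterior+, z: inferior-/superior+, origin mid-brain) and exist so the
whole pipeline can run and be tested end to end on simulated bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["WaypointROI", "TractDefinition", "CleaningParams", "toy_tract_definitions"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class WaypointROI:
    """Axis-aligned plane segment or box with an AND/NOT role.

    ``plane`` form: ``axis`` + ``coord`` + finite ``bounds`` (the box the
    plane segment spans; its extent along ``axis`` is a slab of thickness
    ``2 * tol``).  ``box`` form: only ``bounds``.
    """

    name: str
    role: str  # AND | NOT
    kind: str  # plane | box
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    axis: str | None = None
    coord: float | None = None
    tol: float = 0.5

    def __post_init__(self):
        if self.role not in ("AND", "NOT"):
            raise ValueError("ROI role must be 'AND' or 'NOT'")
        if self.kind not in ("plane", "box"):
            raise ValueError("ROI kind must be 'plane' or 'box'")
        if self.kind == "plane" and (self.axis not in _AXES or self.coord is None):
            raise ValueError("plane ROI needs axis and coord")
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (3, 2) or not np.all(np.isfinite(b)):
            raise ValueError("bounds must be finite (3, 2)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the region."""
        pts = np.asarray(points, dtype=float)
        b = np.asarray(self.bounds, dtype=float)
        inside = np.all((pts >= b[:, 0]) & (pts <= b[:, 1]), axis=1)
        if self.kind == "plane":
            k = _AXES[self.axis]
            inside &= np.abs(pts[:, k] - self.coord) <= self.tol
        return inside

    def intersects(self, streamline: np.ndarray) -> bool:
        """True if any point lies inside, or (planes) a segment crosses the
        plane within the bounds — guarding against point-sampling artifacts."""
        pts = np.asarray(streamline, dtype=float)
        if self.contains(pts).any():
            return True
        if self.kind != "plane":
            return False
        k = _AXES[self.axis]
        d = pts[:, k] - self.coord
        sign_change = d[:-1] * d[1:] < 0
        if not sign_change.any():
            return False
        b = np.asarray(self.bounds, dtype=float)
        for i in np.flatnonzero(sign_change):
            t = d[i] / (d[i] - d[i + 1])
            p = pts[i] + t * (pts[i + 1] - pts[i])
            if np.all((p >= b[:, 0]) & (p <= b[:, 1])):
                return True
        return False

    def crossing_arc_index(self, streamline: np.ndarray) -> float | None:
        """Index (fractional) of the first intersection along the streamline."""
        pts = np.asarray(streamline, dtype=float)
        inside = self.contains(pts)
        first: float | None = float(np.argmax(inside)) if inside.any() else None
        if self.kind == "plane":
            k = _AXES[self.axis]
            d = pts[:, k] - self.coord
            b = np.asarray(self.bounds, dtype=float)
            for i in np.flatnonzero(d[:-1] * d[1:] < 0):
                t = d[i] / (d[i] - d[i + 1])
                p = pts[i] + t * (pts[i + 1] - pts[i])
                if np.all((p >= b[:, 0]) & (p <= b[:, 1])):
                    idx = i + t
                    first = idx if first is None else min(first, idx)
                    break
        return first


@dataclass(frozen=True)
class CleaningParams:
    """Outlier-removal thresholds (in SD units) for tract screening."""

    length_sd: float = 3.0
    spatial_sd: float = 4.0
    max_iterations: int = 5
    distance_metric: str = "mahalanobis"  # or "euclidean"

    def __post_init__(self):
        if self.length_sd <= 0 or self.spatial_sd <= 0:
            raise ValueError("cleaning SD thresholds must be positive")


@dataclass(frozen=True)
class TractDefinition:
    name: str
    hemisphere: str  # L | R
    rois: tuple[WaypointROI, ...]
    cleaning: CleaningParams = field(default_factory=CleaningParams)

    def __post_init__(self):
        object.__setattr__(self, "rois", tuple(self.rois))
        if sum(r.role == "AND" for r in self.rois) < 2:
            raise ValueError("a tract definition needs >= 2 AND ROIs")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")

    @property
    def and_rois(self) -> tuple[WaypointROI, ...]:
        return tuple(r for r in self.rois if r.role == "AND")

    @property
    def not_rois(self) -> tuple[WaypointROI, ...]:
        return tuple(r for r in self.rois if r.role == "NOT")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "TractDefinition":
        rois = tuple(WaypointROI(**r) for r in obj["rois"])
        cleaning = CleaningParams(**obj.get("cleaning", {}))
        return cls(obj["name"], obj["hemisphere"], rois, cleaning)


def _hemi_bounds(hemisphere: str, y, z):
    x = (2.0, 50.0) if hemisphere == "R" else (-50.0, -2.0)
    return (x, tuple(y), tuple(z))


def toy_tract_definitions(hemisphere: str = "L") -> dict[str, TractDefinition]:
    """Named tract presets in the synthetic toy frame.

    Frontal AND planes sit on the anterior-commissure coronal plane
    (y = +15), the shared parietal AND plane on the posterior-commissure
    plane (y = -15); the temporal NOT box lies below the Sylvian proxy
    (z < -5).  SLF branches are stacked dorsoventrally (SLF-I highest).
    SLF cleaning uses the adjusted 1-SD length threshold; all other tracts
    use 3 SD.  Spatial threshold is 4 SD throughout.
    """
    h = hemisphere
    slf_clean = CleaningParams(length_sd=1.0, spatial_sd=4.0)
    defs: dict[str, TractDefinition] = {}
    frontal_z = {"SLF-I": (24.0, 44.0), "SLF-II": (10.0, 25.0), "SLF-III": (-6.0, 10.0)}
    temporal_not = WaypointROI(
        name="temporal-NOT",
        role="NOT",
        kind="box",
        bounds=_hemi_bounds(h, (-20.0, 12.0), (-40.0, -5.0)),
    )
    for branch, zb in frontal_z.items():
        frontal = WaypointROI(
            name=f"{branch}-frontal",
            role="AND",
            kind="plane",
            axis="y",
            coord=15.0,
            bounds=_hemi_bounds(h, (14.0, 16.0), zb),
        )
        parietal = WaypointROI(
            name="parietal",
            role="AND",
            kind="plane",
            axis="y",
            coord=-15.0,
            bounds=_hemi_bounds(h, (-16.0, -14.0), (-10.0, 45.0)),
        )
        defs[branch] = TractDefinition(branch, h, (frontal, parietal, temporal_not), slf_clean)
    arc_frontal = WaypointROI(
        name="Arcuate-frontal",
        role="AND",
        kind="plane",
        axis="y",
        coord=15.0,
        bounds=_hemi_bounds(h, (14.0, 16.0), (-8.0, 14.0)),
    )
    arc_temporal = WaypointROI(
        name="Arcuate-temporal",
        role="AND",
        kind="plane",
        axis="z",
        coord=-8.0,
        bounds=_hemi_bounds(h, (-20.0, 0.0), (-9.0, -7.0)),
    )
    defs["Arcuate"] = TractDefinition("Arcuate", h, (arc_frontal, arc_temporal))
    ilf_posterior = WaypointROI(
        name="ILF-occipital",
        role="AND",
        kind="plane",
        axis="y",
        coord=-30.0,
        bounds=_hemi_bounds(h, (-31.0, -29.0), (-30.0, 0.0)),
    )
    ilf_anterior = WaypointROI(
        name="ILF-anterior-temporal",
        role="AND",
        kind="plane",
        axis="y",
        coord=10.0,
        bounds=_hemi_bounds(h, (9.0, 11.0), (-30.0, 0.0)),
    )
    defs["ILF"] = TractDefinition("ILF", h, (ilf_posterior, ilf_anterior))
    return defs


def save_definitions(defs: dict[str, TractDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: d.to_json() for k, d in defs.items()}, fh, indent=1)


def load_definitions(path: str | Path) -> dict[str, TractDefinition]:
    with open(path) as fh:
        obj = json.load(fh)
    return {k: TractDefinition.from_json(v) for k, v in obj.items()}
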