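"""Synthetic streamline bundles in the toy coordinate frame.

Generates smooth noisy 3D curves that thread the waypoint ROIs of the toy
tract definitions (see :mod:`spelltract.tractometry.geometry`), with
controllable left/right streamline-count asymmetry (the LI target is met
exactly), and optional injected outliers that deviate in length and
lateral offset — fodder for the screening rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..tractometry.streamlines import Tractogram

__all__ = ["BundleGeometry", "toy_bundle_geometries", "simulate_bundle"]


@dataclass(frozen=True)
class BundleGeometry:
    """Centerline control points (right-hemisphere frame; left is mirrored)."""

    name: str
    control_points: np.ndarray  # (k, 3) mm
    spread: float = 1.5  # lateral SD of streamline offsets, mm

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        object.__setattr__(self, "control_points", cp)
        if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
            raise ValueError("need >= 2 control points of shape (k, 3)")
        if not np.isfinite(cp).all():
            raise ValueError("control points must be finite")
        if np.any(np.linalg.norm(np.diff(cp, axis=0), axis=1) < 1e-9):
            raise ValueError("infeasible geometry: coincident control points")


def toy_bundle_geometries() -> dict[str, BundleGeometry]:
    """Centerlines matching the toy tract definitions (right hemisphere)."""
    return {
        "SLF-I": BundleGeometry(
            "SLF-I", [(25, 30, 34), (25, 15, 34), (25, 0, 35), (25, -15, 34), (25, -30, 33)]
        ),
        "SLF-II": BundleGeometry(
            "SLF-II", [(25, 30, 17.5), (25, 15, 17.5), (25, 0, 18.5), (25, -15, 17.5), (25, -30, 17)]
        ),
        "SLF-III": BundleGeometry(
            "SLF-III", [(25, 30, 2.5), (25, 15, 2.5), (25, 0, 3.5), (25, -15, 2.5), (25, -30, 2)]
        ),
        "Arcuate": BundleGeometry(
            "Arcuate", [(25, 30, 3), (25, 18, 5), (25, -5, 10), (25, -16, -2), (25, -14, -20)]
        ),
        "ILF": BundleGeometry(
            "ILF", [(30, -40, -15), (30, -30, -15), (30, -10, -14), (30, 10, -15), (30, 18, -15)]
        ),
    }


def _centerline(cp: np.ndarray, n_points: int = 80) -> np.ndarray:
    """Densely sample the polyline through the control points, then smooth
    the corners with a short moving average (endpoints pinned)."""
    seg = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0, s[-1], n_points)
    line = np.column_stack([np.interp(t, s, cp[:, k]) for k in range(3)])
    kernel = np.ones(5) / 5
    sm = line.copy()
    for k in range(3):
        sm[2:-2, k] = np.convolve(line[:, k], kernel, mode="valid")
    return sm


def simulate_bundle(
    geometry: BundleGeometry,
    n_streamlines: int = 200,
    asymmetry: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    jitter_sd: float = 0.3,
) -> Tractogram:
    """Simulate a bilateral bundle with an exact LI target.

    ``asymmetry`` is the target lateralization index: with ``n_streamlines``
    total, the right hemisphere receives ``round(n * (1 + LI) / 2)``
    streamlines and the left the rest (left streamlines are the mirrored
    geometry).  ``outlier_fraction`` of streamlines are perturbed to
    violate the screening rules (8x lateral offset and ~double length).
    Hemisphere labels are in ``metadata["hemisphere"]``.
    """
    if not -1 <= asymmetry <= 1:
        raise ValueError("asymmetry (LI target) must lie in [-1, 1]")
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_right = int(round(n_streamlines * (1 + asymmetry) / 2))
    n_left = n_streamlines - n_right
    base = _centerline(geometry.control_points)
    n_pts = len(base)

    streamlines: list[np.ndarray] = []
    hemis: list[str] = []
    outlier_flags: list[bool] = []
    for hemi, count in (("R", n_right), ("L", n_left)):
        for _ in range(count):
            offset = rng.normal(0, geometry.spread, size=3)
            jitter = np.cumsum(rng.normal(0, jitter_sd / np.sqrt(n_pts), (n_pts, 3)), axis=0)
            s = base + offset + jitter - jitter.mean(axis=0)
            is_outlier = rng.random() < outlier_fraction
            if is_outlier:
                s = s + rng.normal(0, 8 * geometry.spread, size=3)
                tangent = s[-1] - s[-2]
                tangent /= np.linalg.norm(tangent) or 1.0
                total = np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                ext = s[-1] + np.outer(np.linspace(0, total, 20)[1:], tangent)
                s = np.vstack([s, ext])
            if hemi == "L":
                s = s * np.array([-1.0, 1.0, 1.0])
            streamlines.append(s)
            hemis.append(hemi)
            outlier_flags.append(is_outlier)
    return Tractogram(
        streamlines,
        metadata={
            "bundle": geometry.name,
            "hemisphere": hemis,
            "outlier": outlier_flags,
            "li_target": asymmetry,
            "n_right": n_right,
            "n_left": n_left,
            "seed": seed,
        },
    )
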