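"""Streamline containers, arc-length resampling, and tractogram / FA I/O.

A streamline is an ordered (N, 3) float array of points in millimetres.  A
tractogram is a list of streamlines plus free-form metadata.  Supported
formats: TCK (via nibabel) and plain CSV coordinate tables
(``streamline_id,x,y,z`` with points in order).  FA can be sampled from a
NIfTI volume (trilinear interpolation) or from any callable mapping an
(N, 3) point array to N scalar values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Tractogram",
    "streamline_length",
    "resample_streamline",
    "load_tractogram",
    "save_tractogram",
    "NiftiFASampler",
    "constant_fa",
]


def streamline_length(points: np.ndarray) -> float:
    """Arc length: sum of consecutive Euclidean distances (mm)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("a streamline needs >= 2 points of shape (N, 3)")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_streamline(points: np.ndarray, n: int = 100) -> np.ndarray:
    """Resample to *n* arc-length-equidistant points, endpoints preserved."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("a streamline needs >= 2 points of shape (N, 3)")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, k]) for k in range(3)])


@dataclass
class Tractogram:
    """A collection of streamlines in a common mm coordinate frame."""

    streamlines: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)

    def __getitem__(self, i) -> np.ndarray:
        return self.streamlines[i]

    def lengths(self) -> np.ndarray:
        return np.array([streamline_length(s) for s in self.streamlines])


def load_tractogram(path: str | Path) -> Tractogram:
    """Load a TCK file or a CSV coordinate table (``streamline_id,x,y,z``)."""
    path = Path(path)
    if path.suffix.lower() == ".tck":
        import nibabel as nib

        tck = nib.streamlines.load(str(path))
        return Tractogram(
            [np.asarray(s, dtype=float) for s in tck.streamlines],
            metadata={"source": str(path), "format": "tck"},
        )
    df = pd.read_csv(path)
    required = {"streamline_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    sls = [
        grp[["x", "y", "z"]].to_numpy(dtype=float)
        for _, grp in df.groupby("streamline_id", sort=True)
    ]
    return Tractogram(sls, metadata={"source": str(path), "format": "csv"})


def save_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    """Write TCK (``.tck``) or CSV coordinate table (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".tck":
        import nibabel as nib

        tck = nib.streamlines.TckFile(
            nib.streamlines.Tractogram(
                tractogram.streamlines, affine_to_rasmm=np.eye(4)
            )
        )
        tck.save(str(path))
        return
    frames = []
    for i, s in enumerate(tractogram.streamlines):
        frames.append(
            pd.DataFrame({"streamline_id": i, "x": s[:, 0], "y": s[:, 1], "z": s[:, 2]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class NiftiFASampler:
    """Sample an FA NIfTI volume at mm coordinates (trilinear interpolation)."""

    def __init__(self, img_or_path):
        import nibabel as nib

        img = (
            img_or_path
            if hasattr(img_or_path, "get_fdata")
            else nib.load(str(img_or_path))
        )
        self._data = np.asarray(img.get_fdata(), dtype=float)
        self._inv_affine = np.linalg.inv(img.affine)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        pts = np.asarray(points, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        vox = (self._inv_affine @ hom.T)[:3]
        return map_coordinates(self._data, vox, order=1, mode="nearest")


def constant_fa(value: float) -> Callable[[np.ndarray], np.ndarray]:
    """A uniform FA field (useful for fixtures and invariants)."""

    def sampler(points: np.ndarray) -> np.ndarray:
        return np.full(len(points), float(value))

    return sampler
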