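"""Minimal 3D volume container with anisotropic voxel spacing and NIfTI I/O.

Voxel coordinates are 0-based array indices throughout; world coordinates
live in the NIfTI affine (diagonal spacing, no rotation — phantoms and
pre-registered inputs need nothing more).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_SPACING = (0.8, 0.8, 4.4)  # mm, T1-space acquisition grid


@dataclass
class VolumeGrid:
    """A 3D scalar field on a regular anisotropic grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D array, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.spacing) + [1.0])

    def same_geometry(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), spacing)


def require_same_geometry(**grids: VolumeGrid) -> None:
    """Raise ValueError naming the offending grid on any shape/spacing mismatch."""
    items = list(grids.items())
    ref_name, ref = items[0]
    for name, g in items[1:]:
        if not ref.same_geometry(g):
            raise ValueError(
                f"geometry mismatch: {name} has shape {g.shape} spacing {g.spacing}, "
                f"expected {ref.shape} / {ref.spacing} (from {ref_name})"
            )
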