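"""Phantom MRI generator: co-registered anisotropic volumes with inserted
tubular hyperintense structures and voxel-exact ground truth.

The phantom emulates the inputs of the PVS segmentation stage: a T2-like
intensity volume on the anisotropic T1-space grid (0.8 x 0.8 x 4.4 mm by
default), a region label map built from the parcellation registry, and
disjoint white-matter (WM) and basal-ganglia (BG) masks. PVS-like tubes are
rasterized in physical millimetres — a voxel belongs to a tube if its center
lies within the tube radius of the axis segment — so a 1-mm-radius tube spans
2-3 voxels in-plane but less than one slice, matching the anisotropy of the
emulated acquisition.

Tubes are near-in-plane by default (``max_tilt_deg`` small). With 4.4-mm
slices, a steeply inclined tube rasterizes to in-plane segments that are
laterally far apart in consecutive slices, so it is not 26-connected; and a
through-plane tube stacks full disks whose interior voxels have most of
their 26 neighbours inside the tube, destroying the local-contrast signal
the segmentation relies on. Near-in-plane tubes avoid both degeneracies.

Geometry of the background: the volume is partitioned into a regular grid of
boxes, each assigned one registry label (boxes beyond the registry are
background). Intensity is a per-region constant plus nothing else, scaled by
a smooth multiplicative bias field (to exercise intensity uniformization)
and Gaussian noise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from ..atlas import RegionRegistry, build_registry
from ..volume import DEFAULT_SPACING, VolumeGrid

CONN26 = np.ones((3, 3, 3), dtype=bool)  # face/edge/corner contact


@dataclass(frozen=True)
class GroundTruthPVS:
    """One inserted tube: its voxel set, seed region, and intensity elevation."""

    voxel_set: frozenset[tuple[int, int, int]]
    seed_region: int
    contrast: float

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if not self.voxel_set:
            raise ValueError("empty voxel set")


@dataclass
class Phantom:
    """Co-registered synthetic volumes plus ground truth."""

    t2_like: VolumeGrid
    label_map: VolumeGrid
    wm_mask: VolumeGrid
    bg_mask: VolumeGrid
    truth: list[GroundTruthPVS] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, grid in [("label_map", self.label_map),
                           ("wm_mask", self.wm_mask), ("bg_mask", self.bg_mask)]:
            if not self.t2_like.same_geometry(grid):
                raise ValueError(f"{name} geometry differs from t2_like")
        if np.any(self.wm_mask.values.astype(bool) & self.bg_mask.values.astype(bool)):
            raise ValueError("wm_mask and bg_mask overlap")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.wm_mask.values.astype(bool) | self.bg_mask.values.astype(bool)

    def truth_mask(self) -> np.ndarray:
        m = np.zeros(self.t2_like.shape, dtype=bool)
        for t in self.truth:
            for v in t.voxel_set:
                m[v] = True
        return m

    def save(self, outdir: str | Path, prefix: str = "phantom") -> dict[str, Path]:
        """Write NIfTI volumes and a ground-truth CSV; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "t2": outdir / f"{prefix}_t2.nii.gz",
            "labels": outdir / f"{prefix}_labels.nii.gz",
            "wm_mask": outdir / f"{prefix}_wm_mask.nii.gz",
            "bg_mask": outdir / f"{prefix}_bg_mask.nii.gz",
            "truth": outdir / f"{prefix}_truth.csv",
        }
        self.t2_like.save(paths["t2"])
        VolumeGrid(self.label_map.values.astype(np.int32),
                   self.label_map.spacing).save(paths["labels"])
        VolumeGrid(self.wm_mask.values.astype(np.uint8),
                   self.wm_mask.spacing).save(paths["wm_mask"])
        VolumeGrid(self.bg_mask.values.astype(np.uint8),
                   self.bg_mask.spacing).save(paths["bg_mask"])
        with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["tube_id", "seed_region", "voxel_count",
                        "centroid_i", "centroid_j", "centroid_k", "contrast"])
            for i, t in enumerate(self.truth):
                vox = np.array(sorted(t.voxel_set))
                c = vox.mean(axis=0)
                w.writerow([i, t.seed_region, len(t.voxel_set),
                            f"{c[0]:.3f}", f"{c[1]:.3f}", f"{c[2]:.3f}",
                            f"{t.contrast:g}"])
        return paths


def _block_label_map(shape: tuple[int, int, int],
                     registry: RegionRegistry) -> np.ndarray:
    """Partition the volume into a box grid and assign registry labels.

    Chooses the most cube-like box grid with at least ``len(registry)``
    cells; surplus cells (and nothing else) are background.
    """
    n_needed = len(registry)
    best = None
    for nx in range(1, shape[0] + 1):
        for ny in range(1, shape[1] + 1):
            nz_min = math.ceil(n_needed / (nx * ny))
            for nz in (nz_min, nz_min + 1):
                if nz > shape[2] or nx * ny * nz < n_needed:
                    continue
                # prefer balanced cells, measured in voxels per cell side
                sides = (shape[0] / nx, shape[1] / ny, shape[2] / nz)
                spread = max(sides) / min(sides)
                waste = nx * ny * nz - n_needed
                key = (spread, waste)
                if best is None or key < best[0]:
                    best = (key, (nx, ny, nz))
    nx, ny, nz = best[1]
    ids = registry.label_ids
    labels = np.zeros(shape, dtype=np.int32)
    xb = np.linspace(0, shape[0], nx + 1).astype(int)
    yb = np.linspace(0, shape[1], ny + 1).astype(int)
    zb = np.linspace(0, shape[2], nz + 1).astype(int)
    idx = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if idx < len(ids):
                    labels[xb[i]:xb[i + 1], yb[j]:yb[j + 1], zb[k]:zb[k + 1]] = ids[idx]
                idx += 1
    return labels


def _bias_field(shape: tuple[int, int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative bias: one low-frequency mode across the volume."""
    if amplitude == 0:
        return np.ones(shape)
    ax = [np.linspace(0.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return 1.0 + amplitude * np.sin(np.pi * gx) * np.cos(np.pi * gy) * np.cos(
        0.5 * np.pi * gz
    )


def _rasterize_tube(p0: np.ndarray, p1: np.ndarray, radius: float,
                    spacing: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxels (N x 3 int array) whose centers lie within ``radius`` mm of the
    axis segment p0-p1 (mm coordinates; voxel center of index i is i*spacing)."""
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius) / spacing).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = idx * spacing
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(centers - p0, axis=1)
    else:
        t = np.clip((centers - p0) @ d / seg_len2, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        dist = np.linalg.norm(centers - proj, axis=1)
    return idx[dist <= radius]


def _is_connected_26(voxels: np.ndarray) -> bool:
    if len(voxels) == 0:
        return False
    lo = voxels.min(axis=0)
    box = np.zeros(voxels.max(axis=0) - lo + 1, dtype=bool)
    box[tuple((voxels - lo).T)] = True
    _, n = ndimage.label(box, structure=CONN26)
    return n == 1


def generate_phantom(
    shape: tuple[int, int, int] = (64, 64, 16),
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    n_pvs: int = 50,
    radius_mm: tuple[float, float] = (0.5, 1.0),
    length_mm: tuple[float, float] = (4.0, 12.0),
    contrast: float = 120.0,
    noise_sd: float = 2.0,
    bias_amplitude: float = 0.05,
    region_intensity_sd: float = 5.0,
    base_intensity: float = 100.0,
    max_tilt_deg: float = 5.0,
    seed: int = 0,
    registry: RegionRegistry | None = None,
    max_tries_per_tube: int = 500,
) -> Phantom:
    """Generate a co-registered phantom with ``n_pvs`` non-touching tubes.

    Parameters
    ----------
    contrast : float
        Intensity elevation of tube voxels above the local background, in the
        same (arbitrary) units as the segmentation threshold. The default is
        twice the canonical threshold of 60.
    noise_sd : float
        Additive Gaussian noise standard deviation (0 for a noiseless phantom).
    bias_amplitude : float
        Relative amplitude of the smooth multiplicative bias field.
    region_intensity_sd : float
        SD of the per-region constant intensity offsets around
        ``base_intensity`` (kept small against the threshold so region
        borders never masquerade as PVSs).
    max_tilt_deg : float
        Maximum tube tilt out of the axial plane. See module docstring for
        why the default is small.

    Raises
    ------
    RuntimeError
        If ``n_pvs`` pairwise non-adjacent tubes cannot be placed within the
        retry budget.
    """
    if n_pvs < 0:
        raise ValueError("n_pvs must be >= 0")
    if not (0 < radius_mm[0] <= radius_mm[1]):
        raise ValueError(f"invalid radius range {radius_mm}")
    if not (0 < length_mm[0] <= length_mm[1]):
        raise ValueError(f"invalid length range {length_mm}")
    rng = np.random.default_rng(seed)
    spacing_arr = np.asarray(spacing, dtype=float)
    registry = registry if registry is not None else build_registry()

    labels = _block_label_map(shape, registry)
    bg_ids = {r.label_id for r in registry if r.group == "basal_ganglia"}
    is_bg = np.isin(labels, sorted(bg_ids))
    wm_mask = (labels > 0) & ~is_bg
    bg_mask = (labels > 0) & is_bg
    tissue = labels > 0

    # per-region constant background intensity
    offsets = {rid: rng.normal(0.0, region_intensity_sd)
               for rid in registry.label_ids}
    background = np.full(shape, base_intensity, dtype=float)
    for rid, off in offsets.items():
        background[labels == rid] = base_intensity + off

    # place tubes
    occupied = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)  # occupied dilated by 1 (26-conn)
    truth: list[GroundTruthPVS] = []
    extent = spacing_arr * (np.asarray(shape) - 1)
    max_tilt = math.radians(max_tilt_deg)
    slice_centers = np.arange(shape[2]) * spacing_arr[2]

    for _ in range(n_pvs):
        placed = False
        for _try in range(max_tries_per_tube):
            radius = rng.uniform(*radius_mm)
            length = rng.uniform(*length_mm)
            azim = rng.uniform(0.0, 2.0 * math.pi)
            tilt = rng.uniform(-max_tilt, max_tilt)
            d = np.array([math.cos(azim) * math.cos(tilt),
                          math.sin(azim) * math.cos(tilt),
                          math.sin(tilt)])
            cx = rng.uniform(0.0, extent[0])
            cy = rng.uniform(0.0, extent[1])
            # anchor the axis near a slice-center plane so the thin tube
            # actually intersects voxel centers of that slice
            cz = rng.choice(slice_centers) + rng.uniform(-0.3, 0.3) * radius
            center = np.array([cx, cy, cz])
            p0 = center - 0.5 * length * d
            p1 = center + 0.5 * length * d
            vox = _rasterize_tube(p0, p1, radius, spacing_arr, shape)
            if len(vox) < 2:
                continue
            # keep tubes off the volume border: truncated neighbourhoods and
            # boundary effects of field estimation would erode their contrast
            if np.any(vox.min(axis=0) < 1) or np.any(
                    vox.max(axis=0) >= np.asarray(shape) - 1):
                continue
            if not np.all(tissue[tuple(vox.T)]):
                continue
            if np.any(forbidden[tuple(vox.T)]):
                continue
            if not _is_connected_26(vox):
                continue
            occupied[tuple(vox.T)] = True
            tube_mask = np.zeros(shape, dtype=bool)
            tube_mask[tuple(vox.T)] = True
            forbidden |= ndimage.binary_dilation(tube_mask, structure=CONN26)
            centroid = tuple(int(round(c)) for c in vox.mean(axis=0))
            seed_region = int(labels[centroid]) if labels[centroid] > 0 else int(
                labels[tuple(vox[0])]
            )
            truth.append(GroundTruthPVS(
                voxel_set=frozenset(map(tuple, vox.tolist())),
                seed_region=seed_region, contrast=float(contrast)))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tube {len(truth) + 1}/{n_pvs} after "
                f"{max_tries_per_tube} tries; phantom too small or too crowded")

    t2 = background + contrast * occupied.astype(float)
    t2 = t2 * _bias_field(shape, bias_amplitude)
    if noise_sd > 0:
        t2 = t2 + rng.normal(0.0, noise_sd, size=shape)

    return Phantom(
        t2_like=VolumeGrid(t2, spacing),
        label_map=VolumeGrid(labels, spacing),
        wm_mask=VolumeGrid(wm_mask.astype(np.uint8), spacing),
        bg_mask=VolumeGrid(bg_mask.astype(np.uint8), spacing),
        truth=truth,
    )
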