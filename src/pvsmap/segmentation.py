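"""PVS segmentation by local intensity contrast, 26-connected clustering,
and per-cluster morphometrics.

A voxel inside the white-matter or basal-ganglia mask is a PVS voxel when
its intensity exceeds the mean of its surrounding voxels by strictly more
than a threshold (default 60, in uniformized intensity units; a difference
of exactly 60 is not a PVS). PVS voxels sharing a face, edge, or corner
(26-connectivity) form one cluster. Because slice thickness exceeds PVS
thickness on the anisotropic grid, volumes are voxel counts and diameters
are measured in-plane, per axial slice.

The "surrounding voxels" kernel is configurable: the default is the full
3x3x3 shell (26 neighbours); an in-plane 3x3 shell (8 neighbours) is
offered for strongly anisotropic acquisitions. At volume borders the
neighbourhood is truncated to in-volume voxels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeGrid, require_same_geometry

log = logging.getLogger(__name__)

CONN26 = np.ones((3, 3, 3), dtype=bool)

#: sentinel region for clusters lying entirely on background
BACKGROUND_REGION = 0

KERNELS = ("3d26", "inplane8")


@dataclass
class SegmentationConfig:
    """Parameters of the local-contrast PVS detector."""

    diff_threshold: float = 60.0
    kernel: str = "3d26"
    connectivity: int = 26  # edge-or-corner contact; fixed
    uniformize: bool = True
    uniformize_fwhm_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity (edge/corner contact) is supported")


@dataclass
class PVSCluster:
    """A 26-connected set of supra-threshold voxels."""

    voxels: np.ndarray  # (N, 3) int indices
    volume_voxels: int = 0
    diameter_mm: float | None = None
    region_label: int | None = None
    network_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[1] != 3:
            raise ValueError("voxels must be an (N, 3) index array")
        self.volume_voxels = len(self.voxels)

    @property
    def voxel_set(self) -> frozenset[tuple[int, int, int]]:
        return frozenset(map(tuple, self.voxels.tolist()))

    @property
    def centroid(self) -> np.ndarray:
        return self.voxels.mean(axis=0)


def uniformize(volume: VolumeGrid, mask: VolumeGrid,
               fwhm_mm: float = 10.0) -> VolumeGrid:
    """Divide out a smooth low-frequency intensity field estimated in ``mask``.

    The field is a large-FWHM Gaussian smoothing of the masked intensities
    (normalized convolution, so the estimate is unbiased up to curvature
    near mask borders); the output is rescaled so the masked median is
    preserved. On an already-flat image the operation is the identity up to
    floating-point tolerance.
    """
    require_same_geometry(volume=volume, mask=mask)
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("uniformize: mask is empty")
    sigma_vox = [fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s
                 for s in volume.spacing]
    vals = volume.values.astype(float)
    num = ndimage.gaussian_filter(np.where(m, vals, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(m.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        fld = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 1.0)
    fld = np.where(fld > 1e-12, fld, 1.0)
    out = vals / fld
    med_in = float(np.median(vals[m]))
    med_out = float(np.median(out[m]))
    if med_out != 0:
        out *= med_in / med_out
    return VolumeGrid(out, volume.spacing)


def _neighbor_kernel(kernel: str) -> np.ndarray:
    if kernel == "3d26":
        k = np.ones((3, 3, 3))
        k[1, 1, 1] = 0.0
    elif kernel == "inplane8":
        k = np.ones((3, 3, 1))
        k[1, 1, 0] = 0.0
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return k


def local_contrast(volume: VolumeGrid, mask: VolumeGrid,
                   kernel: str = "3d26") -> VolumeGrid:
    """Voxel intensity minus the mean of its surrounding voxels, inside ``mask``.

    The surrounding-voxel mean is taken over in-volume neighbours only
    (truncated at borders); voxels outside the mask get 0.
    """
    require_same_geometry(volume=volume, mask=mask)
    k = _neighbor_kernel(kernel)
    vals = volume.values.astype(float)
    nbr_sum = ndimage.convolve(vals, k, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(np.ones_like(vals), k, mode="constant", cval=0.0)
    contrast = vals - nbr_sum / nbr_cnt
    contrast[~mask.values.astype(bool)] = 0.0
    return VolumeGrid(contrast, volume.spacing)


def segment(volume: VolumeGrid, wm_mask: VolumeGrid, bg_mask: VolumeGrid,
            config: SegmentationConfig | None = None) -> VolumeGrid:
    """Binary PVS mask: masked voxels whose local contrast strictly exceeds
    the threshold."""
    config = config or SegmentationConfig()
    require_same_geometry(volume=volume, wm_mask=wm_mask, bg_mask=bg_mask)
    tissue = VolumeGrid(
        (wm_mask.values.astype(bool) | bg_mask.values.astype(bool)).astype(np.uint8),
        volume.spacing)
    work = volume
    if config.uniformize:
        work = uniformize(volume, tissue, config.uniformize_fwhm_mm)
    contrast = local_contrast(work, tissue, config.kernel)
    pvs = contrast.values > config.diff_threshold
    return VolumeGrid(pvs.astype(np.uint8), volume.spacing)


def cluster(pvs_mask: VolumeGrid) -> list[PVSCluster]:
    """26-connectivity connected-component labeling of the PVS mask."""
    labeled, n = ndimage.label(pvs_mask.values.astype(bool), structure=CONN26)
    out = []
    for i in range(1, n + 1):
        vox = np.argwhere(labeled == i)
        out.append(PVSCluster(voxels=vox))
    return out


def measure_diameter(cl: PVSCluster,
                     spacing: tuple[float, float, float]) -> float:
    """Maximum over axial slices of the equivalent circular diameter.

    Per slice intersected by the cluster, in-plane area = (voxels in slice)
    x (in-plane voxel area in mm^2) and the equivalent diameter is
    ``2 * sqrt(area / pi)``; the cluster diameter is the slice maximum.
    In-plane because slice thickness exceeds PVS thickness.
    """
    if cl.volume_voxels == 0:
        raise ValueError("cannot measure an empty cluster")
    area_vox = float(spacing[0]) * float(spacing[1])
    _, counts = np.unique(cl.voxels[:, 2], return_counts=True)
    best = int(counts.max())
    return 2.0 * math.sqrt(best * area_vox / math.pi)


def assign_region(cl: PVSCluster, label_map: VolumeGrid) -> int:
    """Majority region label over the cluster's voxels, ignoring background.

    Ties break to the smallest label id; clusters entirely on background get
    the sentinel :data:`BACKGROUND_REGION` (and are excluded from region
    metrics downstream).
    """
    labels = label_map.values[tuple(cl.voxels.T)]
    labels = labels[labels != 0]
    if len(labels) == 0:
        log.info("cluster at %s lies entirely on background; excluded",
                 np.round(cl.centroid, 1))
        return BACKGROUND_REGION
    ids, counts = np.unique(labels, return_counts=True)
    return int(ids[counts == counts.max()].min())


def segment_and_measure(volume: VolumeGrid, wm_mask: VolumeGrid,
                        bg_mask: VolumeGrid, label_map: VolumeGrid,
                        config: SegmentationConfig | None = None
                        ) -> tuple[VolumeGrid, list[PVSCluster]]:
    """Full stage: segment, cluster, and attach diameter and region to each
    cluster. Returns (pvs_mask, clusters)."""
    require_same_geometry(volume=volume, label_map=label_map)
    mask = segment(volume, wm_mask, bg_mask, config)
    clusters = cluster(mask)
    for cl in clusters:
        cl.diameter_mm = measure_diameter(cl, volume.spacing)
        cl.region_label = assign_region(cl, label_map)
    log.info("segmented %d clusters, %d PVS voxels", len(clusters),
             int(mask.values.sum()))
    return mask, clusters
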