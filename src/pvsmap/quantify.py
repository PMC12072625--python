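"""Per-region and per-network PVS metric tables, normalizations, and the
Potter visual rating scale.

Each registry region gets four variables — PVS count, total PVS volume (in
voxels, because slice thickness exceeds PVS thickness), mean PVS diameter
(mm), and the region's own voxel volume — so a strict 72-area quantification
yields 288 data points per subject. Size normalizations divide PVS volume
and count by the voxel count of the containing region ("PVS volume
fraction" / "PVS count fraction"); whole-brain WM PVS volume is normalized
by WM volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NETWORKS, SIDES, RegionRegistry
from .segmentation import BACKGROUND_REGION, PVSCluster
from .volume import VolumeGrid

log = logging.getLogger(__name__)


@dataclass
class RegionMetrics:
    label_id: int
    pvs_count: int
    pvs_volume_voxels: int
    pvs_diameter_mm: float  # mean over clusters in region; 0 if none
    region_voxels: int

    @property
    def volume_fraction(self) -> float:
        return self.pvs_volume_voxels / self.region_voxels if self.region_voxels else 0.0

    @property
    def count_fraction(self) -> float:
        return self.pvs_count / self.region_voxels if self.region_voxels else 0.0


@dataclass
class NetworkMetrics:
    network: str
    side: str
    count: int
    volume_voxels: int
    diameter_mm: float  # cluster-count-weighted mean of member-region diameters


@dataclass
class SubjectQuantification:
    """All quantified variables for one subject."""

    region_metrics: list[RegionMetrics]
    network_metrics: list[NetworkMetrics]
    wm_volume_voxels: int

    @property
    def total_wm_pvs_volume(self) -> int:
        return sum(r.pvs_volume_voxels for r in self.region_metrics)

    @property
    def wm_normalized_pvs_volume(self) -> float:
        return (self.total_wm_pvs_volume / self.wm_volume_voxels
                if self.wm_volume_voxels else 0.0)

    def region_frame(self, subject: str = "subject") -> pd.DataFrame:
        """Long-format table: one row per (region, variable)."""
        rows = []
        for r in self.region_metrics:
            for var, val in [("pvs_count", r.pvs_count),
                             ("pvs_volume_voxels", r.pvs_volume_voxels),
                             ("pvs_diameter_mm", r.pvs_diameter_mm),
                             ("region_voxels", r.region_voxels)]:
                rows.append((subject, r.label_id, var, val))
        return pd.DataFrame(rows, columns=["subject", "region", "variable", "value"])

    def network_frame(self, subject: str = "subject") -> pd.DataFrame:
        rows = [(subject, n.network, n.side, n.count, n.volume_voxels,
                 n.diameter_mm) for n in self.network_metrics]
        return pd.DataFrame(rows, columns=["subject", "network", "side",
                                           "count", "volume_voxels",
                                           "diameter_mm"])


def quantify_regions(clusters: Sequence[PVSCluster], label_map: VolumeGrid,
                     registry: RegionRegistry) -> list[RegionMetrics]:
    """One :class:`RegionMetrics` row per registry region (zero-filled where
    no clusters land). Clusters must already carry region assignments and
    diameters; a cluster assigned to a label absent from the registry is an
    error, a background-assigned cluster is skipped with a log line."""
    region_voxels = {rid: 0 for rid in registry.label_ids}
    ids, counts = np.unique(label_map.values[label_map.values > 0],
                            return_counts=True)
    for rid, c in zip(ids, counts):
        if int(rid) in region_voxels:
            region_voxels[int(rid)] = int(c)

    per_region: dict[int, list[PVSCluster]] = {rid: [] for rid in registry.label_ids}
    n_background = 0
    for cl in clusters:
        if cl.region_label is None:
            raise ValueError("cluster lacks a region assignment; run assign_region")
        if cl.region_label == BACKGROUND_REGION:
            n_background += 1
            continue
        if cl.region_label not in per_region:
            raise KeyError(
                f"cluster assigned to label {cl.region_label}, which is not in "
                f"the registry")
        per_region[cl.region_label].append(cl)
    if n_background:
        log.info("%d cluster(s) on background excluded from region metrics",
                 n_background)

    out = []
    for rid in registry.label_ids:
        cls = per_region[rid]
        diam = float(np.mean([c.diameter_mm for c in cls])) if cls else 0.0
        out.append(RegionMetrics(
            label_id=rid,
            pvs_count=len(cls),
            pvs_volume_voxels=int(sum(c.volume_voxels for c in cls)),
            pvs_diameter_mm=diam,
            region_voxels=region_voxels[rid],
        ))
    return out


def quantify_regions_from_table(cluster_table: pd.DataFrame,
                                label_map: VolumeGrid,
                                registry: RegionRegistry) -> list[RegionMetrics]:
    """Like :func:`quantify_regions`, but from a written cluster table
    (columns region_label, volume_voxels, diameter_mm)."""
    region_voxels = {rid: 0 for rid in registry.label_ids}
    ids, counts = np.unique(label_map.values[label_map.values > 0],
                            return_counts=True)
    for rid, c in zip(ids, counts):
        if int(rid) in region_voxels:
            region_voxels[int(rid)] = int(c)
    grouped = cluster_table[cluster_table["region_label"] != BACKGROUND_REGION]
    unknown = set(grouped["region_label"].astype(int)) - set(registry.label_ids)
    if unknown:
        raise KeyError(f"cluster table references labels not in the registry: "
                       f"{sorted(unknown)}")
    agg = grouped.groupby("region_label").agg(
        pvs_count=("volume_voxels", "size"),
        pvs_volume_voxels=("volume_voxels", "sum"),
        pvs_diameter_mm=("diameter_mm", "mean"))
    out = []
    for rid in registry.label_ids:
        if rid in agg.index:
            row = agg.loc[rid]
            out.append(RegionMetrics(rid, int(row["pvs_count"]),
                                     int(row["pvs_volume_voxels"]),
                                     float(row["pvs_diameter_mm"]),
                                     region_voxels[rid]))
        else:
            out.append(RegionMetrics(rid, 0, 0, 0.0, region_voxels[rid]))
    return out


def aggregate_networks(region_metrics: Sequence[RegionMetrics],
                       registry: RegionRegistry) -> list[NetworkMetrics]:
    """Roll region metrics up into 6 rows (3 networks x 2 sides).

    Counts and volumes are sums over member regions; the network diameter is
    the cluster-count-weighted mean of member-region diameters (0 when the
    network holds no clusters). Regions outside every network contribute
    nowhere.
    """
    by_id = {m.label_id: m for m in region_metrics}
    missing = [rid for rid in registry.label_ids if rid not in by_id]
    if missing:
        raise ValueError(f"region metrics missing for labels {missing}")
    out = []
    for net in NETWORKS:
        for side in SIDES:
            members = [by_id[r.label_id] for r in registry
                       if r.hemisphere == side and net in r.networks]
            count = sum(m.pvs_count for m in members)
            volume = sum(m.pvs_volume_voxels for m in members)
            diam = (sum(m.pvs_count * m.pvs_diameter_mm for m in members) / count
                    if count else 0.0)
            out.append(NetworkMetrics(net, side, count, volume, diam))
    return out


def quantify_subject(clusters: Sequence[PVSCluster], label_map: VolumeGrid,
                     wm_mask: VolumeGrid, registry: RegionRegistry
                     ) -> SubjectQuantification:
    region_metrics = quantify_regions(clusters, label_map, registry)
    return SubjectQuantification(
        region_metrics=region_metrics,
        network_metrics=aggregate_networks(region_metrics, registry),
        wm_volume_voxels=int(wm_mask.values.astype(bool).sum()),
    )


# Potter et al. visual rating bins: 0; 1-10; 11-20; 21-40; >40
_POTTER_UPPER = (0, 10, 20, 40)


def potter_score(pvs_count: int) -> int:
    """Ordinal 0-4 visual rating from a PVS count (bin upper bounds
    inclusive: 0 -> 0, 1-10 -> 1, 11-20 -> 2, 21-40 -> 3, >40 -> 4)."""
    if pvs_count < 0:
        raise ValueError("pvs_count must be non-negative")
    for score, upper in enumerate(_POTTER_UPPER):
        if pvs_count <= upper:
            return score
    return 4


def compare_visual_vs_quantitative(counts: Sequence[float],
                                   scores: Sequence[float]
                                   ) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) between
    quantitative PVS counts and visual scores. Returns (rho, p)."""
    counts = np.asarray(counts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if counts.shape != scores.shape or counts.ndim != 1:
        raise ValueError("counts and scores must be 1D of equal length")
    if len(counts) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(counts == counts[0]) or np.all(scores == scores[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(counts, scores)
    return float(res.statistic), float(res.pvalue)
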