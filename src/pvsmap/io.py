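"""Tabular I/O: cluster, region, and network tables as round-trip-safe CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .segmentation import PVSCluster

CLUSTER_COLUMNS = ["cluster_id", "region_label", "volume_voxels",
                   "diameter_mm", "centroid_i", "centroid_j", "centroid_k"]


def write_cluster_table(clusters: Sequence[PVSCluster],
                        path: str | Path) -> pd.DataFrame:
    rows = []
    for i, cl in enumerate(clusters):
        c = cl.centroid
        rows.append({
            "cluster_id": i,
            "region_label": cl.region_label,
            "volume_voxels": cl.volume_voxels,
            "diameter_mm": cl.diameter_mm,
            "centroid_i": c[0], "centroid_j": c[1], "centroid_k": c[2],
        })
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cluster table lacks columns: {missing}")
    return df
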