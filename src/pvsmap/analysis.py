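"""Extreme-of-outcome group comparison of network-level PVS burden.

The cohort is split on one symptom into its two extreme categories
(intermediate and unknown subjects are excluded), and each of the 18
(network, side, measure) cells — 3 networks x 2 hemispheres x {count,
volume, diameter} — is compared between the groups with a two-sided
Mann-Whitney U test at alpha = 0.05. Per (network, side), the number of
significant measures maps to a severity color: 0 -> none, 1 -> yellow,
2 -> orange, 3 -> red.

No multiplicity correction is applied by default; Benjamini-Hochberg FDR is
available behind a flag.

The statsmodels-style surface is :class:`PVSGroupComparison` (model) whose
``fit()`` returns :class:`GroupComparisonResults` (estimates, severity map,
``summary()``, ``plot_severity()``); the underlying operations
(:func:`split_cohort`, :func:`mann_whitney`, :func:`run_comparisons`,
:func:`severity_map`) are plain functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NETWORKS, SIDES

MEASURES = ("count", "volume", "diameter")
ALPHA_DEFAULT = 0.05

SEVERITY_COLORS = {0: "none", 1: "yellow", 2: "orange", 3: "red"}


@dataclass(frozen=True)
class SplitSpec:
    """Extreme-of-outcome split on one symptom column.

    ``low`` / ``high`` are the category values forming the asymptomatic and
    symptomatic extremes; everything else (intermediates, unknowns) is
    excluded.
    """

    symptom: str
    low: frozenset = frozenset()
    high: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.low & self.high:
            raise ValueError("low and high categories overlap")


#: packaged splits mirroring the emulated study's group definitions
SPLITS: dict[str, SplitSpec] = {
    # no/low language impairment vs non-verbal; intermediates excluded
    "language": SplitSpec("language", frozenset({"none_low"}), frozenset({"absent"})),
    # sensorially unimpaired vs impaired; unknowns excluded
    "sensory": SplitSpec("sensory", frozenset({"no"}), frozenset({"yes"})),
    # without vs with motor stereotypies; unknowns excluded
    "stereotypies": SplitSpec("stereotypies", frozenset({"no"}), frozenset({"yes"})),
    # DSM-5 support level 1 vs 3; level 2 excluded
    "support_level": SplitSpec("support_level", frozenset({1}), frozenset({3})),
}


def split_cohort(cohort: pd.DataFrame, spec: SplitSpec
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into (low, high, excluded) by the split spec."""
    if spec.symptom not in cohort.columns:
        raise KeyError(f"cohort has no column {spec.symptom!r}")
    col = cohort[spec.symptom]
    in_low = col.isin(spec.low) & col.notna()
    in_high = col.isin(spec.high) & col.notna()
    low, high = cohort[in_low], cohort[in_high]
    excluded = cohort[~(in_low | in_high)]
    if len(low) == 0 or len(high) == 0:
        raise ValueError(
            f"split on {spec.symptom!r} leaves an empty group "
            f"(low n={len(low)}, high n={len(high)})")
    return low, high, excluded


def mann_whitney(low: Sequence[float], high: Sequence[float]
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U reported for the
    low group.

    The exact null distribution is used when the combined sample is small
    (n <= 20) and tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if len(low) < 1 or len(high) < 1:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([low, high])
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def run_comparisons(cohort: pd.DataFrame, spec: SplitSpec,
                    measures: Sequence[str] = MEASURES,
                    alpha: float = ALPHA_DEFAULT,
                    fdr: bool = False) -> pd.DataFrame:
    """One Mann-Whitney comparison per (network, side, measure) cell.

    Returns a DataFrame with columns network, side, measure, n_low, n_high,
    U, p, significant, median_low, iqr_low, median_high, iqr_high. With
    ``fdr=True`` the significance flag (and a ``p_adj`` column) use
    Benjamini-Hochberg-adjusted p-values.
    """
    low, high, _ = split_cohort(cohort, spec)
    rows = []
    for net in NETWORKS:
        for side in SIDES:
            for meas in measures:
                col = f"{net}_{side}_{meas}"
                if col not in cohort.columns:
                    raise KeyError(f"cohort has no metric column {col!r}")
                lo = low[col].to_numpy(dtype=float)
                hi = high[col].to_numpy(dtype=float)
                u, p = mann_whitney(lo, hi)
                rows.append({
                    "network": net, "side": side, "measure": meas,
                    "n_low": len(lo), "n_high": len(hi),
                    "U": u, "p": p,
                    "median_low": float(np.median(lo)), "iqr_low": _iqr(lo),
                    "median_high": float(np.median(hi)), "iqr_high": _iqr(hi),
                })
    df = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        rej, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
        df["significant"] = rej
    else:
        df["significant"] = df["p"] < alpha
    return df


def severity_map(results: pd.DataFrame) -> dict[tuple[str, str], dict]:
    """Per (network, side): number of significant measures and severity color.

    Requires all 18 cells (3 networks x 2 sides x 3 measures).
    """
    need = {(n, s, m) for n in NETWORKS for s in SIDES for m in MEASURES}
    have = set(zip(results["network"], results["side"], results["measure"]))
    missing = need - have
    if missing:
        raise ValueError(f"results missing cells: {sorted(missing)}")
    out = {}
    for net in NETWORKS:
        for side in SIDES:
            sub = results[(results["network"] == net) & (results["side"] == side)
                          & results["measure"].isin(MEASURES)]
            k = int(sub["significant"].sum())
            out[(net, side)] = {"n_significant": k, "color": SEVERITY_COLORS[k]}
    return out


def severity_to_json(sev: dict[tuple[str, str], dict], path: str | Path) -> None:
    flat = {f"{net}_{side}": v for (net, side), v in sev.items()}
    Path(path).write_text(json.dumps(flat, indent=2) + "\n", encoding="utf-8")


def severity_from_json(path: str | Path) -> dict[tuple[str, str], dict]:
    flat = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    for key, v in flat.items():
        net, _, side = key.rpartition("_")
        out[(net, side)] = {"n_significant": int(v["n_significant"]),
                            "color": str(v["color"])}
    return out


class PVSGroupComparison:
    """Model: extreme-of-outcome comparison of network PVS burden.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with symptom columns and
        ``{network}_{side}_{measure}`` metric columns.
    split : SplitSpec or str
        A split specification, or the name of a packaged preset
        (``language``, ``sensory``, ``stereotypies``, ``support_level``).
    """

    def __init__(self, cohort: pd.DataFrame, split: SplitSpec | str,
                 measures: Sequence[str] = MEASURES,
                 alpha: float = ALPHA_DEFAULT, fdr: bool = False):
        if isinstance(split, str):
            try:
                split = SPLITS[split]
            except KeyError:
                raise ValueError(
                    f"unknown symptom {split!r}; valid options: "
                    f"{sorted(SPLITS)}") from None
        self.cohort = cohort
        self.split = split
        self.measures = tuple(measures)
        self.alpha = float(alpha)
        self.fdr = bool(fdr)

    @classmethod
    def from_csv(cls, path: str | Path, split: SplitSpec | str,
                 **kwargs) -> "PVSGroupComparison":
        from .synthetic.cohort import load_cohort

        return cls(load_cohort(path), split, **kwargs)

    def fit(self) -> "GroupComparisonResults":
        low, high, excluded = split_cohort(self.cohort, self.split)
        comparisons = run_comparisons(self.cohort, self.split, self.measures,
                                      self.alpha, self.fdr)
        return GroupComparisonResults(self, comparisons,
                                      (len(low), len(high), len(excluded)))


@dataclass
class GroupComparisonResults:
    """Fitted results: the 18-cell comparison table and the severity map."""

    model: PVSGroupComparison
    comparisons: pd.DataFrame
    group_sizes: tuple[int, int, int]  # (low, high, excluded)

    @property
    def severity(self) -> dict[tuple[str, str], dict]:
        return severity_map(self.comparisons)

    def summary(self) -> str:
        lo, hi, ex = self.group_sizes
        lines = [
            "Extreme-of-outcome PVS network comparison",
            "=" * 57,
            f"symptom: {self.model.split.symptom}   "
            f"groups: low n={lo}, high n={hi}, excluded n={ex}",
            f"test: Mann-Whitney U (two-sided), alpha={self.model.alpha:g}"
            + ("  [BH-FDR]" if self.model.fdr else ""),
            "-" * 57,
            f"{'network':<9}{'side':<7}{'measure':<10}{'U':>7}{'p':>9}  sig",
        ]
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"{r['network']:<9}{r['side']:<7}{r['measure']:<10}"
                f"{r['U']:>7.1f}{r['p']:>9.4f}  {'*' if r['significant'] else ''}")
        lines.append("-" * 57)
        for (net, side), v in self.severity.items():
            lines.append(f"{net:<9}{side:<7}{v['n_significant']} abnormal "
                         f"-> {v['color']}")
        return "\n".join(lines)

    def save(self, outdir: str | Path, prefix: str = "comparison"
             ) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"results": outdir / f"{prefix}_results.csv",
                 "severity": outdir / f"{prefix}_severity.json"}
        self.comparisons.to_csv(paths["results"], index=False)
        severity_to_json(self.severity, paths["severity"])
        return paths

    def plot_severity(self, ax=None, title: str | None = None):
        """Render the severity map as a 3x2 colored grid (one tile per
        network and hemisphere)."""
        from .plotting import plot_severity_map

        return plot_severity_map(self.severity, ax=ax,
                                 title=title or self.model.split.symptom)
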