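"""Synthetic subject cohorts with exact categorical marginals and
configurable network-level PVS-burden effects.

A cohort is a pandas DataFrame with one row per subject: demographics
(sex, age), symptom categories (language impairment level, sensory
disturbance, motor stereotypies, DSM-5 support level 1-3), white-matter
volume, and one column per (network, side, measure) PVS metric, named
``{network}_{side}_{measure}`` (e.g. ``CEN_FPN_left_volume``).

Default marginals reproduce the emulated 36-subject cohort exactly (not in
expectation): 22 M / 14 F; language 17 none-low / 4 intermediate / 15
absent; sensory 20 yes / 13 no / 3 unknown; stereotypies 17 yes / 16 no /
3 unknown; support level 10 / 6 / 20. Unknown symptom values are assigned
to the last subjects in enrollment order so split sizes are reproducible.

Baseline metric model (the emulated study reports no per-region burden
distributions, so these are the generator's own stated conditions):
counts are Poisson, volumes and diameters lognormal — positive,
right-skewed, standard for morphometry. Effects are expressed in baseline-SD
units ``d``: lognormal metrics are multiplied by ``exp(d * sigma_log)``
(a d-SD location shift on the log scale, which rank tests cannot tell from
a d-SD normal shift), Poisson rates become ``lambda + d * sqrt(lambda)``.
Effects apply to the symptomatic (high) group of ``effect_symptom``; the
male elevation of WM-PVS burden applies to count and volume metrics of
male subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ..atlas import NETWORKS, SIDES

MEASURES = ("count", "volume", "diameter")

#: column name for one (network, side, measure) cell
def metric_columns() -> list[str]:
    return [f"{n}_{s}_{m}" for n in NETWORKS for s in SIDES for m in MEASURES]


def _check_marginal(name: str, counts: Mapping, n: int) -> None:
    total = sum(counts.values())
    if total != n:
        raise ValueError(
            f"{name} marginal sums to {total}, expected n_subjects = {n}")
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"{name} marginal has negative counts")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``effect_sizes`` maps ``(network, side, measure)`` to an effect ``d`` in
    baseline-SD units, applied to the high group of ``effect_symptom``.
    ``seed`` fixes all randomness.
    """

    n_subjects: int = 36
    sex_counts: dict[str, int] = field(
        default_factory=lambda: {"M": 22, "F": 14})
    language_counts: dict[str, int] = field(
        default_factory=lambda: {"none_low": 17, "intermediate": 4, "absent": 15})
    sensory_counts: dict[str, int] = field(
        default_factory=lambda: {"yes": 20, "no": 13, "unknown": 3})
    stereotypies_counts: dict[str, int] = field(
        default_factory=lambda: {"yes": 17, "no": 16, "unknown": 3})
    support_counts: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 20})
    age_mean: float = 4.0
    age_sd: float = 2.3
    age_range: tuple[float, float] = (1.0, 9.0)
    # baseline metric model
    count_rate: float = 12.0           # Poisson rate per (network, side)
    volume_median: float = 60.0        # voxels, lognormal median
    volume_sigma_log: float = 0.5
    diameter_median: float = 1.2       # mm, lognormal median
    diameter_sigma_log: float = 0.15
    wm_volume_mean: float = 4.0e5      # voxels
    wm_volume_sd: float = 4.0e4
    # effects
    effect_sizes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    effect_symptom: str = "language"
    sex_effect: float = 0.8            # SD units, male count/volume elevation
    seed: int = 0

    def validate(self) -> None:
        _check_marginal("sex", self.sex_counts, self.n_subjects)
        _check_marginal("language", self.language_counts, self.n_subjects)
        _check_marginal("sensory", self.sensory_counts, self.n_subjects)
        _check_marginal("stereotypies", self.stereotypies_counts, self.n_subjects)
        _check_marginal("support_level", self.support_counts, self.n_subjects)
        for (net, side, meas) in self.effect_sizes:
            if net not in NETWORKS or side not in SIDES or meas not in MEASURES:
                raise ValueError(
                    f"unknown effect cell ({net}, {side}, {meas})")

    def with_effect(self, network: str, side: str, measure: str,
                    d: float) -> "CohortSpec":
        """Copy of the spec with one additional effect cell."""
        eff = dict(self.effect_sizes)
        eff[(network, side, measure)] = d
        return replace(self, effect_sizes=eff)


# the high (symptomatic) category per symptom, mirroring the splits
_HIGH_CATEGORY = {"language": "absent", "sensory": "yes",
                  "stereotypies": "yes", "support_level": 3}


def _assign_categories(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    df = pd.DataFrame({"subject_id": [f"S{i + 1:03d}" for i in range(n)]})
    df["sex"] = rng.permutation(
        np.concatenate([np.repeat(k, v) for k, v in spec.sex_counts.items()]))
    df["language"] = rng.permutation(np.concatenate(
        [np.repeat(k, v) for k, v in spec.language_counts.items()]))
    df["support_level"] = rng.permutation(np.concatenate(
        [np.repeat(k, v) for k, v in spec.support_counts.items()])).astype(int)
    # unknowns deterministically on the last subjects (enrollment order)
    for col, counts in [("sensory", spec.sensory_counts),
                        ("stereotypies", spec.stereotypies_counts)]:
        n_unknown = counts.get("unknown", 0)
        known = rng.permutation(np.concatenate(
            [np.repeat(k, v) for k, v in counts.items() if k != "unknown"]))
        df[col] = np.concatenate([known, np.repeat("unknown", n_unknown)])
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    df["age_years"] = np.clip(age, *spec.age_range).round(1)
    return df


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort; marginals are reproduced exactly, not in law."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    df = _assign_categories(spec, rng)
    n = spec.n_subjects

    high = (df[spec.effect_symptom] == _HIGH_CATEGORY[spec.effect_symptom]) \
        if spec.effect_symptom in df.columns else pd.Series(False, index=df.index)
    male = df["sex"] == "M"

    for net in NETWORKS:
        for side in SIDES:
            for meas in MEASURES:
                d = spec.effect_sizes.get((net, side, meas), 0.0)
                if meas == "count":
                    lam = np.full(n, spec.count_rate)
                    lam[high.to_numpy()] += d * np.sqrt(spec.count_rate)
                    lam[male.to_numpy()] += spec.sex_effect * np.sqrt(spec.count_rate)
                    vals = rng.poisson(np.maximum(lam, 0.0))
                else:
                    median = (spec.volume_median if meas == "volume"
                              else spec.diameter_median)
                    sig = (spec.volume_sigma_log if meas == "volume"
                           else spec.diameter_sigma_log)
                    logv = rng.normal(np.log(median), sig, size=n)
                    logv[high.to_numpy()] += d * sig
                    if meas == "volume":
                        logv[male.to_numpy()] += spec.sex_effect * sig
                    vals = np.exp(logv)
                    if meas == "volume":
                        vals = np.round(vals).astype(int)
                df[f"{net}_{side}_{meas}"] = vals

    df["wm_volume_voxels"] = np.maximum(
        rng.normal(spec.wm_volume_mean, spec.wm_volume_sd, size=n), 1.0
    ).round().astype(int)
    return df


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in metric_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks metric columns: {missing}")
    return df
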