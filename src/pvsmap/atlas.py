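"""Parcellation registry: 72 analyzed areas and their cognitive-network membership.

The registry encodes, per hemisphere, the 36 white-matter/basal-ganglia areas
in which perivascular spaces (PVSs) are quantified — 8 temporal, 11 frontal,
5 parietal, 4 occipital, 4 cingulate, and 4 basal-ganglia labels, a
Mindboggle/DKT-style frame — plus their membership in three large-scale
cognitive networks: the Default Mode Network (DMN), the merged Central
Executive / Frontoparietal Network (CEN/FPN, which includes the caudate), and
the Salience Network (SN).

Two region sets are exposed:

``strict_72``
    exactly the 72 quantified areas (36 per hemisphere).
``analysis``
    the 72 areas plus two extra labels per hemisphere that carry network
    membership but are not part of the 72-area quantification frame: the
    insula (an SN key region that is not a DKT white-matter area of the
    listing) and the angular gyrus (the DMN's parietal key region; in
    DKT-style parcellations it falls inside the inferior parietal label,
    which here carries CEN/FPN membership only, so a distinct angular label
    keeps DMN and CEN/FPN disjoint).

With the analysis set, per-hemisphere network sizes are DMN = 5,
CEN/FPN = 6, SN = 2.

Label-id scheme (stable, 0 = background): left hemisphere 1-36 in listing
order, insula 37, angular gyrus 38; right hemisphere adds 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

NETWORKS = ("DMN", "CEN_FPN", "SN")
SIDES = ("left", "right")
GROUPS = ("temporal", "frontal", "parietal", "occipital", "cingulate",
          "basal_ganglia", "insula")

RIGHT_OFFSET = 100  # right-hemisphere label_id = left id + 100

# (name, group) per hemisphere, in listing order within group.
_STRICT_AREAS = [
    ("entorhinal", "temporal"),
    ("parahippocampal", "temporal"),
    ("fusiform", "temporal"),
    ("superior_temporal", "temporal"),
    ("middle_temporal", "temporal"),
    ("inferior_temporal", "temporal"),
    ("transverse_temporal", "temporal"),
    ("temporal_pole", "temporal"),
    ("superior_frontal", "frontal"),
    ("rostral_middle_frontal", "frontal"),
    ("caudal_middle_frontal", "frontal"),
    ("pars_opercularis", "frontal"),
    ("pars_triangularis", "frontal"),
    ("pars_orbitalis", "frontal"),
    ("lateral_orbitofrontal", "frontal"),
    ("medial_orbitofrontal", "frontal"),
    ("precentral", "frontal"),
    ("paracentral", "frontal"),
    ("frontal_pole", "frontal"),
    ("postcentral", "parietal"),
    ("supramarginal", "parietal"),
    ("superior_parietal", "parietal"),
    ("inferior_parietal", "parietal"),
    ("precuneus", "parietal"),
    ("lingual", "occipital"),
    ("pericalcarine", "occipital"),
    ("cuneus", "occipital"),
    ("lateral_occipital", "occipital"),
    ("rostral_anterior_cingulate", "cingulate"),
    ("caudal_anterior_cingulate", "cingulate"),
    ("posterior_cingulate", "cingulate"),
    ("isthmus_cingulate", "cingulate"),
    ("thalamus", "basal_ganglia"),
    ("caudate", "basal_ganglia"),
    ("putamen", "basal_ganglia"),
    ("pallidus", "basal_ganglia"),
]

# Analysis-set extras: network key regions outside the strict 72.
_EXTRA_AREAS = [
    ("insula", "insula"),
    ("angular", "parietal"),
]

_NETWORK_MEMBERS = {
    "DMN": {"angular", "medial_orbitofrontal", "middle_temporal",
            "posterior_cingulate", "precuneus"},
    "CEN_FPN": {"caudal_anterior_cingulate", "inferior_parietal",
                "inferior_temporal", "lateral_orbitofrontal", "caudate",
                "rostral_middle_frontal"},
    "SN": {"insula", "rostral_anterior_cingulate"},
}


@dataclass(frozen=True)
class Region:
    """One labeled area in one hemisphere."""

    name: str
    hemisphere: str  # "left" | "right"
    group: str
    label_id: int
    networks: frozenset[str] = field(default_factory=frozenset)
    in_strict_72: bool = True

    def __post_init__(self) -> None:
        if self.hemisphere not in SIDES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.label_id <= 0:
            raise ValueError("label_id must be strictly positive (0 is background)")
        bad = set(self.networks) - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown networks {sorted(bad)}")


class RegionRegistry:
    """Ordered, queryable collection of :class:`Region`.

    Ordering is hemisphere-major (left, right), group-minor, listing order
    within group; analysis-set extras follow the strict areas within each
    hemisphere.
    """

    def __init__(self, regions: Sequence[Region]):
        self.regions: tuple[Region, ...] = tuple(regions)
        ids = [r.label_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate label_id in registry")
        self._by_id = {r.label_id: r for r in self.regions}
        self._by_key = {(r.name, r.hemisphere): r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionRegistry) and self.regions == other.regions

    @property
    def label_ids(self) -> list[int]:
        return [r.label_id for r in self.regions]

    def by_label(self, label_id: int) -> Region:
        try:
            return self._by_id[label_id]
        except KeyError:
            raise KeyError(f"label_id {label_id} not in registry") from None

    def get(self, name: str, hemisphere: str) -> Region:
        try:
            return self._by_key[(name, hemisphere)]
        except KeyError:
            raise KeyError(f"region {name!r}/{hemisphere!r} not in registry") from None

    def __contains__(self, label_id: int) -> bool:
        return label_id in self._by_id

    def strict(self) -> "RegionRegistry":
        """The 72-area quantification view (drops analysis-set extras)."""
        return RegionRegistry([r for r in self.regions if r.in_strict_72])

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "hemisphere", "group", "label_id",
                        "networks", "in_strict_72"])
            for r in self.regions:
                w.writerow([r.name, r.hemisphere, r.group, r.label_id,
                            ";".join(sorted(r.networks)), int(r.in_strict_72)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionRegistry":
        import csv

        regions = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                nets = frozenset(n for n in row["networks"].split(";") if n)
                regions.append(Region(
                    name=row["name"], hemisphere=row["hemisphere"],
                    group=row["group"], label_id=int(row["label_id"]),
                    networks=nets, in_strict_72=bool(int(row["in_strict_72"])),
                ))
        return cls(regions)


def _hemisphere_regions(hemisphere: str) -> list[Region]:
    offset = 0 if hemisphere == "left" else RIGHT_OFFSET
    out = []
    for i, (name, group) in enumerate(_STRICT_AREAS, start=1):
        nets = frozenset(n for n, members in _NETWORK_MEMBERS.items()
                         if name in members)
        out.append(Region(name, hemisphere, group, offset + i, nets, True))
    for j, (name, group) in enumerate(_EXTRA_AREAS, start=len(_STRICT_AREAS) + 1):
        nets = frozenset(n for n, members in _NETWORK_MEMBERS.items()
                         if name in members)
        out.append(Region(name, hemisphere, group, offset + j, nets, False))
    return out


def build_registry(mode: str = "analysis") -> RegionRegistry:
    """Build the full registry.

    Parameters
    ----------
    mode : {"analysis", "strict_72"}
        ``analysis`` (default) includes the insula and angular-gyrus extras
        needed for full network membership; ``strict_72`` restricts to the
        72 quantified areas.
    """
    if mode not in ("analysis", "strict_72"):
        raise ValueError(f"unknown registry mode {mode!r}")
    reg = RegionRegistry(_hemisphere_regions("left") + _hemisphere_regions("right"))
    return reg.strict() if mode == "strict_72" else reg


def regions_in_network(registry: RegionRegistry, network: str,
                       hemisphere: str) -> list[Region]:
    """Member regions of one network in one hemisphere, in registry order."""
    if network not in NETWORKS:
        raise ValueError(f"unknown network {network!r}; expected one of {NETWORKS}")
    if hemisphere not in SIDES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}; expected one of {SIDES}")
    return [r for r in registry
            if r.hemisphere == hemisphere and network in r.networks]


def packaged_registry_csv() -> Path:
    """Path to the registry CSV shipped with the package."""
    return Path(importlib.resources.files("pvsmap") / "data" / "regions.csv")
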