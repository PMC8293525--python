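"""Planning-region geography: neighbourhoods, sub-regions and population strata.

A planning region is a set of neighbourhoods (abstract ids, no coordinates)
partitioned into sub-regions, each neighbourhood carrying a stratified
population count table. Strata are (age band, sex, morbidity level) cells —
a transparent, coarse stand-in for individual-level case-mix grouping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd


class Stratum(NamedTuple):
    """One population cell: age band x sex x morbidity level."""

    age_band: str
    sex: str
    morbidity: str


@dataclass(frozen=True)
class StrataConfig:
    """The finite category sets strata are drawn from.

    Defaults give 9 age bands x 2 sexes x 3 morbidity levels = 54 strata:
    small enough for exhaustive tests, rich enough for heterogeneous needs.
    """

    age_bands: tuple[str, ...] = (
        "0-9", "10-19", "20-29", "30-39", "40-49",
        "50-59", "60-69", "70-79", "80+",
    )
    sexes: tuple[str, ...] = ("F", "M")
    morbidity_levels: tuple[str, ...] = ("low", "moderate", "high")

    def __post_init__(self) -> None:
        for name in ("age_bands", "sexes", "morbidity_levels"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ValueError(f"strata config: {name} must be non-empty")
            if len(set(values)) != len(values):
                raise ValueError(f"strata config: {name} has duplicates")

    def strata(self) -> list[Stratum]:
        """All strata in a fixed, reproducible order."""
        return [
            Stratum(a, s, m)
            for a, s, m in itertools.product(
                self.age_bands, self.sexes, self.morbidity_levels
            )
        ]

    def validate_stratum(self, stratum: Stratum) -> None:
        if (
            stratum.age_band not in self.age_bands
            or stratum.sex not in self.sexes
            or stratum.morbidity not in self.morbidity_levels
        ):
            raise ValueError(f"stratum {stratum} outside configured category sets")


@dataclass
class NeighbourhoodSpec:
    """One neighbourhood: id, display name, sub-region, stratified population."""

    id: str
    name: str
    sub_region: str
    population: dict[Stratum, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stratum, count in self.population.items():
            if count < 0:
                raise ValueError(
                    f"neighbourhood {self.id}: negative count for {stratum}"
                )

    @property
    def total_population(self) -> int:
        return int(sum(self.population.values()))


@dataclass
class Region:
    """A planning region whose sub-regions partition its neighbourhoods."""

    neighbourhoods: list[NeighbourhoodSpec]
    sub_regions: dict[str, set[str]]
    strata_config: StrataConfig = field(default_factory=StrataConfig)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.neighbourhoods]
        if len(set(ids)) != len(ids):
            raise ValueError("neighbourhood ids are not unique")
        id_set = set(ids)
        covered: set[str] = set()
        for sub_id, members in self.sub_regions.items():
            unknown = members - id_set
            if unknown:
                raise ValueError(
                    f"sub-region {sub_id} references unknown neighbourhoods {sorted(unknown)}"
                )
            overlap = covered & members
            if overlap:
                raise ValueError(
                    f"neighbourhoods {sorted(overlap)} appear in more than one sub-region"
                )
            covered |= members
        if covered != id_set:
            missing = id_set - covered
            raise ValueError(
                f"neighbourhoods {sorted(missing)} belong to no sub-region"
            )
        for n in self.neighbourhoods:
            if n.sub_region not in self.sub_regions:
                raise ValueError(f"neighbourhood {n.id}: unknown sub-region {n.sub_region}")
            if n.id not in self.sub_regions[n.sub_region]:
                raise ValueError(
                    f"neighbourhood {n.id} declares sub-region {n.sub_region} "
                    "but is not a member of it"
                )
            for stratum in n.population:
                self.strata_config.validate_stratum(stratum)

    @property
    def ids(self) -> list[str]:
        return [n.id for n in self.neighbourhoods]

    @property
    def n_neighbourhoods(self) -> int:
        return len(self.neighbourhoods)

    def sub_region_of(self, neighbourhood_id: str) -> str:
        for n in self.neighbourhoods:
            if n.id == neighbourhood_id:
                return n.sub_region
        raise KeyError(neighbourhood_id)

    def population_frame(self) -> pd.DataFrame:
        """Counts as a neighbourhood x stratum table (missing cells are 0)."""
        strata = self.strata_config.strata()
        columns = pd.MultiIndex.from_tuples(
            strata, names=["age_band", "sex", "morbidity"]
        )
        data = [
            [n.population.get(stratum, 0) for stratum in strata]
            for n in self.neighbourhoods
        ]
        return pd.DataFrame(data, index=pd.Index(self.ids, name="neighbourhood_id"),
                            columns=columns)

    def membership_frame(self) -> pd.DataFrame:
        """Tidy (neighbourhood_id, name, sub_region) table."""
        return pd.DataFrame(
            {
                "neighbourhood_id": self.ids,
                "name": [n.name for n in self.neighbourhoods],
                "sub_region": [n.sub_region for n in self.neighbourhoods],
            }
        )


def geography_groups(region: Region, level: str) -> dict[str, list[str]]:
    """Map geography id -> member neighbourhood ids at the requested level."""
    if level == "neighbourhood":
        return {i: [i] for i in region.ids}
    if level == "sub_region":
        return {s: sorted(members) for s, members in sorted(region.sub_regions.items())}
    if level == "city":
        return {"city": list(region.ids)}
    raise ValueError(
        f"unknown aggregation level {level!r}; expected neighbourhood, sub_region or city"
    )
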