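"""Resident service needs: stratum rates -> expected annual visits, plus growth.

The needs model is the transparent stand-in for an individual-level population
grouper: each stratum carries an expected number of annual family-physician
visits per person, and neighbourhood needs are the exact linear aggregation
count x rate over strata. The rate table is a pluggable input, so aggregated
output from a real case-mix grouper can be substituted without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .region import Region, Stratum

#: Default annual growth factor above which a neighbourhood is a growth hot-spot.
DEFAULT_HOTSPOT_THRESHOLD = 1.02


@dataclass
class NeedsRateTable:
    """Expected visits/person/year for every configured stratum."""

    rates: dict[Stratum, float]

    def __post_init__(self) -> None:
        for stratum, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"negative needs rate for stratum {stratum}")

    def as_series(self, strata: list[Stratum]) -> pd.Series:
        missing = [s for s in strata if s not in self.rates]
        if missing:
            raise KeyError(
                "needs rate table is missing strata: "
                + ", ".join(map(str, missing[:5]))
                + (" ..." if len(missing) > 5 else "")
            )
        return pd.Series([self.rates[s] for s in strata], index=pd.MultiIndex.from_tuples(strata))


@dataclass
class GrowthProjection:
    """Per-neighbourhood annual growth factor and planning horizon in years."""

    factors: pd.Series  # index: neighbourhood_id, values: g > 0
    horizon: int

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("growth horizon must be >= 0")
        if (self.factors <= 0).any():
            bad = self.factors[self.factors <= 0].index.tolist()
            raise ValueError(f"growth factors must be > 0; offending: {bad[:5]}")


def expected_resident_visits(region: Region, rates: NeedsRateTable) -> pd.Series:
    """V_RES per neighbourhood: sum over strata of count(x, s) * rate(s)."""
    pop = region.population_frame()
    strata = region.strata_config.strata()
    rate_vec = rates.as_series(strata)
    visits = pop.to_numpy(dtype=float) @ rate_vec.to_numpy()
    return pd.Series(visits, index=pop.index, name="v_res")


def apply_growth(
    needs: pd.Series,
    growth: GrowthProjection,
    *,
    mode: str = "visits",
    region: Region | None = None,
    rates: NeedsRateTable | None = None,
) -> pd.Series:
    """Project needs forward: V_RES_x(t) = V_RES_x(0) * g_x^horizon.

    ``mode="visits"`` compounds the visit totals directly. ``mode="population"``
    grows the stratified counts and re-applies the rate table; because each
    neighbourhood's factor is uniform across its strata the two modes agree
    exactly, and the flag exists so stratum-specific growth could be slotted
    in later.
    """
    factors = growth.factors.reindex(needs.index)
    if factors.isna().any():
        missing = factors[factors.isna()].index.tolist()
        raise ValueError(f"growth factors missing for neighbourhoods {missing[:5]}")
    multiplier = factors.to_numpy(dtype=float) ** growth.horizon
    if mode == "visits":
        return (needs * multiplier).rename(needs.name)
    if mode == "population":
        if region is None or rates is None:
            raise ValueError("population growth mode requires region and rates")
        pop = region.population_frame().to_numpy(dtype=float) * multiplier[:, None]
        rate_vec = rates.as_series(region.strata_config.strata()).to_numpy()
        return pd.Series(pop @ rate_vec, index=needs.index, name=needs.name)
    raise ValueError(f"unknown growth mode {mode!r}")


def growth_hotspots(
    growth: GrowthProjection, threshold: float = DEFAULT_HOTSPOT_THRESHOLD
) -> list[str]:
    """Neighbourhoods whose annual growth factor meets the hot-spot threshold."""
    return growth.factors[growth.factors >= threshold].index.tolist()


def aggregate_needs(needs: pd.Series, region: Region, level: str) -> pd.DataFrame:
    """Aggregate per-neighbourhood visits to a geography level (exact sums)."""
    from .region import geography_groups

    groups = geography_groups(region, level)
    rows = [
        {
            "geography_id": gid,
            "level": level,
            "visits_per_year": float(needs.loc[members].sum()),
        }
        for gid, members in groups.items()
    ]
    return pd.DataFrame(rows)
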