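"""Workforce service capacity: stock-flow projection and adjustment chain.

Each profession's capacity starts from the stock of providers (headcounts by
age band and practice neighbourhood), projected forward in discrete annual
steps under inflow, outflow, retirement and death rates. The projected stock
converts to deliverable annual visits through a chain of multiplicative
adjustments — activity rate, in-region participation, in-scope share of
practice, a practice-pattern factor and a subjective productivity lever —
with hour-denominated professions harmonized to visits via a visits-per-hour
conversion. Physician capacity is always denominated in visits/year; other
regulated professions use hours/year (nurse practitioners may use either).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .region import Region, geography_groups

VALID_UNITS = ("visits", "hours")

#: Professions whose capacity unit must be visits/year.
VISIT_ONLY_PROFESSIONS = ("family_physician", "physician")


@dataclass
class WorkforceStock:
    """Provider headcounts by age band and practice neighbourhood."""

    profession: str
    unit: str  # "visits" or "hours"
    base_output: float  # visits/year or hours/year per full-time provider
    cohorts: pd.DataFrame  # columns: neighbourhood_id, age_band, headcount
    age_bands: tuple[str, ...]  # ordered provider age bands

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(
                f"unknown capacity unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if any(tag in self.profession for tag in VISIT_ONLY_PROFESSIONS) and self.unit != "visits":
            raise ValueError(
                f"{self.profession}: physician capacity must be denominated in visits"
            )
        if self.base_output <= 0:
            raise ValueError("base_output must be positive")
        required = {"neighbourhood_id", "age_band", "headcount"}
        if not required <= set(self.cohorts.columns):
            raise ValueError(f"cohort table must have columns {sorted(required)}")
        if (self.cohorts["headcount"] < 0).any():
            raise ValueError("headcounts must be non-negative")
        unknown = set(self.cohorts["age_band"]) - set(self.age_bands)
        if unknown:
            raise ValueError(f"cohort age bands {sorted(unknown)} not in declared order")

    @property
    def total_headcount(self) -> float:
        return float(self.cohorts["headcount"].sum())

    def headcount_by_neighbourhood(self) -> pd.Series:
        return self.cohorts.groupby("neighbourhood_id")["headcount"].sum()


@dataclass
class FlowRates:
    """Annual stock-flow rates for one profession.

    ``inflow_rate`` is new entrants per year as a proportion of the current
    total stock (may exceed 1); the three attrition-type rates are per-head
    proportions in [0, 1], with retirement and death resolved by age band.
    """

    inflow_rate: float = 0.0
    outflow_rate: float = 0.0
    retirement_rate: dict[str, float] = field(default_factory=dict)
    death_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.inflow_rate < 0:
            raise ValueError("inflow rate must be >= 0")
        if not 0.0 <= self.outflow_rate <= 1.0:
            raise ValueError("outflow rate must lie in [0, 1]")
        for name, table in (("retirement", self.retirement_rate), ("death", self.death_rate)):
            for band, r in table.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{name} rate for band {band!r} outside [0, 1]")
        for band in set(self.retirement_rate) | set(self.death_rate):
            if self.retirement_rate.get(band, 0.0) + self.death_rate.get(band, 0.0) > 1.0:
                raise ValueError(f"retirement + death exceed 1 for band {band!r}")


@dataclass(frozen=True)
class CapacityAdjustments:
    """Multiplicative factors converting raw provider output to usable capacity."""

    activity_rate: float = 1.0          # share of licensees actively practising
    participation_rate: float = 1.0     # share of activity delivered inside the region
    scope_share: float = 1.0            # share of activity that is in-scope primary care
    practice_pattern_factor: float = 1.0
    productivity_factor: float = 1.0    # subjective scenario lever

    def __post_init__(self) -> None:
        for name in ("activity_rate", "participation_rate", "scope_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.practice_pattern_factor <= 0 or self.productivity_factor <= 0:
            raise ValueError("pattern and productivity factors must be positive")

    def product(self) -> float:
        return (
            self.activity_rate
            * self.participation_rate
            * self.scope_share
            * self.practice_pattern_factor
            * self.productivity_factor
        )


@dataclass
class CapacityEstimate:
    """Deliverable visits/year per neighbourhood for one profession.

    ``audit`` records every multiplicative factor applied, so the headline
    total is exactly reproducible as total_headcount x base_output x factors.
    """

    profession: str
    capacity: pd.Series  # index neighbourhood_id, visits/year
    audit: dict[str, float]

    def __post_init__(self) -> None:
        if (self.capacity < 0).any():
            raise ValueError("capacity must be non-negative")
        headline = float(self.capacity.sum())
        product = float(np.prod([v for k, v in self.audit.items()]))
        if headline > 0 and abs(product - headline) / headline > 1e-9:
            raise ValueError("audit-trail product does not reproduce capacity total")


def project_stock(
    stock: WorkforceStock,
    rates: FlowRates,
    horizon: int,
    *,
    band_years: int = 10,
    inflow_band: str | None = None,
) -> WorkforceStock:
    """Advance the provider stock ``horizon`` years in discrete annual steps.

    Each year every cohort loses retirement + death + outflow shares, a
    1/band_years fraction of survivors ages into the next band, and inflow
    (inflow_rate x current total stock, allocated across neighbourhoods in
    proportion to their stock) enters the youngest band unless ``inflow_band``
    names another. Headcounts are floored at zero with a warning rather than
    erroring, so aggressive scenario rates remain explorable.
    """
    if horizon < 0:
        raise ValueError("projection horizon must be >= 0")
    bands = list(stock.age_bands)
    if inflow_band is None:
        inflow_band = bands[0]
    if inflow_band not in bands:
        raise ValueError(f"inflow band {inflow_band!r} not a declared age band")

    # Dense neighbourhood x band matrix for the annual update.
    nbhd_ids = sorted(stock.cohorts["neighbourhood_id"].unique())
    H = (
        stock.cohorts.pivot_table(
            index="neighbourhood_id", columns="age_band", values="headcount",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(index=nbhd_ids, columns=bands, fill_value=0.0)
        .to_numpy(dtype=float)
    )
    survival = np.array(
        [
            1.0
            - rates.retirement_rate.get(b, 0.0)
            - rates.death_rate.get(b, 0.0)
            - rates.outflow_rate
            for b in bands
        ]
    )
    if (survival < 0).any():
        warnings.warn(
            f"{stock.profession}: combined annual exit rates exceed 1; flooring at 0",
            stacklevel=2,
        )
        survival = np.clip(survival, 0.0, None)
    j_in = bands.index(inflow_band)
    ageing = 1.0 / band_years if len(bands) > 1 else 0.0
    for _ in range(horizon):
        total_before = H.sum()
        H = H * survival
        if ageing:
            moved = H[:, :-1] * ageing
            H[:, :-1] -= moved
            H[:, 1:] += moved
        inflow_total = rates.inflow_rate * total_before
        if inflow_total > 0:
            weights = H.sum(axis=1)
            w = weights / weights.sum() if weights.sum() > 0 else np.full(len(nbhd_ids), 1.0 / len(nbhd_ids))
            H[:, j_in] += inflow_total * w
    cohorts = pd.DataFrame(
        {
            "neighbourhood_id": np.repeat(nbhd_ids, len(bands)),
            "age_band": np.tile(bands, len(nbhd_ids)),
            "headcount": H.ravel(),
        }
    )
    return replace(stock, cohorts=cohorts)


def capacity_from_stock(
    stock: WorkforceStock,
    adj: CapacityAdjustments,
    visits_per_hour: float | None = None,
) -> CapacityEstimate:
    """Convert a provider stock into deliverable visits/year per neighbourhood."""
    if stock.unit == "hours":
        if visits_per_hour is None or visits_per_hour <= 0:
            raise ValueError(
                f"{stock.profession}: hour-denominated capacity needs a positive "
                "visits_per_hour conversion rate"
            )
        conversion = float(visits_per_hour)
    else:
        conversion = 1.0
    per_provider = stock.base_output * adj.product() * conversion
    capacity = stock.headcount_by_neighbourhood() * per_provider
    audit = {
        "total_headcount": stock.total_headcount,
        "base_output": stock.base_output,
        "activity_rate": adj.activity_rate,
        "participation_rate": adj.participation_rate,
        "scope_share": adj.scope_share,
        "practice_pattern_factor": adj.practice_pattern_factor,
        "productivity_factor": adj.productivity_factor,
        "visits_per_hour": conversion,
    }
    return CapacityEstimate(stock.profession, capacity.rename("capacity"), audit)


def total_capacity(
    estimates: list[CapacityEstimate], region: Region, level: str
) -> pd.DataFrame:
    """Capacity by geography and profession, plus an all-profession total row.

    Output columns: geography_id, level, profession, capacity. The
    profession value "ALL" carries the cross-profession sum per geography.
    """
    groups = geography_groups(region, level)
    rows = []
    for gid, members in groups.items():
        total = 0.0
        for est in estimates:
            value = float(est.capacity.reindex(members).fillna(0.0).sum())
            rows.append(
                {"geography_id": gid, "level": level,
                 "profession": est.profession, "capacity": value}
            )
            total += value
        rows.append(
            {"geography_id": gid, "level": level, "profession": "ALL", "capacity": total}
        )
    return pd.DataFrame(rows)
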