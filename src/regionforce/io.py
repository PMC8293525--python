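"""Delimited-text I/O for synthetic regions and results bundles.

All tables are plain CSV; the manifest recording seed and parameters is YAML.
The on-disk layout of a region directory:

    neighbourhoods.csv   neighbourhood_id, name, sub_region
    population.csv       neighbourhood_id, age_band, sex, morbidity, count
    needs_rates.csv      age_band, sex, morbidity, visits_per_person_per_year
    flows.csv            origin_id, destination_id, proportion
    external_inflow.csv  destination_id, visits_per_year
    growth.csv           neighbourhood_id, growth_factor
    unmet_indicators.csv neighbourhood_id, low_urgency_ed, acsc, survey_share,
                         consultation_adjustment
    workforce.csv        profession, neighbourhood_id, age_band, headcount,
                         base_output, unit
    scope_matrix.csv     service_id, profession, eligible, efficiency
    service_shares.csv   service_id, share
    manifest.yaml        seed + generator parameters
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .allocation import ScopeMatrix
from .capacity import WorkforceStock
from .flows import FlowMatrix
from .needs import GrowthProjection, NeedsRateTable
from .region import NeighbourhoodSpec, Region, StrataConfig, Stratum
from .synthetic import PROVIDER_AGE_BANDS


def _float_format(df: pd.DataFrame) -> pd.DataFrame:
    return df


def write_region_dir(
    path: str | Path,
    region: Region,
    rates: NeedsRateTable,
    flows: FlowMatrix,
    growth: GrowthProjection,
    unmet_inputs: pd.DataFrame,
    stocks: list[WorkforceStock],
    scope: ScopeMatrix,
    manifest: dict,
) -> Path:
    """Write a complete synthetic region as a directory of CSV tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    region.membership_frame().to_csv(path / "neighbourhoods.csv", index=False)

    pop_rows = [
        {
            "neighbourhood_id": nb.id,
            "age_band": s.age_band,
            "sex": s.sex,
            "morbidity": s.morbidity,
            "count": c,
        }
        for nb in region.neighbourhoods
        for s, c in nb.population.items()
    ]
    pd.DataFrame(pop_rows).to_csv(path / "population.csv", index=False)

    rate_rows = [
        {
            "age_band": s.age_band,
            "sex": s.sex,
            "morbidity": s.morbidity,
            "visits_per_person_per_year": r,
        }
        for s, r in rates.rates.items()
    ]
    pd.DataFrame(rate_rows).to_csv(path / "needs_rates.csv", index=False)

    flows.to_frame().to_csv(path / "flows.csv", index=False)
    pd.DataFrame(
        {"destination_id": list(flows.ids), "visits_per_year": flows.external_inflow}
    ).to_csv(path / "external_inflow.csv", index=False)

    growth.factors.rename("growth_factor").rename_axis("neighbourhood_id").reset_index().to_csv(
        path / "growth.csv", index=False
    )
    unmet_inputs.rename_axis("neighbourhood_id").reset_index().to_csv(
        path / "unmet_indicators.csv", index=False
    )

    wf_rows = []
    for stock in stocks:
        for _, row in stock.cohorts.iterrows():
            wf_rows.append(
                {
                    "profession": stock.profession,
                    "neighbourhood_id": row["neighbourhood_id"],
                    "age_band": row["age_band"],
                    "headcount": row["headcount"],
                    "base_output": stock.base_output,
                    "unit": stock.unit,
                }
            )
    pd.DataFrame(wf_rows).to_csv(path / "workforce.csv", index=False)

    scope_rows = [
        {
            "service_id": s,
            "profession": p,
            "eligible": bool(scope.eligibility.loc[s, p]),
            "efficiency": float(scope.efficiency.loc[s, p]),
        }
        for s in scope.services
        for p in scope.professions
    ]
    pd.DataFrame(scope_rows).to_csv(path / "scope_matrix.csv", index=False)
    scope.shares.rename("share").rename_axis("service_id").reset_index().to_csv(
        path / "service_shares.csv", index=False
    )

    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_region_dir(path: str | Path) -> dict:
    """Load a region directory back into domain objects.

    Returns a dict with keys region, rates, flows, growth, unmet_inputs,
    stocks, scope, manifest.
    """
    path = Path(path)
    members = pd.read_csv(path / "neighbourhoods.csv", dtype={"neighbourhood_id": str})
    pop = pd.read_csv(path / "population.csv", dtype={"neighbourhood_id": str})

    age_bands = tuple(dict.fromkeys(pop["age_band"]))
    sexes = tuple(dict.fromkeys(pop["sex"]))
    morbidity = tuple(dict.fromkeys(pop["morbidity"]))
    strata_config = StrataConfig(age_bands, sexes, morbidity)

    pop_by_nbhd: dict[str, dict[Stratum, int]] = {}
    for row in pop.itertuples(index=False):
        stratum = Stratum(row.age_band, row.sex, row.morbidity)
        pop_by_nbhd.setdefault(row.neighbourhood_id, {})[stratum] = int(row.count)

    neighbourhoods = [
        NeighbourhoodSpec(
            id=row.neighbourhood_id,
            name=row.name,
            sub_region=row.sub_region,
            population=pop_by_nbhd.get(row.neighbourhood_id, {}),
        )
        for row in members.itertuples(index=False)
    ]
    sub_regions: dict[str, set[str]] = {}
    for row in members.itertuples(index=False):
        sub_regions.setdefault(row.sub_region, set()).add(row.neighbourhood_id)
    region = Region(neighbourhoods, sub_regions, strata_config)

    rate_df = pd.read_csv(path / "needs_rates.csv")
    rates = NeedsRateTable(
        {
            Stratum(r.age_band, r.sex, r.morbidity): float(r.visits_per_person_per_year)
            for r in rate_df.itertuples(index=False)
        }
    )

    flow_df = pd.read_csv(path / "flows.csv", dtype={"origin_id": str, "destination_id": str})
    P = (
        flow_df.pivot(index="origin_id", columns="destination_id", values="proportion")
        .reindex(index=region.ids, columns=region.ids)
        .fillna(0.0)
        .to_numpy()
    )
    ext = (
        pd.read_csv(path / "external_inflow.csv", dtype={"destination_id": str})
        .set_index("destination_id")["visits_per_year"]
        .reindex(region.ids)
        .fillna(0.0)
        .to_numpy()
    )
    flows = FlowMatrix(tuple(region.ids), P, ext)

    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh) or {}

    growth_df = pd.read_csv(path / "growth.csv", dtype={"neighbourhood_id": str})
    growth = GrowthProjection(
        growth_df.set_index("neighbourhood_id")["growth_factor"].reindex(region.ids),
        horizon=int(manifest.get("growth_horizon", 0)),
    )

    unmet_inputs = pd.read_csv(
        path / "unmet_indicators.csv", dtype={"neighbourhood_id": str}
    ).set_index("neighbourhood_id").reindex(region.ids)

    wf = pd.read_csv(path / "workforce.csv", dtype={"neighbourhood_id": str})
    stocks = []
    for prof, group in wf.groupby("profession", sort=True):
        bands = tuple(
            b for b in PROVIDER_AGE_BANDS if b in set(group["age_band"])
        ) or tuple(dict.fromkeys(group["age_band"]))
        stocks.append(
            WorkforceStock(
                profession=str(prof),
                unit=str(group["unit"].iloc[0]),
                base_output=float(group["base_output"].iloc[0]),
                cohorts=group[["neighbourhood_id", "age_band", "headcount"]].reset_index(drop=True),
                age_bands=bands,
            )
        )

    scope_df = pd.read_csv(path / "scope_matrix.csv")
    shares = pd.read_csv(path / "service_shares.csv").set_index("service_id")["share"]
    eligibility = scope_df.pivot(index="service_id", columns="profession", values="eligible")
    efficiency = scope_df.pivot(index="service_id", columns="profession", values="efficiency")
    scope = ScopeMatrix(
        shares=shares.reindex(eligibility.index),
        eligibility=eligibility.astype(bool),
        efficiency=efficiency.astype(float),
    )

    return {
        "region": region,
        "rates": rates,
        "flows": flows,
        "growth": growth,
        "unmet_inputs": unmet_inputs,
        "stocks": stocks,
        "scope": scope,
        "manifest": manifest,
    }
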