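"""Synthetic planning regions: internally consistent fixtures for every stage.

Real inputs to a regional workforce model (census strata, case-mix grouper
output, provider registries, utilization extracts) are access-controlled, so
this module fabricates a complete, self-consistent planning region instead:
stratified neighbourhood populations, a needs-rate table, an origin-
destination flow matrix with external inflow, unmet-need indicators, growth
factors, and per-profession workforce stocks.

Defaults mirror the scale of a large Canadian city: 140 neighbourhoods in 5
sub-regions, neighbourhood populations log-normal around 19,000 (≈2.7 M
residents citywide). One top-level integer seed fans out into fixed,
per-component substreams, so adding a new generator never perturbs the
output of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capacity import VALID_UNITS, WorkforceStock
from .flows import FlowMatrix
from .needs import GrowthProjection, NeedsRateTable
from .region import NeighbourhoodSpec, Region, StrataConfig, Stratum

# Fixed substream keys: never renumber, only append.
_SUBSTREAMS = {
    "region": 0,
    "needs_rates": 1,
    "flows": 2,
    "growth": 3,
    "unmet": 4,
    "workforce": 5,
}

#: Ordered provider age bands used by workforce stocks.
PROVIDER_AGE_BANDS = ("<35", "35-44", "45-54", "55-64", "65+")

# Age profile of a large-city population (shares over the 9 default bands)
# and how morbidity concentrates with age; stylized, not calibrated.
_AGE_SHARES = np.array([0.10, 0.10, 0.16, 0.17, 0.14, 0.13, 0.10, 0.06, 0.04])
_MORBIDITY_BY_AGE = {
    # (low, moderate, high) shares by age-band index
    0: (0.85, 0.12, 0.03), 1: (0.85, 0.12, 0.03), 2: (0.78, 0.17, 0.05),
    3: (0.72, 0.21, 0.07), 4: (0.65, 0.25, 0.10), 5: (0.55, 0.30, 0.15),
    6: (0.45, 0.35, 0.20), 7: (0.35, 0.38, 0.27), 8: (0.25, 0.40, 0.35),
}
# Expected annual family-physician visits per person by age band, before
# morbidity and sex multipliers; U-shaped over age.
_AGE_VISIT_RATES = np.array([3.0, 1.8, 2.0, 2.2, 2.4, 2.8, 3.4, 4.5, 6.0])
_MORBIDITY_MULT = {"low": 0.6, "moderate": 1.2, "high": 2.6}
_SEX_MULT = {"F": 1.08, "M": 0.92}

#: Nominal visits/person/year used to size the external-inflow vector.
NOMINAL_VISIT_RATE = 3.0


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[component],))
    )


@dataclass(frozen=True)
class ProfessionSpec:
    """Configuration for one profession's synthetic workforce."""

    name: str
    unit: str  # "visits" or "hours"
    base_output: float  # visits/yr or hours/yr per full-time provider
    density_per_1000: float  # providers per 1,000 residents
    # Age distribution of the current stock over PROVIDER_AGE_BANDS.
    age_shares: tuple[float, ...] = (0.18, 0.27, 0.25, 0.20, 0.10)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(
                f"profession {self.name!r}: unknown unit {self.unit!r}; "
                f"expected one of {VALID_UNITS}"
            )
        if abs(sum(self.age_shares) - 1.0) > 1e-9:
            raise ValueError(f"profession {self.name!r}: age shares must sum to 1")
        if self.base_output <= 0 or self.density_per_1000 < 0:
            raise ValueError(f"profession {self.name!r}: invalid output or density")


DEFAULT_PROFESSIONS = (
    ProfessionSpec("family_physician", "visits", 4200.0, 0.75),
    ProfessionSpec("nurse_practitioner", "visits", 3000.0, 0.15),
    ProfessionSpec("registered_nurse", "hours", 1600.0, 0.50),
)


def generate_region(
    n_neighbourhoods: int = 140,
    n_subregions: int = 5,
    strata_config: StrataConfig | None = None,
    seed: int = 0,
    mean_population: float = 19_000.0,
    population_sigma: float = 0.35,
) -> Region:
    """Generate a region whose sub-regions partition its neighbourhoods.

    Neighbourhood totals are log-normal around ``mean_population``; each
    total is split across strata by a multinomial over a stylized age x sex x
    morbidity profile. Deterministic for a given seed.
    """
    if n_neighbourhoods < 1:
        raise ValueError("n_neighbourhoods must be >= 1")
    if not 1 <= n_subregions <= n_neighbourhoods:
        raise ValueError("need 1 <= n_subregions <= n_neighbourhoods")
    strata_config = strata_config or StrataConfig()
    if len(strata_config.age_bands) != len(_AGE_SHARES):
        age_w = np.full(len(strata_config.age_bands), 1.0 / len(strata_config.age_bands))
    else:
        age_w = _AGE_SHARES
    rng = _rng(seed, "region")

    strata = strata_config.strata()
    n_morb = len(strata_config.morbidity_levels)
    weights = []
    for s in strata:
        ai = strata_config.age_bands.index(s.age_band)
        morb_shares = _MORBIDITY_BY_AGE.get(ai)
        if morb_shares is None or len(morb_shares) != n_morb:
            morb_shares = tuple(1.0 / n_morb for _ in range(n_morb))
        mi = strata_config.morbidity_levels.index(s.morbidity)
        weights.append(age_w[ai] / len(strata_config.sexes) * morb_shares[mi])
    weights = np.asarray(weights)
    weights = weights / weights.sum()

    mu = np.log(mean_population) - population_sigma**2 / 2.0
    totals = np.maximum(rng.lognormal(mu, population_sigma, n_neighbourhoods), 1.0)

    width = len(str(n_neighbourhoods))
    neighbourhoods = []
    sub_regions: dict[str, set[str]] = {
        f"S{k + 1}": set() for k in range(n_subregions)
    }
    for i in range(n_neighbourhoods):
        counts = rng.multinomial(int(round(totals[i])), weights)
        nid = f"N{i + 1:0{width}d}"
        sub = f"S{i * n_subregions // n_neighbourhoods + 1}"
        sub_regions[sub].add(nid)
        neighbourhoods.append(
            NeighbourhoodSpec(
                id=nid,
                name=f"Neighbourhood {i + 1}",
                sub_region=sub,
                population={s: int(c) for s, c in zip(strata, counts)},
            )
        )
    return Region(neighbourhoods, sub_regions, strata_config)


def generate_needs_rates(
    strata_config: StrataConfig | None = None,
    seed: int = 0,
    jitter: float = 0.05,
) -> NeedsRateTable:
    """Expected visits/person/year per stratum: U-shaped in age, scaled by
    morbidity and sex, with mild log-normal jitter (sd ``jitter``)."""
    strata_config = strata_config or StrataConfig()
    rng = _rng(seed, "needs_rates")
    n_age = len(strata_config.age_bands)
    if n_age == len(_AGE_VISIT_RATES):
        age_rates = _AGE_VISIT_RATES
    else:
        age_rates = np.full(n_age, float(np.mean(_AGE_VISIT_RATES)))
    rates: dict[Stratum, float] = {}
    for s in strata_config.strata():
        ai = strata_config.age_bands.index(s.age_band)
        base = (
            age_rates[ai]
            * _MORBIDITY_MULT.get(s.morbidity, 1.0)
            * _SEX_MULT.get(s.sex, 1.0)
        )
        rates[s] = float(base * rng.lognormal(0.0, jitter))
    return NeedsRateTable(rates)


def generate_flow_matrix(
    region: Region,
    locality: float = 0.6,
    external_share: float = 0.05,
    seed: int = 0,
) -> FlowMatrix:
    """OD flow matrix with diagonal mass ``locality``.

    Each row keeps exactly ``locality`` of its visits at home; the remaining
    mass is split among the other neighbourhoods by Dirichlet weights.
    External inflow totals ``external_share`` of the region's nominal resident
    visit volume (population x 3 visits/yr), spread across destinations in
    proportion to population with log-normal jitter. locality=1 gives the
    identity matrix; external_share=0 gives zero inflow.
    """
    if not 0.0 <= locality <= 1.0:
        raise ValueError("locality must lie in [0, 1]")
    if not 0.0 <= external_share < 1.0:
        raise ValueError("external_share must lie in [0, 1)")
    rng = _rng(seed, "flows")
    n = region.n_neighbourhoods
    P = np.zeros((n, n))
    for i in range(n):
        if n == 1 or locality == 1.0:
            P[i, i] = 1.0
            continue
        off = rng.dirichlet(np.ones(n - 1)) * (1.0 - locality)
        row = np.insert(off, i, locality)
        P[i] = row
    pop = np.array([nb.total_population for nb in region.neighbourhoods], dtype=float)
    if external_share > 0:
        total_external = external_share * pop.sum() * NOMINAL_VISIT_RATE
        raw = np.maximum(pop, 1.0) * rng.lognormal(0.0, 0.3, n)
        external = total_external * raw / raw.sum()
    else:
        external = np.zeros(n)
    return FlowMatrix(tuple(region.ids), P, external)


def generate_growth(
    region: Region,
    seed: int = 0,
    mean_factor: float = 1.01,
    sd: float = 0.008,
    horizon: int = 5,
) -> GrowthProjection:
    """Per-neighbourhood annual growth factors, log-normal around the mean."""
    rng = _rng(seed, "growth")
    factors = rng.lognormal(np.log(mean_factor), sd, region.n_neighbourhoods)
    return GrowthProjection(
        pd.Series(factors, index=region.ids, name="growth_factor"), horizon
    )


def generate_unmet_inputs(region: Region, seed: int = 0) -> pd.DataFrame:
    """Unmet-need proxy indicators per neighbourhood.

    Low-urgency ED visits ~ Poisson(0.03/person/yr), ACSC hospitalizations
    ~ Poisson(0.004/person/yr), survey unmet share ~ Beta(2, 38) (mean 5%),
    consultation adjustment 1 everywhere (an elicitation lever, not data).
    """
    rng = _rng(seed, "unmet")
    pop = np.array([nb.total_population for nb in region.neighbourhoods], dtype=float)
    return pd.DataFrame(
        {
            "low_urgency_ed": rng.poisson(0.03 * pop).astype(float),
            "acsc": rng.poisson(0.004 * pop).astype(float),
            "survey_share": rng.beta(2.0, 38.0, region.n_neighbourhoods),
            "consultation_adjustment": np.ones(region.n_neighbourhoods),
        },
        index=pd.Index(region.ids, name="neighbourhood_id"),
    )


def generate_workforce(
    region: Region,
    professions: tuple[ProfessionSpec, ...] | list[ProfessionSpec] = DEFAULT_PROFESSIONS,
    seed: int = 0,
) -> list[WorkforceStock]:
    """Per-profession stocks: headcounts ~ Poisson(density x population) per
    neighbourhood, spread over provider age bands by the profession's profile."""
    if not professions:
        raise ValueError("professions must be non-empty")
    rng = _rng(seed, "workforce")
    pop = np.array([nb.total_population for nb in region.neighbourhoods], dtype=float)
    stocks = []
    for spec in professions:
        expected = spec.density_per_1000 * pop / 1000.0
        rows = []
        for i, nid in enumerate(region.ids):
            head = rng.poisson(expected[i])
            counts = rng.multinomial(head, np.asarray(spec.age_shares))
            for band, c in zip(PROVIDER_AGE_BANDS, counts):
                rows.append(
                    {"neighbourhood_id": nid, "age_band": band, "headcount": float(c)}
                )
        stocks.append(
            WorkforceStock(
                profession=spec.name,
                unit=spec.unit,
                base_output=spec.base_output,
                cohorts=pd.DataFrame(rows),
                age_bands=PROVIDER_AGE_BANDS,
            )
        )
    return stocks


# --- Scope / plasticity defaults -------------------------------------------

#: Default service categories and their shares of total requirements.
DEFAULT_SERVICE_SHARES = {
    "routine_acute": 0.35,
    "chronic_disease": 0.30,
    "preventive": 0.20,
    "mental_health": 0.15,
}

# Which default professions may deliver which service category.
_DEFAULT_ELIGIBILITY = {
    "family_physician": ("routine_acute", "chronic_disease", "preventive", "mental_health"),
    "nurse_practitioner": ("routine_acute", "chronic_disease", "preventive", "mental_health"),
    "registered_nurse": ("chronic_disease", "preventive"),
}


def generate_scope_matrix(
    profession_names: list[str],
    service_shares: dict[str, float] | None = None,
    eligibility: dict[str, list[str]] | None = None,
):
    """Build the scope (plasticity) matrix for the given professions.

    ``eligibility`` maps service id -> eligible professions; defaults come
    from the built-in profiles, and professions without a profile are
    assumed eligible for every service (permissive for custom professions).
    Deterministic — no randomness is involved.
    """
    from .allocation import ScopeMatrix

    shares = pd.Series(service_shares or DEFAULT_SERVICE_SHARES, dtype=float)
    shares = shares / shares.sum()
    services = list(shares.index)
    elig = pd.DataFrame(False, index=services, columns=profession_names)
    for p in profession_names:
        if eligibility is not None:
            allowed = {s for s, profs in eligibility.items() if p in profs}
        elif p in _DEFAULT_ELIGIBILITY:
            allowed = set(_DEFAULT_ELIGIBILITY[p]) & set(services)
        else:
            allowed = set(services)
        for s in allowed:
            elig.loc[s, p] = True
    return ScopeMatrix(shares=shares, eligibility=elig)
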