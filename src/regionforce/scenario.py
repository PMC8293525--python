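"""Scenario engine: declarative overrides, end-to-end runs, comparisons.

A scenario is a named set of (decision point, parameter path, value)
overrides applied to the run configuration before anything is computed.
Decision points correspond to the stages where the model admits intervention:
population profile, growth, flows, unmet need, workforce profile, capacity
adjustments, productivity, model of care / scope, and virtual care. Overrides
are data, never code, and the baseline and scenario share one seed, so a
comparison isolates exactly the override's effect.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allocation import (
    GapReport,
    allocate_services,
    assess_alignment,
    final_alignment,
)
from .capacity import CapacityAdjustments, FlowRates, capacity_from_stock, project_stock, total_capacity
from .flows import shift_care_closer_to_home
from .needs import GrowthProjection, apply_growth, expected_resident_visits, growth_hotspots
from .requirements import compute_requirements, requirements_at_level
from .synthetic import (
    DEFAULT_PROFESSIONS,
    ProfessionSpec,
    generate_flow_matrix,
    generate_growth,
    generate_needs_rates,
    generate_region,
    generate_scope_matrix,
    generate_unmet_inputs,
    generate_workforce,
)
from .unmet import UnmetNeedWeights, compute_umn

LEVELS = ("neighbourhood", "sub_region", "city")


def _default_profession_cfg() -> dict:
    out = {}
    for spec in DEFAULT_PROFESSIONS:
        out[spec.name] = {
            "unit": spec.unit,
            "base_output": spec.base_output,
            "density_per_1000": spec.density_per_1000,
            "rates": {
                "inflow_rate": 0.03,
                "outflow_rate": 0.01,
                "retirement_rate": {"55-64": 0.05, "65+": 0.15},
                "death_rate": {"55-64": 0.004, "65+": 0.02},
            },
            "adjustments": {
                "activity_rate": 0.92,
                "participation_rate": 0.95,
                "scope_share": 0.90 if spec.unit == "visits" else 0.35,
                "practice_pattern_factor": 1.0,
                "productivity_factor": 1.0,
            },
        }
    return out


def default_config() -> dict:
    """The baseline run configuration (a fresh copy)."""
    return copy.deepcopy(
        {
            "seed": 0,
            "region": {
                "n_neighbourhoods": 140,
                "n_subregions": 5,
                "mean_population": 19_000.0,
                "population_sigma": 0.35,
            },
            "needs": {"rate_jitter": 0.05},
            "flows": {
                "locality": 0.6,
                "external_share": 0.05,
                "closer_to_home_delta": 0.0,
            },
            "growth": {
                "horizon": 5,
                "mean_factor": 1.01,
                "sd": 0.008,
                "hotspot_threshold": 1.02,
                "mode": "visits",
            },
            "unmet_need": {
                "weights": {"ed": 1.0, "acsc": 5.0, "survey": 1.0},
            },
            "workforce": {
                "horizon": 5,
                "visits_per_hour": 3.0,
                "productivity_factor": 1.0,
                "professions": _default_profession_cfg(),
            },
            "allocation": {
                "level": "sub_region",
                "virtual_share": 0.0,
                "virtual_efficiency": 1.0,
                "service_shares": None,
                "eligibility": None,
            },
        }
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: dict | None) -> dict:
    """Merge over defaults and check every value before any computation."""
    cfg = _deep_merge(default_config(), config or {})
    errors: list[str] = []
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    r = cfg["region"]
    if not (isinstance(r["n_neighbourhoods"], int) and r["n_neighbourhoods"] >= 1):
        errors.append("region.n_neighbourhoods must be a positive integer")
    if not (isinstance(r["n_subregions"], int) and 1 <= r["n_subregions"] <= r["n_neighbourhoods"]):
        errors.append("region.n_subregions must satisfy 1 <= n_subregions <= n_neighbourhoods")
    if r["mean_population"] <= 0:
        errors.append("region.mean_population must be positive")
    f = cfg["flows"]
    if not 0.0 <= f["locality"] <= 1.0:
        errors.append("flows.locality must lie in [0, 1]")
    if not 0.0 <= f["external_share"] < 1.0:
        errors.append("flows.external_share must lie in [0, 1)")
    if not 0.0 <= f["closer_to_home_delta"] <= 1.0:
        errors.append("flows.closer_to_home_delta must lie in [0, 1]")
    g = cfg["growth"]
    if not (isinstance(g["horizon"], int) and g["horizon"] >= 0):
        errors.append("growth.horizon must be a non-negative integer")
    if g["mean_factor"] <= 0:
        errors.append("growth.mean_factor must be positive")
    if g["mode"] not in ("visits", "population"):
        errors.append("growth.mode must be 'visits' or 'population'")
    for name, w in cfg["unmet_need"]["weights"].items():
        if name not in ("ed", "acsc", "survey"):
            errors.append(f"unmet_need.weights.{name} is not a recognized weight")
        elif w < 0:
            errors.append(f"unmet_need.weights.{name} must be >= 0")
    wf = cfg["workforce"]
    if not (isinstance(wf["horizon"], int) and wf["horizon"] >= 0):
        errors.append("workforce.horizon must be a non-negative integer")
    if wf["visits_per_hour"] <= 0:
        errors.append("workforce.visits_per_hour must be positive")
    if wf["productivity_factor"] <= 0:
        errors.append("workforce.productivity_factor must be positive")
    if not wf["professions"]:
        errors.append("workforce.professions must be non-empty")
    a = cfg["allocation"]
    if a["level"] not in LEVELS:
        errors.append(f"allocation.level must be one of {LEVELS}")
    if not 0.0 <= a["virtual_share"] <= 1.0:
        errors.append("allocation.virtual_share must lie in [0, 1]")
    if a["virtual_efficiency"] <= 0:
        errors.append("allocation.virtual_efficiency must be positive")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# --- Scenarios --------------------------------------------------------------

#: Decision point -> config path prefixes it may override.
DECISION_POINTS: dict[str, tuple[str, ...]] = {
    "population_profile": ("region.", "needs."),
    "growth": ("growth.",),
    "flows": ("flows.",),
    "unmet_need": ("unmet_need.",),
    "workforce_profile": ("workforce.professions.", "workforce.horizon"),
    "adjustments": ("workforce.professions.", "workforce.visits_per_hour"),
    "productivity": ("workforce.productivity_factor", "workforce.professions."),
    "model_of_care/scope": (
        "allocation.level",
        "allocation.service_shares",
        "allocation.eligibility",
    ),
    "virtual_care": ("allocation.virtual_share", "allocation.virtual_efficiency"),
}


@dataclass(frozen=True)
class Override:
    decision_point: str
    path: str  # dotted config path, e.g. "growth.mean_factor"
    value: object

    def __post_init__(self) -> None:
        if self.decision_point not in DECISION_POINTS:
            raise ValueError(
                f"unknown decision point {self.decision_point!r}; "
                f"expected one of {sorted(DECISION_POINTS)}"
            )
        prefixes = DECISION_POINTS[self.decision_point]
        if not any(self.path == p or self.path.startswith(p) for p in prefixes):
            raise ValueError(
                f"path {self.path!r} is not a parameter of decision point "
                f"{self.decision_point!r} (allowed prefixes: {prefixes})"
            )


@dataclass
class Scenario:
    """A named, declarative set of parameter overrides."""

    name: str = "baseline"
    overrides: list[Override] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        overrides = [
            Override(o["decision_point"], o["path"], o["value"])
            for o in raw.get("overrides", [])
        ]
        return cls(name=raw.get("name", Path(path).stem), overrides=overrides)

    @property
    def empty(self) -> bool:
        return not self.overrides


def _set_path(cfg: dict, path: str, value: object) -> None:
    keys = path.split(".")
    node = cfg
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"override path {path!r} does not exist in the configuration")
        node = node[key]
    leaf = keys[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(f"override path {path!r} does not exist in the configuration")
    node[leaf] = value


def apply_scenario(cfg: dict, scenario: Scenario | None) -> dict:
    cfg = copy.deepcopy(cfg)
    if scenario is not None:
        for override in scenario.overrides:
            _set_path(cfg, override.path, override.value)
    return cfg


# --- Pipeline ---------------------------------------------------------------


@dataclass
class Bundle:
    """All outputs of one end-to-end run, plus the manifest describing it."""

    config: dict
    manifest: dict
    requirements: pd.DataFrame          # per-neighbourhood V_TOT decomposition
    requirements_level: pd.DataFrame    # at the allocation level
    capacity: pd.DataFrame              # geography x profession capacity table
    gap_pre: GapReport
    gap_post: GapReport
    summary: pd.DataFrame               # shortfall/surplus classification
    hotspots: list[str]

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "requirements": self.requirements,
            "requirements_level": self.requirements_level,
            "capacity": self.capacity,
            "gap_pre": self.gap_pre.table,
            "gap_post": self.gap_post.table,
            "allocation": self.gap_post.plan,
            "summary": self.summary,
        }

    def equals(self, other: "Bundle") -> bool:
        """Bit-for-bit equality of every output frame."""
        for name, frame in self.frames().items():
            other_frame = other.frames()[name]
            if frame is None or other_frame is None:
                if frame is not other_frame:
                    return False
                continue
            if not frame.equals(other_frame):
                return False
        return True

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in self.frames().items():
            if frame is not None:
                frame.to_csv(path / f"{name}.csv", index=False)
        with open(path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        return path


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict | None = None, scenario: Scenario | None = None) -> Bundle:
    """Run the whole model: requirements, capacity, gap, allocation.

    Deterministic given (config, scenario): all randomness flows from the
    single configured seed through fixed per-component substreams, so a
    baseline and a scenario run differ only through the overridden
    parameters.
    """
    cfg = apply_scenario(validate_config(config), scenario)
    validate_config(cfg)  # overrides must not break the schema either
    seed = cfg["seed"]

    # Step 1 feeders: population profile, growth, flows, unmet need.
    region = generate_region(
        n_neighbourhoods=cfg["region"]["n_neighbourhoods"],
        n_subregions=cfg["region"]["n_subregions"],
        seed=seed,
        mean_population=cfg["region"]["mean_population"],
        population_sigma=cfg["region"]["population_sigma"],
    )
    rates = generate_needs_rates(
        region.strata_config, seed=seed, jitter=cfg["needs"]["rate_jitter"]
    )
    needs_now = expected_resident_visits(region, rates)
    growth = generate_growth(
        region,
        seed=seed,
        mean_factor=cfg["growth"]["mean_factor"],
        sd=cfg["growth"]["sd"],
        horizon=cfg["growth"]["horizon"],
    )
    needs = apply_growth(
        needs_now, growth, mode=cfg["growth"]["mode"], region=region, rates=rates
    )
    flows = generate_flow_matrix(
        region,
        locality=cfg["flows"]["locality"],
        external_share=cfg["flows"]["external_share"],
        seed=seed,
    )
    if cfg["flows"]["closer_to_home_delta"] > 0:
        flows = shift_care_closer_to_home(flows, cfg["flows"]["closer_to_home_delta"])
    unmet_inputs = generate_unmet_inputs(region, seed=seed)
    weights = UnmetNeedWeights(**cfg["unmet_need"]["weights"])
    umn = compute_umn(unmet_inputs, needs, weights)

    # Step 1: service requirements.
    req = compute_requirements(needs, flows, umn)
    level = cfg["allocation"]["level"]
    req_level = requirements_at_level(req, region, level)

    # Step 2: workforce capacity.
    specs = [
        ProfessionSpec(
            name=name,
            unit=p["unit"],
            base_output=p["base_output"],
            density_per_1000=p["density_per_1000"],
        )
        for name, p in cfg["workforce"]["professions"].items()
    ]
    stocks = generate_workforce(region, specs, seed=seed)
    estimates = []
    for stock in stocks:
        pcfg = cfg["workforce"]["professions"][stock.profession]
        projected = project_stock(
            stock, FlowRates(**pcfg["rates"]), cfg["workforce"]["horizon"]
        )
        adj_kwargs = dict(pcfg["adjustments"])
        adj_kwargs["productivity_factor"] = (
            adj_kwargs.get("productivity_factor", 1.0)
            * cfg["workforce"]["productivity_factor"]
        )
        estimates.append(
            capacity_from_stock(
                projected,
                CapacityAdjustments(**adj_kwargs),
                visits_per_hour=cfg["workforce"]["visits_per_hour"],
            )
        )
    cap_table = total_capacity(estimates, region, level)

    # Steps 3-5: alignment, allocation, final gap.
    gap_pre = assess_alignment(req_level, cap_table, level)
    scope = generate_scope_matrix(
        [s.name for s in specs],
        service_shares=cfg["allocation"]["service_shares"],
        eligibility=cfg["allocation"]["eligibility"],
    )
    gap_post = allocate_services(
        req_level,
        cap_table,
        scope,
        level,
        virtual_share=cfg["allocation"]["virtual_share"],
        virtual_efficiency=cfg["allocation"]["virtual_efficiency"],
    )
    summary = final_alignment(gap_post)

    manifest = {
        "seed": seed,
        "config_sha256": config_hash(cfg),
        "version": __version__,
        "scenario": scenario.name if scenario is not None else "baseline",
        "n_neighbourhoods": region.n_neighbourhoods,
        "level": level,
    }
    return Bundle(
        config=cfg,
        manifest=manifest,
        requirements=req.table.rename_axis("neighbourhood_id").reset_index(),
        requirements_level=req_level,
        capacity=cap_table,
        gap_pre=gap_pre,
        gap_post=gap_post,
        summary=summary,
        hotspots=growth_hotspots(growth, cfg["growth"]["hotspot_threshold"]),
    )


def compare(baseline: Bundle, scenario: Bundle) -> pd.DataFrame:
    """Per-geography, per-metric differences between two runs.

    Metrics: v_tot (neighbourhood level), capacity (all-profession, run
    level), gap (pre-allocation) and post_allocation_gap. Columns: metric,
    geography_id, baseline, scenario, abs_diff, rel_diff.
    """
    rows = []

    def add(metric: str, base: pd.Series, scen: pd.Series) -> None:
        scen = scen.reindex(base.index)
        for gid in base.index:
            b, s = float(base.loc[gid]), float(scen.loc[gid])
            rows.append(
                {
                    "metric": metric,
                    "geography_id": gid,
                    "baseline": b,
                    "scenario": s,
                    "abs_diff": s - b,
                    "rel_diff": (s - b) / b if b != 0 else float("nan"),
                }
            )

    add(
        "v_tot",
        baseline.requirements.set_index("neighbourhood_id")["v_tot"],
        scenario.requirements.set_index("neighbourhood_id")["v_tot"],
    )
    base_cap = baseline.capacity.query("profession == 'ALL'").set_index("geography_id")["capacity"]
    scen_cap = scenario.capacity.query("profession == 'ALL'").set_index("geography_id")["capacity"]
    add("capacity", base_cap, scen_cap)
    add(
        "gap",
        baseline.gap_pre.table.set_index("geography_id")["gap"],
        scenario.gap_pre.table.set_index("geography_id")["gap"],
    )
    add(
        "post_allocation_gap",
        baseline.gap_post.table.set_index("geography_id")["post_allocation_gap"],
        scenario.gap_post.table.set_index("geography_id")["post_allocation_gap"],
    )
    return pd.DataFrame(rows)
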