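"""Gap assessment and task-shifting allocation across overlapping scopes.

The gap is requirement minus capacity (positive = shortfall, negative =
surplus) throughout. Allocation formalizes task shifting as a linear program
per geography: service requirements split into service categories, each
deliverable only by professions whose regulated scope covers it; the LP
minimizes total unmet service visits subject to eligibility and capacity,
with an efficiency matrix expressing how much capacity one delivered visit
consumes. Shifting visits between in-person and virtual delivery is modelled
as a capacity-consumption rescaling of the requirement.

Among equally optimal plans, ties break lexicographically in favour of
professions earlier in the scope matrix's column order (a second LP phase),
so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog


@dataclass
class ScopeMatrix:
    """Service categories, their requirement shares, and who may deliver them.

    ``shares`` maps service id -> share of total requirements (sums to 1;
    applied uniformly across geographies unless a per-geography frame is
    supplied via ``shares_by_geography``). ``eligibility`` is a service x
    profession boolean frame; ``efficiency`` (same shape) is capacity visits
    consumed per service visit delivered, default 1.
    """

    shares: pd.Series  # index: service id, values sum to 1
    eligibility: pd.DataFrame  # services x professions, bool
    efficiency: pd.DataFrame | None = None
    shares_by_geography: pd.DataFrame | None = None  # geography x service

    def __post_init__(self) -> None:
        self.shares = self.shares.astype(float)
        if abs(self.shares.sum() - 1.0) > 1e-9:
            raise ValueError("service shares must sum to 1")
        if (self.shares < 0).any():
            raise ValueError("service shares must be non-negative")
        if list(self.eligibility.index) != list(self.shares.index):
            raise ValueError("eligibility rows must match the service list")
        if self.efficiency is None:
            self.efficiency = pd.DataFrame(
                1.0, index=self.eligibility.index, columns=self.eligibility.columns
            )
        if (
            list(self.efficiency.index) != list(self.eligibility.index)
            or list(self.efficiency.columns) != list(self.eligibility.columns)
        ):
            raise ValueError("efficiency frame must match eligibility shape")
        if (self.efficiency.to_numpy() <= 0).any():
            raise ValueError("efficiency entries must be positive")
        no_provider = self.eligibility.index[~self.eligibility.any(axis=1)]
        required = [s for s in no_provider if self.shares.loc[s] > 0]
        if required:
            raise ValueError(
                f"service(s) {list(required)} have a positive requirement share "
                "but no eligible profession"
            )
        if self.shares_by_geography is not None:
            sums = self.shares_by_geography.sum(axis=1)
            if (np.abs(sums - 1.0) > 1e-9).any():
                raise ValueError("per-geography service shares must sum to 1")

    @property
    def services(self) -> list[str]:
        return list(self.shares.index)

    @property
    def professions(self) -> list[str]:
        return list(self.eligibility.columns)

    def shares_for(self, geography_id: str) -> pd.Series:
        if self.shares_by_geography is not None and geography_id in self.shares_by_geography.index:
            return self.shares_by_geography.loc[geography_id]
        return self.shares


@dataclass
class GapReport:
    """Requirements-vs-capacity alignment at one geography level."""

    level: str
    table: pd.DataFrame  # geography_id, requirement, capacity, gap [, post_allocation_gap]
    plan: pd.DataFrame | None = None  # geography_id, service, profession, visits
    service_detail: pd.DataFrame | None = None  # geography_id, service, requirement, delivered, unmet

    @property
    def total_gap(self) -> float:
        return float(self.table["gap"].sum())

    @property
    def total_unmet(self) -> float:
        if self.service_detail is None:
            return float(self.table["gap"].clip(lower=0.0).sum())
        return float(self.service_detail["unmet"].sum())


def assess_alignment(
    req_table: pd.DataFrame, cap_table: pd.DataFrame, level: str
) -> GapReport:
    """Pre-allocation gap per geography: requirement - all-profession capacity."""
    req = req_table.set_index("geography_id")["v_tot"]
    cap_all = cap_table[cap_table["profession"] == "ALL"].set_index("geography_id")["capacity"]
    if set(req.index) != set(cap_all.index):
        raise ValueError(
            "requirements and capacity tables cover different geographies: "
            f"{sorted(set(req.index) ^ set(cap_all.index))[:5]}"
        )
    cap_all = cap_all.reindex(req.index)
    table = pd.DataFrame(
        {
            "geography_id": req.index,
            "requirement": req.to_numpy(dtype=float),
            "capacity": cap_all.to_numpy(dtype=float),
        }
    )
    table["gap"] = table["requirement"] - table["capacity"]
    return GapReport(level=level, table=table)


def solve_allocation(
    requirements: dict[str, float],
    capacities: dict[str, float],
    eligibility: pd.DataFrame,
    efficiency: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Exact LP for one geography: minimize unmet service visits.

    Variables are delivered(s, p) over eligible pairs; constraints are
    per-profession capacity (in capacity units, via efficiency) and
    per-service requirement caps. Returns (delivered frame services x
    professions, unmet total). A second phase fixes total delivery at its
    optimum and prefers professions in column order, making ties
    deterministic.
    """
    services = list(eligibility.index)
    professions = list(eligibility.columns)
    pairs = [
        (s, p)
        for s in services
        for p in professions
        if bool(eligibility.loc[s, p]) and requirements.get(s, 0.0) > 0
    ]
    delivered = pd.DataFrame(0.0, index=services, columns=professions)
    total_req = float(sum(requirements.get(s, 0.0) for s in services))
    if not pairs or total_req == 0:
        return delivered, total_req

    n = len(pairs)
    # Inequalities: capacity rows then requirement rows.
    A_ub, b_ub = [], []
    for p in professions:
        row = [float(efficiency.loc[s_, p_]) if p_ == p else 0.0 for s_, p_ in pairs]
        A_ub.append(row)
        b_ub.append(max(float(capacities.get(p, 0.0)), 0.0))
    for s in services:
        row = [1.0 if s_ == s else 0.0 for s_, p_ in pairs]
        A_ub.append(row)
        b_ub.append(float(requirements.get(s, 0.0)))

    res = linprog(
        c=-np.ones(n), A_ub=np.asarray(A_ub), b_ub=np.asarray(b_ub),
        bounds=[(0, None)] * n, method="highs",
    )
    if not res.success:  # pragma: no cover - LP above is always feasible (x=0)
        raise RuntimeError(f"allocation LP failed: {res.message}")
    best_total = -res.fun

    # Phase 2: among optimal plans, prefer earlier professions (lexicographic
    # tie-break): minimize sum of rank-weighted delivery at fixed total.
    weights = np.array([professions.index(p_) for _, p_ in pairs], dtype=float)
    res2 = linprog(
        c=weights,
        A_ub=np.asarray(A_ub), b_ub=np.asarray(b_ub),
        A_eq=np.ones((1, n)), b_eq=[best_total],
        bounds=[(0, None)] * n, method="highs",
    )
    x = res2.x if res2.success else res.x
    for (s, p), value in zip(pairs, x):
        delivered.loc[s, p] = max(float(value), 0.0)
    unmet = total_req - float(delivered.to_numpy().sum())
    return delivered, max(unmet, 0.0)


def allocate_services(
    req_table: pd.DataFrame,
    cap_table: pd.DataFrame,
    scope: ScopeMatrix,
    level: str,
    *,
    virtual_share: float = 0.0,
    virtual_efficiency: float = 1.0,
) -> GapReport:
    """Task-shifting allocation per geography at the requested level.

    Each geography's V_TOT splits into service-category requirements by the
    scope shares; the per-geography LP allocates them across eligible
    professions. ``virtual_share``/``virtual_efficiency`` rescale requirements
    to capacity-consumption units before solving (see :func:`shift_virtual`).
    """
    req = req_table.set_index("geography_id")["v_tot"]
    caps = cap_table[cap_table["profession"] != "ALL"]
    unknown = set(caps["profession"]) - set(scope.professions)
    if unknown:
        raise ValueError(f"professions {sorted(unknown)} missing from scope matrix")

    plan_rows, detail_rows, table_rows = [], [], []
    for gid in req.index:
        requirement_total = shift_virtual(
            float(req.loc[gid]), virtual_share, virtual_efficiency
        )
        shares = scope.shares_for(gid)
        service_req = {s: requirement_total * float(shares.loc[s]) for s in scope.services}
        geo_caps = (
            caps[caps["geography_id"] == gid]
            .groupby("profession")["capacity"].sum()
            .to_dict()
        )
        delivered, unmet = solve_allocation(
            service_req, geo_caps, scope.eligibility, scope.efficiency
        )
        for s in scope.services:
            row_delivered = float(delivered.loc[s].sum())
            detail_rows.append(
                {
                    "geography_id": gid, "service": s,
                    "requirement": service_req[s],
                    "delivered": row_delivered,
                    "unmet": max(service_req[s] - row_delivered, 0.0),
                }
            )
            for p in scope.professions:
                if delivered.loc[s, p] > 0:
                    plan_rows.append(
                        {"geography_id": gid, "service": s, "profession": p,
                         "visits": float(delivered.loc[s, p])}
                    )
        capacity_total = float(sum(geo_caps.values()))
        table_rows.append(
            {
                "geography_id": gid,
                "requirement": requirement_total,
                "capacity": capacity_total,
                "gap": requirement_total - capacity_total,
                "post_allocation_gap": unmet,
            }
        )
    return GapReport(
        level=level,
        table=pd.DataFrame(table_rows),
        plan=pd.DataFrame(plan_rows, columns=["geography_id", "service", "profession", "visits"]),
        service_detail=pd.DataFrame(detail_rows),
    )


def shift_virtual(
    requirement: float | pd.Series, virtual_share: float, virtual_efficiency: float
):
    """Re-express a visit requirement in capacity-consumption units.

    A ``virtual_share`` of visits moves to virtual delivery, each consuming
    ``virtual_efficiency`` capacity visits; in-person visits consume 1. The
    adjusted requirement is requirement x ((1 - share) + share x efficiency);
    share 0 or efficiency 1 leave totals unchanged.
    """
    if not 0.0 <= virtual_share <= 1.0:
        raise ValueError("virtual_share must lie in [0, 1]")
    if virtual_efficiency <= 0:
        raise ValueError("virtual_efficiency must be positive")
    factor = (1.0 - virtual_share) + virtual_share * virtual_efficiency
    return requirement * factor


def validate_plan(
    plan: pd.DataFrame,
    req_table: pd.DataFrame,
    cap_table: pd.DataFrame,
    scope: ScopeMatrix,
    level: str,
    tol: float = 1e-9,
) -> GapReport:
    """Check a user-supplied (descriptive) allocation plan against constraints.

    The plan must respect eligibility, per-profession capacity and
    per-service requirements; violations raise with the offending row named.
    Returns the resulting GapReport so manual plans report through the same
    channel as LP plans.
    """
    required_cols = {"geography_id", "service", "profession", "visits"}
    if not required_cols <= set(plan.columns):
        raise ValueError(f"plan must have columns {sorted(required_cols)}")
    if (plan["visits"] < 0).any():
        raise ValueError("plan visits must be non-negative")
    for _, row in plan.iterrows():
        if not bool(scope.eligibility.loc[row["service"], row["profession"]]):
            raise ValueError(
                f"plan assigns service {row['service']!r} to ineligible "
                f"profession {row['profession']!r}"
            )
    req = req_table.set_index("geography_id")["v_tot"]
    caps = cap_table[cap_table["profession"] != "ALL"]
    detail_rows, table_rows = [], []
    for gid in req.index:
        geo_plan = plan[plan["geography_id"] == gid]
        shares = scope.shares_for(gid)
        used = geo_plan.assign(
            consumed=lambda d: [
                v * float(scope.efficiency.loc[s, p])
                for s, p, v in zip(d["service"], d["profession"], d["visits"])
            ]
        ).groupby("profession")["consumed"].sum()
        geo_caps = caps[caps["geography_id"] == gid].groupby("profession")["capacity"].sum()
        for p, consumed in used.items():
            if consumed > float(geo_caps.get(p, 0.0)) + tol:
                raise ValueError(
                    f"plan over-uses capacity of {p!r} in geography {gid!r}"
                )
        for s in scope.services:
            s_req = float(req.loc[gid]) * float(shares.loc[s])
            s_del = float(geo_plan[geo_plan["service"] == s]["visits"].sum())
            if s_del > s_req + tol:
                raise ValueError(
                    f"plan over-delivers service {s!r} in geography {gid!r}"
                )
            detail_rows.append(
                {"geography_id": gid, "service": s, "requirement": s_req,
                 "delivered": s_del, "unmet": max(s_req - s_del, 0.0)}
            )
        capacity_total = float(geo_caps.sum())
        table_rows.append(
            {
                "geography_id": gid,
                "requirement": float(req.loc[gid]),
                "capacity": capacity_total,
                "gap": float(req.loc[gid]) - capacity_total,
                "post_allocation_gap": float(
                    sum(r["unmet"] for r in detail_rows if r["geography_id"] == gid)
                ),
            }
        )
    return GapReport(level=level, table=pd.DataFrame(table_rows),
                     plan=plan.copy(), service_detail=pd.DataFrame(detail_rows))


def final_alignment(report: GapReport, tol: float = 1e-6) -> pd.DataFrame:
    """Classify each geography as shortfall, surplus or aligned.

    Uses the post-allocation gap when present (shortfall = unmet need remains;
    surplus = spare capacity that could be diverted elsewhere), otherwise the
    raw requirement - capacity gap.
    """
    t = report.table
    if "post_allocation_gap" in t.columns:
        residual = np.where(
            t["post_allocation_gap"] > tol,
            t["post_allocation_gap"],
            np.minimum(t["gap"], 0.0),
        )
    else:
        residual = t["gap"].to_numpy(dtype=float)
    status = np.where(residual > tol, "shortfall", np.where(residual < -tol, "surplus", "aligned"))
    return pd.DataFrame(
        {
            "geography_id": t["geography_id"],
            "residual_gap": residual,
            "status": status,
        }
    )
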