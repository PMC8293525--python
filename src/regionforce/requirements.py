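"""Service requirements: total annual visits to be delivered in each place.

For neighbourhood x the requirement combines four additive terms:

    V_TOT_x = V_RES_x * P[x, x]                    (residents cared for at home)
            + sum_{n != x} V_RES_n * P[n, x]       (inflow from other neighbourhoods)
            + external_inflow_x                    (patients from outside the region)
            + UMN_x                                (unmet need, visit-equivalents)

Because the flow matrix is row-stochastic the first two terms conserve total
resident visits, giving the citywide identity
sum V_TOT = sum V_RES + sum external + sum UMN.

Two code paths compute the same quantity: a vectorized matrix form used by the
pipeline, and the literal per-neighbourhood summation kept as a readable
reference that the matrix form is regression-tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flows import FlowMatrix
from .region import Region, geography_groups
from .unmet import UnmetNeedEstimate

COMPONENT_COLUMNS = (
    "resident_retained",
    "inflow_neighbourhoods",
    "inflow_external",
    "unmet_need",
)


@dataclass
class RequirementsEstimate:
    """Per-neighbourhood V_TOT with its four-component decomposition."""

    table: pd.DataFrame  # index neighbourhood_id; v_tot + COMPONENT_COLUMNS

    def __post_init__(self) -> None:
        t = self.table
        for col in ("v_tot", *COMPONENT_COLUMNS):
            if col not in t.columns:
                raise ValueError(f"requirements table missing column {col!r}")
            if (t[col] < -1e-12).any():
                raise ValueError(f"requirements component {col!r} is negative")
        recomposed = t[list(COMPONENT_COLUMNS)].sum(axis=1)
        scale = np.maximum(t["v_tot"].abs(), 1.0)
        if (np.abs(recomposed - t["v_tot"]) / scale > 1e-6).any():
            raise ValueError("component decomposition does not reproduce v_tot")

    @property
    def v_tot(self) -> pd.Series:
        return self.table["v_tot"]


def compute_requirements(
    needs: pd.Series, flows: FlowMatrix, umn: UnmetNeedEstimate
) -> RequirementsEstimate:
    """Assemble V_TOT per neighbourhood from needs, flows and unmet need."""
    ids = list(flows.ids)
    if list(needs.index) != ids:
        raise ValueError("resident needs and flow matrix cover different regions")
    if list(umn.umn.index) != ids:
        raise ValueError("unmet need and flow matrix cover different regions")
    v = needs.to_numpy(dtype=float)
    located = v @ flows.P
    retained = v * np.diag(flows.P)
    table = pd.DataFrame(
        {
            "resident_retained": retained,
            "inflow_neighbourhoods": located - retained,
            "inflow_external": flows.external_inflow,
            "unmet_need": umn.umn.to_numpy(dtype=float),
        },
        index=pd.Index(ids, name="neighbourhood_id"),
    )
    table.insert(0, "v_tot", table.sum(axis=1))
    return RequirementsEstimate(table)


def compute_requirements_looped(
    needs: pd.Series, flows: FlowMatrix, umn: UnmetNeedEstimate
) -> pd.Series:
    """Literal summation form of the requirements equation (reference path).

    For each x: V_RES_x*P[x,x] + sum over n != x of V_RES_n*P[n,x]
    + external_x + UMN_x. Kept deliberately as explicit loops.
    """
    ids = list(flows.ids)
    v = needs.to_numpy(dtype=float)
    u = umn.umn.to_numpy(dtype=float)
    out = np.empty(len(ids))
    for x in range(len(ids)):
        total = v[x] * flows.P[x, x]
        for n in range(len(ids)):
            if n != x:
                total += v[n] * flows.P[n, x]
        total += flows.external_inflow[x] + u[x]
        out[x] = total
    return pd.Series(out, index=pd.Index(ids, name="neighbourhood_id"), name="v_tot")


def requirements_at_level(
    req: RequirementsEstimate, region: Region, level: str
) -> pd.DataFrame:
    """Aggregate requirements (component-wise, exact sums) to a geography level."""
    groups = geography_groups(region, level)
    rows = []
    for gid, members in groups.items():
        sub = req.table.loc[members]
        row = {"geography_id": gid, "level": level}
        row.update({col: float(sub[col].sum()) for col in sub.columns})
        rows.append(row)
    return pd.DataFrame(rows)
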