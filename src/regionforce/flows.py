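"""Origin-destination care-seeking flows.

The flow matrix P is row-stochastic: P[i, j] is the share of visits needed by
residents of neighbourhood i that are received in neighbourhood j. Its
diagonal is the "care at home" share; external inflow is an exogenous
per-destination vector of visits delivered to patients residing outside the
planning region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel origin id for visit records of patients residing outside the region.
EXTERNAL_ORIGIN = "EXTERNAL"

# Rows must sum to 1 to within this tolerance after renormalization.
ROW_SUM_TOL = 1e-9
# Deviations up to this size are silently renormalized; larger ones are
# treated as corrupt input and rejected.
ROW_SUM_RENORM_LIMIT = 1e-6


@dataclass
class FlowMatrix:
    """Row-stochastic OD proportions plus external inflow per destination."""

    ids: tuple[str, ...]
    P: np.ndarray
    external_inflow: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        n = len(self.ids)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (n, n):
            raise ValueError(
                f"flow matrix shape {self.P.shape} does not match {n} neighbourhoods"
            )
        if self.external_inflow is None:
            self.external_inflow = np.zeros(n)
        self.external_inflow = np.asarray(self.external_inflow, dtype=float)
        if self.external_inflow.shape != (n,):
            raise ValueError("external inflow length does not match region size")
        if np.any(self.external_inflow < 0):
            raise ValueError("external inflow must be non-negative")
        if np.any(self.P < -ROW_SUM_RENORM_LIMIT) or np.any(
            self.P > 1 + ROW_SUM_RENORM_LIMIT
        ):
            raise ValueError("flow proportions must lie in [0, 1]")
        row_sums = self.P.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > ROW_SUM_RENORM_LIMIT)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"flow matrix row {self.ids[i]!r} sums to {row_sums[i]:.9f}, not 1"
            )
        # Small drift (<= 1e-6) is renormalized so downstream conservation
        # identities hold to 1e-9.
        self.P = np.clip(self.P / row_sums[:, None], 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def diagonal(self) -> pd.Series:
        """Share of care residents receive at home (P_RES per neighbourhood)."""
        return pd.Series(np.diag(self.P), index=list(self.ids), name="p_res")

    def to_frame(self) -> pd.DataFrame:
        """Long (origin_id, destination_id, proportion) representation."""
        origins = np.repeat(self.ids, self.n)
        destinations = np.tile(self.ids, self.n)
        return pd.DataFrame(
            {
                "origin_id": origins,
                "destination_id": destinations,
                "proportion": self.P.ravel(),
            }
        )


def redistribute(needs: pd.Series, flows: FlowMatrix) -> pd.Series:
    """Locate resident needs at service destinations: located_j = sum_i v_i P[i,j].

    Conserves total visits because P is row-stochastic; external inflow is
    handled additively downstream and is *not* included here.
    """
    if list(needs.index) != list(flows.ids):
        raise ValueError("needs index does not match flow matrix neighbourhoods")
    located = needs.to_numpy(dtype=float) @ flows.P
    return pd.Series(located, index=list(flows.ids), name="located_visits")


def shift_care_closer_to_home(flows: FlowMatrix, delta: float) -> FlowMatrix:
    """Counterfactual: move a fraction delta of each row's away-from-home mass home.

    New diagonal p' = p + delta*(1-p); off-diagonal entries scale by (1-delta)
    so each row still sums to 1. delta=0 is the identity, delta=1 collapses
    the matrix to the identity matrix (all care at home).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    P = flows.P.copy()
    diag = np.diag(P).copy()
    P *= 1.0 - delta
    np.fill_diagonal(P, diag + delta * (1.0 - diag))
    return FlowMatrix(flows.ids, P, flows.external_inflow.copy())


def estimate_flows_from_visit_records(
    records: Iterable[tuple[str, str]], ids: Sequence[str]
) -> FlowMatrix:
    """Build a FlowMatrix from (origin, destination) visit records.

    P[i, j] is the observed share of origin-i visits received in j. Origins
    with no observed visits default to self-care (P[i, i] = 1), which keeps
    the identity limit clean for empty inputs. Records with the
    ``EXTERNAL`` origin sentinel accumulate into the external-inflow vector.
    """
    ids = list(ids)
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    counts = np.zeros((n, n))
    external = np.zeros(n)
    for origin, destination in records:
        if destination not in index:
            raise ValueError(f"unknown destination id {destination!r}")
        j = index[destination]
        if origin == EXTERNAL_ORIGIN:
            external[j] += 1
        elif origin in index:
            counts[index[origin], j] += 1
        else:
            raise ValueError(f"unknown origin id {origin!r}")
    totals = counts.sum(axis=1)
    P = np.eye(n)
    observed = totals > 0
    P[observed] = counts[observed] / totals[observed, None]
    return FlowMatrix(tuple(ids), P, external)
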