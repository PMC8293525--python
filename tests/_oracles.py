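"""Independent brute-force oracles kept deliberately naive.

These re-derive expected values by direct enumeration or explicit loops and
must stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def double_loop_visits(counts: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Per-neighbourhood expected visits by explicit double loop."""
    n, k = counts.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(k):
            out[i] += counts[i, j] * rates[j]
    return out


def double_loop_redistribute(v: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Located visits per destination by explicit double loop."""
    n = len(v)
    out = np.zeros(n)
    for j in range(n):
        for i in range(n):
            out[j] += v[i] * P[i, j]
    return out


def iterate_stock(headcount: float, exit_rate: float, inflow: float, years: int) -> float:
    """Single-cohort stock projection by explicit annual iteration."""
    h = headcount
    for _ in range(years):
        h = max(h * (1.0 - exit_rate), 0.0) + inflow * h
    return h


def brute_force_min_unmet(
    requirements: dict[str, int],
    capacities: dict[str, int],
    eligible: dict[tuple[str, str], bool],
) -> int:
    """Exhaustive search over integer allocations (efficiency 1).

    Enumerates delivered(service, profession) over every feasible integer
    grid point via depth-first search with a sound upper-bound prune, and
    returns the minimum total unmet service visits. With unit efficiency the
    constraint matrix is totally unimodular, so this integer optimum equals
    the LP optimum.
    """
    services = list(requirements)
    professions = list(capacities)
    pairs = [
        (s, p) for s in services for p in professions if eligible.get((s, p), False)
    ]
    total_req = sum(requirements.values())
    best_delivered = 0
    rem_req = dict(requirements)
    rem_cap = dict(capacities)

    def dfs(k: int, delivered: int) -> None:
        nonlocal best_delivered
        bound = delivered + min(sum(rem_req.values()), sum(rem_cap.values()))
        if bound <= best_delivered:
            return
        if k == len(pairs):
            best_delivered = max(best_delivered, delivered)
            return
        s, p = pairs[k]
        top = min(rem_req[s], rem_cap[p])
        for d in range(top, -1, -1):
            rem_req[s] -= d
            rem_cap[p] -= d
            dfs(k + 1, delivered + d)
            rem_req[s] += d
            rem_cap[p] += d

    dfs(0, 0)
    return total_req - best_delivered
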