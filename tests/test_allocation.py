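"""Gap assessment and LP allocation against brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest

import regionforce as rf
from _oracles import brute_force_min_unmet


def _scope(shares, eligibility, efficiency=None):
    services = list(shares)
    professions = list(next(iter(eligibility.values())).keys()) if isinstance(
        next(iter(eligibility.values())), dict
    ) else list(eligibility)
    elig = pd.DataFrame(
        {p: [eligibility[s][p] for s in services] for p in eligibility[services[0]]},
        index=services,
    )
    eff = None
    if efficiency is not None:
        eff = pd.DataFrame(
            {p: [efficiency[s][p] for s in services] for p in efficiency[services[0]]},
            index=services,
        )
    return rf.ScopeMatrix(pd.Series(shares), elig, eff)


class TestAssessAlignment:
    def _tables(self, req_values, cap_values):
        req = pd.DataFrame({"geography_id": list(req_values), "level": "city",
                            "v_tot": list(req_values.values())})
        rows = []
        for gid, c in cap_values.items():
            rows.append({"geography_id": gid, "level": "city",
                         "profession": "family_physician", "capacity": c})
            rows.append({"geography_id": gid, "level": "city",
                         "profession": "ALL", "capacity": c})
        return req, pd.DataFrame(rows)

    def test_perfect_alignment_gap_zero(self):
        req, cap = self._tables({"g": 100.0}, {"g": 100.0})
        report = rf.assess_alignment(req, cap, "city")
        assert report.table["gap"].iloc[0] == 0.0

    def test_shortfall_is_positive(self):
        req, cap = self._tables({"g": 150.0}, {"g": 100.0})
        report = rf.assess_alignment(req, cap, "city")
        assert report.table["gap"].iloc[0] == pytest.approx(50.0)

    def test_random_tables_match_subtraction(self):
        rng = np.random.default_rng(2)
        reqs = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 100, 10))}
        caps = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 100, 10))}
        req, cap = self._tables(reqs, caps)
        report = rf.assess_alignment(req, cap, "city")
        for _, row in report.table.iterrows():
            assert row["gap"] == pytest.approx(
                reqs[row["geography_id"]] - caps[row["geography_id"]]
            )

    def test_geography_mismatch_rejected(self):
        req, cap = self._tables({"g": 1.0}, {"h": 1.0})
        with pytest.raises(ValueError, match="different geographies"):
            rf.assess_alignment(req, cap, "city")


class TestSolveAllocation:
    def test_single_omnipotent_profession_closes_gap(self):
        scope_elig = pd.DataFrame({"fp": [True, True]}, index=["s1", "s2"])
        eff = pd.DataFrame({"fp": [1.0, 1.0]}, index=["s1", "s2"])
        delivered, unmet = rf.solve_allocation(
            {"s1": 60.0, "s2": 40.0}, {"fp": 200.0}, scope_elig, eff
        )
        assert unmet == pytest.approx(0.0, abs=1e-9)
        assert delivered.to_numpy().sum() == pytest.approx(100.0)

    def test_worked_overlapping_scope_instance(self):
        """Services 60/40; A (both, cap 50), B (service 2 only, cap 40).

        Optimal: B covers all 40 of service 2, A delivers 50 of service 1,
        leaving exactly 10 unmet.
        """
        elig = pd.DataFrame({"A": [True, True], "B": [False, True]},
                            index=["s1", "s2"])
        eff = pd.DataFrame(1.0, index=["s1", "s2"], columns=["A", "B"])
        delivered, unmet = rf.solve_allocation(
            {"s1": 60.0, "s2": 40.0}, {"A": 50.0, "B": 40.0}, elig, eff
        )
        assert unmet == pytest.approx(10.0, abs=1e-9)
        assert delivered.loc["s2", "B"] == pytest.approx(40.0, abs=1e-9)
        oracle = brute_force_min_unmet(
            {"s1": 60, "s2": 40}, {"A": 50, "B": 40},
            {("s1", "A"): True, ("s2", "A"): True, ("s2", "B"): True},
        )
        assert unmet == pytest.approx(oracle, abs=1e-9)

    def test_ineligible_pairs_get_zero(self):
        elig = pd.DataFrame({"A": [True, False], "B": [False, True]},
                            index=["s1", "s2"])
        eff = pd.DataFrame(1.0, index=["s1", "s2"], columns=["A", "B"])
        delivered, _ = rf.solve_allocation(
            {"s1": 10.0, "s2": 10.0}, {"A": 100.0, "B": 100.0}, elig, eff
        )
        assert delivered.loc["s2", "A"] == 0.0
        assert delivered.loc["s1", "B"] == 0.0

    def test_conservation_delivered_plus_unmet(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            services = [f"s{i}" for i in range(int(rng.integers(1, 4)))]
            profs = [f"p{i}" for i in range(int(rng.integers(1, 4)))]
            elig = pd.DataFrame(rng.random((len(services), len(profs))) < 0.7,
                                index=services, columns=profs)
            elig.iloc[:, 0] = True  # keep every service deliverable
            eff = pd.DataFrame(1.0, index=services, columns=profs)
            req = {s: float(rng.integers(0, 16)) for s in services}
            cap = {p: float(rng.integers(0, 21)) for p in profs}
            delivered, unmet = rf.solve_allocation(req, cap, elig, eff)
            assert delivered.to_numpy().sum() + unmet == pytest.approx(
                sum(req.values()), abs=1e-7
            )
            # Capacity is never exceeded.
            for p in profs:
                assert delivered[p].sum() <= cap[p] + 1e-7

    def test_lp_equals_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_s, n_p = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            services = [f"s{i}" for i in range(n_s)]
            profs = [f"p{i}" for i in range(n_p)]
            elig_mask = rng.random((n_s, n_p)) < 0.6
            elig_mask[:, 0] |= ~elig_mask.any(axis=1)
            elig = pd.DataFrame(elig_mask, index=services, columns=profs)
            eff = pd.DataFrame(1.0, index=services, columns=profs)
            req = {s: int(rng.integers(0, 16)) for s in services}
            cap = {p: int(rng.integers(0, 21)) for p in profs}
            _, lp_unmet = rf.solve_allocation(
                {k: float(v) for k, v in req.items()},
                {k: float(v) for k, v in cap.items()}, elig, eff,
            )
            oracle = brute_force_min_unmet(
                req, cap,
                {(s, p): bool(elig.loc[s, p]) for s in services for p in profs},
            )
            assert lp_unmet == pytest.approx(oracle, abs=1e-6)

    def test_efficiency_inflates_capacity_use(self):
        elig = pd.DataFrame({"A": [True]}, index=["s1"])
        eff = pd.DataFrame({"A": [2.0]}, index=["s1"])  # 2 capacity per visit
        delivered, unmet = rf.solve_allocation({"s1": 10.0}, {"A": 10.0}, elig, eff)
        assert delivered.loc["s1", "A"] == pytest.approx(5.0)
        assert unmet == pytest.approx(5.0)

    def test_tie_break_prefers_earlier_profession(self):
        elig = pd.DataFrame({"first": [True], "second": [True]}, index=["s1"])
        eff = pd.DataFrame(1.0, index=["s1"], columns=["first", "second"])
        delivered, _ = rf.solve_allocation({"s1": 10.0},
                                           {"first": 10.0, "second": 10.0},
                                           elig, eff)
        assert delivered.loc["s1", "first"] == pytest.approx(10.0)
        assert delivered.loc["s1", "second"] == pytest.approx(0.0)


class TestScopeMatrix:
    def test_uncovered_required_service_rejected(self):
        elig = pd.DataFrame({"A": [True, False]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            rf.ScopeMatrix(pd.Series({"s1": 0.5, "s2": 0.5}), elig)

    def test_shares_must_sum_to_one(self):
        elig = pd.DataFrame({"A": [True]}, index=["s1"])
        with pytest.raises(ValueError, match="sum to 1"):
            rf.ScopeMatrix(pd.Series({"s1": 0.7}), elig)


class TestShiftVirtual:
    def test_share_zero_identity(self):
        assert rf.shift_virtual(100.0, 0.0, 0.8) == pytest.approx(100.0)

    def test_full_virtual_unit_efficiency_conserves(self):
        assert rf.shift_virtual(100.0, 1.0, 1.0) == pytest.approx(100.0)

    def test_half_virtual_at_80_percent(self):
        assert rf.shift_virtual(100.0, 0.5, 0.8) == pytest.approx(90.0)


class TestAllocateServices:
    def _inputs(self):
        req = pd.DataFrame({"geography_id": ["g"], "level": ["city"],
                            "v_tot": [100.0]})
        cap = pd.DataFrame(
            [
                {"geography_id": "g", "level": "city",
                 "profession": "family_physician", "capacity": 80.0},
                {"geography_id": "g", "level": "city",
                 "profession": "nurse_practitioner", "capacity": 40.0},
                {"geography_id": "g", "level": "city",
                 "profession": "ALL", "capacity": 120.0},
            ]
        )
        scope = rf.generate_scope_matrix(["family_physician", "nurse_practitioner"])
        return req, cap, scope

    def test_surplus_capacity_closes_gap(self):
        req, cap, scope = self._inputs()
        report = rf.allocate_services(req, cap, scope, "city")
        assert report.table["post_allocation_gap"].iloc[0] == pytest.approx(0.0,
                                                                            abs=1e-7)
        # delivered + unmet = requirement per service
        detail = report.service_detail
        np.testing.assert_allclose(
            (detail["delivered"] + detail["unmet"]).to_numpy(),
            detail["requirement"].to_numpy(), rtol=1e-9,
        )

    def test_allocation_never_worsens_unmet(self):
        """Optimal task shifting beats any fixed no-shifting assignment."""
        rng = np.random.default_rng(23)
        scope = rf.generate_scope_matrix(["family_physician", "nurse_practitioner",
                                          "registered_nurse"])
        for _ in range(50):
            v_tot = float(rng.uniform(50, 300))
            caps = {p: float(rng.uniform(0, 150)) for p in scope.professions}
            req = pd.DataFrame({"geography_id": ["g"], "level": ["city"],
                                "v_tot": [v_tot]})
            rows = [{"geography_id": "g", "level": "city", "profession": p,
                     "capacity": c} for p, c in caps.items()]
            rows.append({"geography_id": "g", "level": "city",
                         "profession": "ALL", "capacity": sum(caps.values())})
            report = rf.allocate_services(req, pd.DataFrame(rows), scope, "city")
            # Baseline without task shifting: each service served greedily by
            # its first eligible profession out of that profession's
            # remaining capacity — a feasible, fixed assignment.
            remaining = dict(caps)
            baseline_unmet = 0.0
            for s in scope.services:
                p = next(p for p in scope.professions if scope.eligibility.loc[s, p])
                want = v_tot * scope.shares[s]
                served = min(want, remaining[p])
                remaining[p] -= served
                baseline_unmet += want - served
            assert report.total_unmet <= baseline_unmet + 1e-6

    def test_virtual_share_reduces_effective_requirement(self):
        req, cap, scope = self._inputs()
        base = rf.allocate_services(req, cap, scope, "city")
        virtual = rf.allocate_services(req, cap, scope, "city",
                                       virtual_share=0.5, virtual_efficiency=0.8)
        assert virtual.table["requirement"].iloc[0] == pytest.approx(
            0.9 * base.table["requirement"].iloc[0]
        )


class TestFinalAlignment:
    def test_zero_gap_is_aligned(self):
        report = rf.GapReport("city", pd.DataFrame(
            {"geography_id": ["g"], "requirement": [10.0], "capacity": [10.0],
             "gap": [0.0]}
        ))
        summary = rf.final_alignment(report)
        assert summary["status"].iloc[0] == "aligned"

    def test_mixed_signs_classified(self):
        report = rf.GapReport("city", pd.DataFrame(
            {
                "geography_id": ["a", "b", "c"],
                "requirement": [10.0, 10.0, 10.0],
                "capacity": [5.0, 15.0, 10.0],
                "gap": [5.0, -5.0, 0.0],
            }
        ))
        summary = rf.final_alignment(report)
        assert list(summary["status"]) == ["shortfall", "surplus", "aligned"]

    def test_counts_match_direct_filter(self):
        rng = np.random.default_rng(3)
        gaps = rng.uniform(-10, 10, 40)
        report = rf.GapReport("city", pd.DataFrame(
            {
                "geography_id": [f"g{i}" for i in range(40)],
                "requirement": np.abs(gaps) + 10,
                "capacity": np.abs(gaps) + 10 - gaps,
                "gap": gaps,
            }
        ))
        summary = rf.final_alignment(report)
        assert (summary["status"] == "shortfall").sum() == (gaps > 1e-6).sum()
        assert (summary["status"] == "surplus").sum() == (gaps < -1e-6).sum()


class TestValidatePlan:
    def _inputs(self):
        req = pd.DataFrame({"geography_id": ["g"], "level": ["city"],
                            "v_tot": [100.0]})
        cap = pd.DataFrame(
            [
                {"geography_id": "g", "level": "city",
                 "profession": "family_physician", "capacity": 120.0},
                {"geography_id": "g", "level": "city",
                 "profession": "registered_nurse", "capacity": 40.0},
                {"geography_id": "g", "level": "city",
                 "profession": "ALL", "capacity": 160.0},
            ]
        )
        scope = rf.generate_scope_matrix(["family_physician", "registered_nurse"])
        return req, cap, scope

    def test_valid_manual_plan_accepted(self):
        req, cap, scope = self._inputs()
        plan = pd.DataFrame(
            [{"geography_id": "g", "service": "preventive",
              "profession": "registered_nurse", "visits": 20.0}]
        )
        report = rf.validate_plan(plan, req, cap, scope, "city")
        assert report.plan is not None

    def test_ineligible_assignment_rejected(self):
        req, cap, scope = self._inputs()
        plan = pd.DataFrame(
            [{"geography_id": "g", "service": "routine_acute",
              "profession": "registered_nurse", "visits": 1.0}]
        )
        with pytest.raises(ValueError, match="ineligible"):
            rf.validate_plan(plan, req, cap, scope, "city")

    def test_over_capacity_plan_rejected(self):
        req, cap, scope = self._inputs()
        plan = pd.DataFrame(
            [{"geography_id": "g", "service": "preventive",
              "profession": "registered_nurse", "visits": 500.0}]
        )
        with pytest.raises(ValueError, match="over-"):
            rf.validate_plan(plan, req, cap, scope, "city")
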