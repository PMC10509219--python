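"""Allocation LP, greedy oracle, sampler, constraint families, uncertainty."""

import numpy as np
import pytest

from aqequity import (
    CRF,
    ConstraintSpec,
    build_constraints,
    evaluate_scenario,
    greedy_ratio_oracle,
    sample_scenarios,
    solve_allocation,
    source_total_mortality,
    uncertainty_bounds,
)
from aqequity.errors import AlignmentError, InfeasibleError, LabelError
from aqequity.optimize import ReductionScenario, policy_retention, realize_inventory

from conftest import enumerate_vertex_optimum, random_single_group_instance


def _single_group_spec(co2, target):
    eligible = np.asarray(co2) > 0
    return ConstraintSpec(family="nation-total", eligible=eligible,
                          groups={"nation": eligible}, targets={"nation": float(target)})


class TestSolveAllocation:
    def test_two_source_vertex(self):
        """TM=(10,1), CO2=(1,1), target 1, min -> keep the cleaner source."""
        sol = solve_allocation(np.array([10.0, 1.0]), np.array([1.0, 1.0]),
                               _single_group_spec([1.0, 1.0], 1.0), "min")
        assert sol.s == pytest.approx([0.0, 1.0], abs=1e-9)
        assert sol.objective == pytest.approx(1.0, rel=1e-9)

    def test_full_target_forces_all_ones(self):
        tm, co2 = np.array([3.0, 5.0]), np.array([2.0, 4.0])
        sol = solve_allocation(tm, co2, _single_group_spec(co2, co2.sum()), "min")
        assert sol.s == pytest.approx([1.0, 1.0], abs=1e-9)
        assert sol.objective == pytest.approx(tm.sum(), rel=1e-9)

    def test_zero_target_forces_all_zeros(self):
        tm, co2 = np.array([3.0, 5.0]), np.array([2.0, 4.0])
        sol = solve_allocation(tm, co2, _single_group_spec(co2, 0.0), "min")
        assert sol.s == pytest.approx([0.0, 0.0], abs=1e-9)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_target_names_group(self):
        with pytest.raises(InfeasibleError, match="nation"):
            solve_allocation(np.array([1.0]), np.array([1.0]),
                             _single_group_spec([1.0], 2.0), "min")

    def test_constraint_residuals_within_tolerance(self, small_study):
        sol = solve_allocation(small_study["tm"], small_study["co2"],
                               small_study["spec"], "min")
        for key, target in small_study["spec"].targets.items():
            assert sol.co2_by_group[key] == pytest.approx(target, rel=1e-9)


class TestGreedyOracle:
    def test_ratio_order_two_sources(self):
        sol = greedy_ratio_oracle(np.array([10.0, 1.0]), np.array([1.0, 1.0]), 1.0, "min")
        assert sol.s == pytest.approx([0.0, 1.0])

    def test_equal_ratio_tie_zeroes_lower_id_first(self):
        sol = greedy_ratio_oracle(np.array([2.0, 2.0]), np.array([1.0, 1.0]), 1.0, "min")
        assert sol.s == pytest.approx([0.0, 1.0])

    def test_fractional_marginal_source(self):
        # zero worst source (id 0), half-retain the next
        sol = greedy_ratio_oracle(np.array([10.0, 4.0, 1.0]),
                                  np.array([1.0, 2.0, 1.0]), 2.0, "min")
        assert sol.s == pytest.approx([0.0, 0.5, 1.0])
        assert sol.objective == pytest.approx(3.0)

    @pytest.mark.parametrize("sense", ["min", "max"])
    def test_matches_vertex_enumeration_on_random_instances(self, sense):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tm, co2, target = random_single_group_instance(rng, n_max=6)
            greedy = greedy_ratio_oracle(tm, co2, target, sense)
            brute = enumerate_vertex_optimum(tm, co2, target, sense)
            assert greedy.objective == pytest.approx(brute, rel=1e-9, abs=1e-9)


class TestThreeWayOracleAgreement:
    @pytest.mark.parametrize("sense", ["min", "max"])
    def test_lp_greedy_enumeration_agree(self, sense):
        rng = np.random.default_rng(11)
        for _ in range(40):
            tm, co2, target = random_single_group_instance(rng, n_max=8)
            lp = solve_allocation(tm, co2, _single_group_spec(co2, target), sense)
            greedy = greedy_ratio_oracle(tm, co2, target, sense)
            brute = enumerate_vertex_optimum(tm, co2, target, sense)
            assert lp.objective == pytest.approx(brute, rel=1e-9, abs=1e-9)
            assert greedy.objective == pytest.approx(brute, rel=1e-9, abs=1e-9)


class TestBuildConstraints:
    def test_nation_total_single_group(self, small_study):
        spec = small_study["spec"]
        assert list(spec.groups) == ["nation"]
        assert spec.groups["nation"].sum() == spec.eligible.sum()

    def test_state_sector_partitions_eligible(self, small_study):
        spec = build_constraints(small_study["inv"], small_study["inv_policy"],
                                 "state-sector", tm=small_study["tm"])
        cover = sum(m.astype(int) for m in spec.groups.values())
        np.testing.assert_array_equal(cover > 0, spec.eligible)
        assert (cover <= 1).all()

    def test_zero_co2_source_ineligible(self, small_study):
        import dataclasses

        inv = [dataclasses.replace(s) for s in small_study["inv"]]
        inv[0] = dataclasses.replace(inv[0], co2=0.0)
        inv_policy = [dataclasses.replace(s) for s in small_study["inv_policy"]]
        inv_policy[0] = dataclasses.replace(inv_policy[0], co2=0.0)
        spec = build_constraints(inv, inv_policy, "nation-total")
        assert not spec.eligible[0]

    def test_zero_mortality_source_ineligible_with_tm(self, small_study):
        tm = small_study["tm"].copy()
        tm[3] = 0.0
        spec = build_constraints(small_study["inv"], small_study["inv_policy"],
                                 "nation-total", tm=tm)
        assert not spec.eligible[3]

    def test_mismatched_source_sets_raise(self, small_study):
        with pytest.raises(AlignmentError):
            build_constraints(small_study["inv"], small_study["inv_policy"][:-1],
                              "nation-total")

    def test_unknown_family_raises(self, small_study):
        with pytest.raises(LabelError):
            build_constraints(small_study["inv"], small_study["inv_policy"], "county-total")


class TestNestingMonotonicity:
    def test_fewer_constraints_never_worse(self, small_study):
        """nation-total <= {nation-sector, state-total} <= state-sector <= policy."""
        inv, inv_policy = small_study["inv"], small_study["inv_policy"]
        tm, co2 = small_study["tm"], small_study["co2"]
        obj = {}
        for family in ("nation-total", "nation-sector", "state-total", "state-sector"):
            spec = build_constraints(inv, inv_policy, family, tm=tm)
            obj[family] = solve_allocation(tm, co2, spec, "min").objective
        spec_ss = build_constraints(inv, inv_policy, "state-sector", tm=tm)
        s_policy = policy_retention(inv, inv_policy)
        policy_obj = float((s_policy * tm)[spec_ss.eligible].sum())
        tol = 1e-9 * max(policy_obj, 1.0)
        assert obj["nation-total"] <= obj["nation-sector"] + tol
        assert obj["nation-total"] <= obj["state-total"] + tol
        assert obj["nation-sector"] <= obj["state-sector"] + tol
        assert obj["state-total"] <= obj["state-sector"] + tol
        assert obj["state-sector"] <= policy_obj + tol


class TestSampler:
    def test_residuals_within_tolerance(self, small_study):
        spec, co2 = small_study["spec"], small_study["co2"]
        for sc in sample_scenarios(co2, spec, n=20, seed=5):
            for key, target in spec.targets.items():
                assert sc.co2_by_group[key] == pytest.approx(target, rel=1e-6)

    def test_same_seed_identical_scenarios(self, small_study):
        spec, co2 = small_study["spec"], small_study["co2"]
        a = sample_scenarios(co2, spec, n=5, seed=9)
        b = sample_scenarios(co2, spec, n=5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.s, y.s)

    def test_objectives_inside_optimal_envelope(self, small_study):
        spec, co2, tm = small_study["spec"], small_study["co2"], small_study["tm"]
        lo = solve_allocation(tm, co2, spec, "min").objective
        hi = solve_allocation(tm, co2, spec, "max").objective
        tol = 1e-9 * max(hi, 1.0)
        for sc in sample_scenarios(co2, spec, n=50, seed=3):
            objective = float((sc.s * tm)[spec.eligible].sum())
            assert lo - tol <= objective <= hi + tol


class TestStringencyMonotonicity:
    def test_deeper_cuts_never_increase_min_mortality(self, small_study):
        """Retained-CO2 targets 60%/50%/40% of baseline: objective decreases."""
        tm, co2 = small_study["tm"], small_study["co2"]
        eligible = small_study["spec"].eligible
        cap = co2[eligible].sum()
        objs = []
        for retained in (0.6, 0.5, 0.4):
            spec = _single_group_spec(np.where(eligible, co2, 0.0), retained * cap)
            objs.append(solve_allocation(tm, co2, spec, "min").objective)
        assert objs[0] >= objs[1] >= objs[2]


class TestEvaluateScenario:
    def test_all_ones_reproduces_baseline(self, small_study):
        s = ReductionScenario(s=np.ones(len(small_study["inv"])), source_ids=[],
                              objective=float("nan"), provenance="policy-case")
        point, table = evaluate_scenario(s, small_study["inv"], small_study["srm"],
                                         small_study["pop"], small_study["incidence"],
                                         CRF())
        assert point.d_exposure_minority == pytest.approx(0.0, abs=1e-12)
        assert point.d_disparity_minority_pp == pytest.approx(0.0, abs=1e-12)

    def test_all_zeros_leaves_background_only(self, small_study):
        from aqequity.airquality import apply_srm

        s = ReductionScenario(s=np.zeros(len(small_study["inv"])), source_ids=[],
                              objective=float("nan"), provenance="sampled")
        field = apply_srm(realize_inventory(s, small_study["inv"]), small_study["srm"],
                          background=0.1)
        np.testing.assert_allclose(field.total, 0.1, atol=1e-15)

    def test_min_optimum_beats_every_sample_on_mortality(self, small_study):
        tm, co2, spec = small_study["tm"], small_study["co2"], small_study["spec"]
        opt = solve_allocation(tm, co2, spec, "min")
        args = (small_study["inv"], small_study["srm"], small_study["pop"],
                small_study["incidence"], CRF())
        opt_point, _ = evaluate_scenario(opt, *args)
        for sc in sample_scenarios(co2, spec, n=10, seed=2):
            point, _ = evaluate_scenario(sc, *args)
            assert opt_point.objective <= point.objective + 1e-9 * point.objective

    def test_realized_inventory_scales_all_pollutants_jointly(self, small_study):
        inv = small_study["inv"]
        s = np.full(len(inv), 0.5)
        sc = ReductionScenario(s=s, source_ids=[], objective=float("nan"),
                               provenance="sampled")
        out = realize_inventory(sc, inv)
        for a, b in zip(inv, out):
            assert b.co2 == pytest.approx(0.5 * a.co2)
            for p, m in a.pollutants.items():
                assert b.mass(p) == pytest.approx(0.5 * m)


class TestUncertaintyBounds:
    def test_bounds_bracket_policy_case(self, small_study):
        from aqequity.exposure import scenario_delta_table
        from aqequity.airquality import apply_srm
        from aqequity.optimize import realize_inventory

        inv, inv_policy = small_study["inv"], small_study["inv_policy"]
        bounds = uncertainty_bounds(inv, inv_policy, small_study["srm"],
                                    small_study["pop"], small_study["incidence"],
                                    CRF(), tm=small_study["tm"])
        policy = ReductionScenario(s=policy_retention(inv, inv_policy), source_ids=[],
                                   objective=float("nan"), provenance="policy-case")
        base_field = apply_srm(inv, small_study["srm"])
        field = apply_srm(realize_inventory(policy, inv), small_study["srm"])
        table = scenario_delta_table(field, base_field, small_study["pop"])
        for g in bounds.index:
            de = table.loc[g, "d_exposure"]
            assert bounds.loc[g, "d_exposure_lo"] <= de + 1e-9
            assert de <= bounds.loc[g, "d_exposure_hi"] + 1e-9

    def test_single_point_source_per_group_collapses_bounds(self, small_study):
        """With no redistribution freedom the range is the policy case."""
        import dataclasses

        # restrict to one point source: all others become area sources
        inv = [dataclasses.replace(s, kind="area", stack=None) if i > 0
               else dataclasses.replace(s, kind="point")
               for i, s in enumerate(small_study["inv"])]
        inv_policy = [dataclasses.replace(s, kind="area", stack=None) if i > 0
                      else dataclasses.replace(s, kind="point")
                      for i, s in enumerate(small_study["inv_policy"])]
        bounds = uncertainty_bounds(inv, inv_policy, small_study["srm"],
                                    small_study["pop"], small_study["incidence"],
                                    CRF(), tm=small_study["tm"])
        for g in bounds.index:
            assert bounds.loc[g, "d_exposure_lo"] == pytest.approx(
                bounds.loc[g, "d_exposure_hi"], abs=1e-9)
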