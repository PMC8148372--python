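import numpy as np
import pytest

from bpscreen.markov import (
    CohortSpec,
    Stratum,
    build_arm_cohorts,
    build_switcher_cohorts,
    discounted_sum,
    incremental_results,
    run_cohort,
)
from bpscreen.risk_engine import framingham_risk, RiskProfile
from bpscreen.short_term import arm_cost_ledger, build_baseline_scenario
from bpscreen.uncertainty import evaluate_incremental

from _oracles import microsimulate


class TestDiscountedSum:
    def test_zero_rate_is_plain_sum(self):
        assert discounted_sum([3.0, 4.0, 5.0], 0.0) == pytest.approx(12.0)

    def test_two_cycle_hand_check(self):
        assert discounted_sum([100.0, 100.0], 0.03) == pytest.approx(
            100.0 + 100.0 / 1.03
        )

    def test_empty_stream(self):
        assert discounted_sum([], 0.03) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discounted_sum([1.0], -0.01)


class TestRunCohort:
    def test_zero_risk_cohort_yields_annuity_qalys(self, params, deathless_table):
        """No events, no deaths: QALYs are the closed-form discounted annuity."""
        cohort = CohortSpec(
            "toy", (Stratum(count=250.0, sex="male", age=53, status="normotensive"),)
        )
        trace = run_cohort(
            cohort,
            params,
            deathless_table,
            risk_multipliers={"ami": 0.0, "stroke": 0.0},
        )
        annuity = sum(1.03**-t for t in range(20))
        assert trace.total_qalys == pytest.approx(250.0 * annuity, rel=1e-12)
        assert trace.total_cost == 0.0

    def test_two_cycle_trace_matches_hand_computation(self, params, deathless_table):
        """One stratum, two cycles, no background mortality: occupancy,
        costs and QALYs equal explicit hand-computed matrix-vector products."""
        stratum = Stratum(count=1.0, sex="male", age=53, status="untreated")
        trace = run_cohort(
            CohortSpec("toy", (stratum,)), params, deathless_table, horizon=2
        )
        prof = RiskProfile(age=53, sex="male", sbp=147, tc_hdl_ratio=4.0)
        pa = framingham_risk(prof, "mi")
        ps = framingham_risk(prof, "stroke")
        # cycle 1 occupancy: split of the initial healthy unit
        expected_1 = [1 - pa - ps, pa, ps, 0.0, 0.0, 0.0]
        assert trace.occupancy[0, 1] == pytest.approx(expected_1, abs=1e-15)
        # rewards: cycle 0 healthy, cycle 1 carries event-year costs/decrements
        cost_1 = (pa + ps) * 112_000
        qaly_1 = (1 - pa - ps) + 0.75 * pa + 0.5 * ps
        assert trace.cost_stream == pytest.approx([0.0, cost_1])
        assert trace.qaly_stream == pytest.approx([1.0, qaly_1])
        assert trace.total_qalys == pytest.approx(1.0 + qaly_1 / 1.03)

    def test_occupancy_conserved_every_cycle(self, params, life_table):
        screen, _ = build_arm_cohorts(params, "all")
        trace = run_cohort(screen, params, life_table)
        totals = trace.occupancy_total().sum(axis=1)
        assert np.allclose(totals, params.cohort_size, atol=1e-9)

    def test_qalys_bounded_by_life_years_and_horizon(self, params, life_table):
        screen, _ = build_arm_cohorts(params, "all")
        trace = run_cohort(screen, params, life_table)
        alive = trace.occupancy[:, :20, :5].sum(axis=(0, 2))
        discounted_ly = discounted_sum(alive, params.discount_rate)
        assert trace.total_qalys <= discounted_ly <= trace.life_years
        assert trace.life_years <= 20 * params.cohort_size

    def test_drug_cost_accrues_only_while_alive_and_treated(
        self, params, deathless_table
    ):
        treated = CohortSpec(
            "t", (Stratum(count=10.0, sex="female", age=53, status="treated"),)
        )
        trace = run_cohort(
            treated,
            params,
            deathless_table,
            risk_multipliers={"ami": 0.0, "stroke": 0.0},
        )
        annuity = sum(1.03**-t for t in range(20))
        assert trace.total_cost == pytest.approx(10.0 * 2150.0 * annuity, rel=1e-12)

    def test_horizon_below_one_rejected(self, params, life_table):
        cohort, _ = build_arm_cohorts(params)
        with pytest.raises(ValueError):
            run_cohort(cohort, params, life_table, horizon=0)

    def test_microsimulation_oracle_agrees_with_cohort_engine(
        self, params, life_table
    ):
        """Individual-level Monte Carlo (1e5 people, same matrices)
        reproduces the cohort model's mean cost and QALYs within 3 SE."""
        stratum = Stratum(count=1.0, sex="male", age=53, status="untreated")
        trace = run_cohort(CohortSpec("one", (stratum,)), params, life_table)
        mc_cost, mc_qaly, se_cost, se_qaly = microsimulate(
            stratum,
            params,
            life_table,
            n=100_000,
            horizon=20,
            discount_rate=0.03,
            seed=42,
        )
        assert abs(trace.total_cost - mc_cost) < 3 * se_cost
        assert abs(trace.total_qalys - mc_qaly) < 3 * se_qaly


class TestIncremental:
    def test_switcher_difference_equals_full_arm_difference(self, params, life_table):
        full = build_arm_cohorts(params, "all")
        mini = build_switcher_cohorts(params, "all")
        res = []
        for screen, comp in (full, mini):
            ts = run_cohort(screen, params, life_table)
            tc = run_cohort(comp, params, life_table)
            res.append(
                (ts.total_cost - tc.total_cost, ts.total_qalys - tc.total_qalys)
            )
        assert res[0][0] == pytest.approx(res[1][0], rel=1e-9)
        assert res[0][1] == pytest.approx(res[1][1], rel=1e-9)

    def test_identical_arms_tagged_undefined(self, params, life_table):
        cohort, _ = build_arm_cohorts(params)
        trace = run_cohort(cohort, params, life_table)
        res = incremental_results(trace, trace, None, "payer")
        assert res.tag == "undefined" and res.icer is None

    def test_icer_scales_with_joint_cost_rescaling(self, params, life_table):
        base = evaluate_incremental(params, life_table)
        doubled_costs = params.scaled_costs(
            {k: 2.0 for k in params.unit_costs}
        )
        scaled = evaluate_incremental(doubled_costs, life_table)
        assert scaled.delta_qalys == pytest.approx(base.delta_qalys, rel=1e-12)
        assert scaled.icer == pytest.approx(2.0 * base.icer, rel=1e-12)

    def test_mismatched_horizons_rejected(self, params, life_table):
        screen, comp = build_switcher_cohorts(params)
        t1 = run_cohort(screen, params, life_table, horizon=10)
        t2 = run_cohort(comp, params, life_table, horizon=20)
        with pytest.raises(ValueError):
            incremental_results(t1, t2, None, "payer")

    def test_short_term_component_included(self, params, life_table):
        scenario = build_baseline_scenario(params)
        ledgers = tuple(
            arm_cost_ledger(scenario, params, arm, "payer")
            for arm in ("screening", "no_screening")
        )
        screen, comp = build_switcher_cohorts(params)
        ts, tc = run_cohort(screen, params, life_table), run_cohort(
            comp, params, life_table
        )
        with_st = incremental_results(ts, tc, ledgers, "payer")
        without = incremental_results(ts, tc, None, "payer")
        assert with_st.delta_cost - without.delta_cost == pytest.approx(595_069)
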