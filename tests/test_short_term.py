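import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpscreen.short_term import (
    ArmVolumes,
    ScenarioVolumes,
    arm_cost_ledger,
    build_baseline_scenario,
    build_scenario,
    cost_per_identified_case,
)

# Published ledger line totals (SEK) for the baseline cascade.
PUBLISHED_LINES = [
    ("screening", "Fixed screening program cost", 165_343),
    ("screening", "BP test (dental care)", 236_925),
    ("screening", "BP test (primary care)", 120_988),
    ("screening", "ECG", 12_750),
    ("screening", "Lab tests", 40_800),
    ("screening", "Setting diagnosis", 133_280),
    ("screening", "Time use (dental care)", 162_000),
    ("screening", "Time use (primary care)", 194_880),
    ("screening", "Time use (BP test at home)", 656_320),
    ("screening", "Travel costs", 9_685),
    ("no_screening", "BP test (primary care)", 47_978),
    ("no_screening", "ECG", 4_575),
    ("no_screening", "Lab tests", 14_640),
    ("no_screening", "Setting diagnosis", 47_824),
    ("no_screening", "Time use (primary care)", 29_280),
    ("no_screening", "Travel costs", 1_586),
]


@pytest.fixture(scope="module")
def ledgers(params):
    scenario = build_baseline_scenario(params)
    return {
        (arm, persp): arm_cost_ledger(scenario, params, arm, persp)
        for arm in ("screening", "no_screening")
        for persp in ("payer", "societal")
    }


class TestBaselineLedger:
    @pytest.mark.parametrize("arm,item,total", PUBLISHED_LINES)
    def test_line_totals_reproduce_published_ledger(self, ledgers, arm, item, total):
        ledger = ledgers[(arm, "societal")]
        line = next(l for l in ledger.lines if l.item == item)
        assert line.total == pytest.approx(total, abs=1e-6)

    @pytest.mark.parametrize(
        "arm,persp,total",
        [
            ("screening", "payer", 710_086),
            ("no_screening", "payer", 115_017),
            ("screening", "societal", 1_732_971),
            ("no_screening", "societal", 145_883),
        ],
    )
    def test_grand_totals(self, ledgers, arm, persp, total):
        assert ledgers[(arm, persp)].total == pytest.approx(total, abs=1e-6)

    def test_baseline_volumes_back_derived(self, params):
        v = build_baseline_scenario(params)
        assert v.screening.ecg == 170 and v.no_screening.ecg == 61
        assert v.screening.phc_bp_visits == 812 and v.no_screening.phc_bp_visits == 322
        assert v.screening.hours_home == 4102
        assert v.screening.dental_bp_tests == 2025

    def test_admin_cost_stands_alone_with_zero_volumes(self, params):
        empty = ArmVolumes(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, admin=True)
        scenario = ScenarioVolumes(
            screening=empty,
            no_screening=dataclasses.replace(empty, admin=False),
        )
        ledger = arm_cost_ledger(scenario, params, "screening", "payer")
        assert ledger.total == pytest.approx(165_343)


class TestCostPerCase:
    def test_incremental_cost_per_case_both_perspectives(self, ledgers, params):
        cases = (params.identified_cases_screening,
                 params.identified_cases_comparator_true)
        payer = cost_per_identified_case(
            ledgers[("screening", "payer")], ledgers[("no_screening", "payer")], *cases
        )
        societal = cost_per_identified_case(
            ledgers[("screening", "societal")],
            ledgers[("no_screening", "societal")],
            *cases,
        )
        assert payer.delta_cases == 124
        assert payer.delta_cost == pytest.approx(595_069)
        assert round(payer.incremental_per_case) == 4_799
        assert round(societal.incremental_per_case) == 12_799
        # within-arm averages, payer perspective
        assert round(payer.screen_per_case) == 4_177
        assert round(payer.comp_per_case) == 2_500

    def test_equal_case_counts_tagged_undefined(self, ledgers):
        res = cost_per_identified_case(
            ledgers[("screening", "payer")], ledgers[("screening", "payer")], 170, 170
        )
        assert res.tag == "undefined" and res.incremental_per_case is None
        assert res.delta_cost == 0.0

    def test_unknown_arm_and_perspective_rejected(self, params):
        scenario = build_baseline_scenario(params)
        with pytest.raises(ValueError):
            scenario.arm("placebo")
        with pytest.raises(ValueError):
            arm_cost_ledger(scenario, params, "screening", "galactic")


class TestLedgerProperties:
    @given(cases=st.floats(min_value=0, max_value=500),
           comp=st.floats(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_additivity_and_perspective_monotonicity(self, params, cases, comp):
        """Totals equal the sum of lines; societal >= payer always."""
        scenario = build_scenario(params, screen_cases=cases, comp_diagnosed=comp)
        for arm in ("screening", "no_screening"):
            societal = arm_cost_ledger(scenario, params, arm, "societal")
            payer = arm_cost_ledger(scenario, params, arm, "payer")
            assert societal.total == pytest.approx(
                sum(l.total for l in societal.lines), rel=1e-12
            )
            assert societal.total >= payer.total

    def test_doubling_volumes_doubles_variable_lines(self, params):
        base = build_baseline_scenario(params)
        doubled = ScenarioVolumes(
            screening=base.screening.scaled(2.0),
            no_screening=base.no_screening.scaled(2.0),
        )
        lb = arm_cost_ledger(base, params, "screening", "societal")
        ld = arm_cost_ledger(doubled, params, "screening", "societal")
        admin = "Fixed screening program cost"
        for l_base, l_doub in zip(lb.lines, ld.lines):
            factor = 1.0 if l_base.item == admin else 2.0
            assert l_doub.total == pytest.approx(factor * l_base.total, rel=1e-12)
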