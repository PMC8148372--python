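import csv
import importlib.resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpscreen.risk_engine import (
    AMI_YEAR,
    DEAD,
    POST_AMI,
    POST_STROKE,
    STROKE_YEAR,
    LifeTable,
    RiskProfile,
    annual_event_probability,
    background_mortality,
    build_transition_matrix,
    framingham_risk,
    load_life_table,
)

from _oracles import chd_risk_am_form


def profile(age=53, sex="male", sbp=147, ratio=4.0, **kw):
    return RiskProfile(age=age, sex=sex, sbp=sbp, tc_hdl_ratio=ratio, **kw)


class TestFramingham:
    @pytest.mark.parametrize("sex,ratio", [("male", 4.0), ("female", 3.2)])
    @pytest.mark.parametrize("age", [40, 53, 64, 74])
    @pytest.mark.parametrize("years", [1.0, 10.0])
    def test_chd_matches_independent_am_parametrisation(self, sex, ratio, age, years):
        """The merged coefficient table equals the a/m published form."""
        p = profile(age=age, sex=sex, ratio=ratio)
        expected = chd_risk_am_form(
            age, 147, ratio, female=(sex == "female"), years=years
        )
        assert framingham_risk(p, "chd", years) == pytest.approx(expected, abs=2e-4)

    @given(
        age=st.floats(30, 90),
        sbp=st.floats(100, 200),
        ratio=st.floats(2.0, 8.0),
        sex=st.sampled_from(["male", "female"]),
        endpoint=st.sampled_from(["mi", "chd", "stroke"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_risks_are_probabilities(self, age, sbp, ratio, sex, endpoint):
        p = RiskProfile(age=age, sex=sex, sbp=sbp, tc_hdl_ratio=ratio)
        assert 0.0 <= framingham_risk(p, endpoint) <= 1.0

    @pytest.mark.parametrize("endpoint", ["mi", "chd", "stroke"])
    def test_treatment_lowers_risk_monotonically(self, endpoint):
        """p(SBP 147) > p(SBP 140) > p(SBP 131), all else equal."""
        risks = [
            framingham_risk(profile(sbp=s), endpoint) for s in (147, 140, 131)
        ]
        assert risks[0] > risks[1] > risks[2]

    @pytest.mark.parametrize("endpoint", ["mi", "chd", "stroke"])
    def test_risk_increases_with_age_within_validity(self, endpoint):
        risks = [framingham_risk(profile(age=a), endpoint) for a in (45, 55, 65, 74)]
        assert all(lo < hi for lo, hi in zip(risks, risks[1:]))

    def test_mi_risk_never_exceeds_chd_risk(self):
        for sex, ratio in (("male", 4.0), ("female", 3.2)):
            for age in (45, 53, 65, 74):
                p = profile(age=age, sex=sex, ratio=ratio)
                assert framingham_risk(p, "mi") <= framingham_risk(p, "chd")

    def test_age_outside_validity_clamped(self):
        assert framingham_risk(profile(age=90), "mi") == framingham_risk(
            profile(age=74), "mi"
        )

    def test_diabetic_profiles_rejected(self):
        with pytest.raises(ValueError, match="diabetic"):
            RiskProfile(age=53, sex="male", sbp=147, tc_hdl_ratio=4.0, diabetic=True)

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            annual_event_probability(profile(), "angina")


class TestLifeTable:
    def test_mortality_rises_with_age(self, life_table):
        for sex in ("male", "female"):
            assert life_table.q(80, sex) > life_table.q(50, sex)

    def test_terminal_age_is_absorbing(self, life_table):
        assert life_table.q(100, "male") == 1.0
        assert life_table.q(140, "male") == 1.0  # beyond the table

    def test_lookup_matches_fixture_file(self, life_table):
        ref = (
            importlib.resources.files("bpscreen")
            / "data"
            / "life_table_sweden_2017_synthetic.csv"
        )
        with importlib.resources.as_file(ref) as path, open(path) as fh:
            rows = {
                (int(r["age"]), r["sex"]): float(r["qx"]) for r in csv.DictReader(fh)
            }
        assert life_table.q(53, "male") == rows[(53, "male")]
        assert life_table.q(67, "female") == rows[(67, "female")]

    def test_invalid_tables_rejected(self):
        ages = np.arange(40, 101)
        bad = np.zeros(ages.size)  # final-age probability is not 1
        with pytest.raises(ValueError):
            LifeTable(ages=ages, qx={"male": bad})

    def test_background_mortality_is_table_lookup(self, life_table):
        assert background_mortality(60, "female", life_table) == life_table.q(
            60, "female"
        )


class TestTransitionMatrix:
    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("sbp", [131, 140, 147])
    def test_rows_stochastic_over_all_ages(self, params, life_table, sex, sbp):
        ratio = 4.0 if sex == "male" else 3.2
        for age in range(40, 101):
            m = build_transition_matrix(
                RiskProfile(age=age, sex=sex, sbp=sbp, tc_hdl_ratio=ratio),
                params,
                life_table,
            )
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(m >= 0)

    def test_dead_row_is_identity(self, params, life_table):
        m = build_transition_matrix(profile(), params, life_table)
        expected = np.zeros(6)
        expected[DEAD] = 1.0
        assert np.array_equal(m[DEAD], expected)

    def test_case_fatality_entries(self, params, life_table):
        m = build_transition_matrix(profile(sex="male"), params, life_table)
        assert m[AMI_YEAR, DEAD] == 0.144
        assert m[STROKE_YEAR, DEAD] == 0.102
        w = build_transition_matrix(
            profile(sex="female", ratio=3.2), params, life_table
        )
        assert w[AMI_YEAR, DEAD] == 0.173
        assert w[STROKE_YEAR, DEAD] == 0.144

    def test_post_event_mortality_adds_background(self, params, life_table):
        age = 60
        m = build_transition_matrix(profile(age=age), params, life_table)
        q = life_table.q(age, "male")
        assert m[POST_STROKE, DEAD] == pytest.approx(min(1.0, q + 0.074))
        assert m[POST_AMI, DEAD] == pytest.approx(min(1.0, q + 0.018))

    def test_no_recurrent_or_cross_track_transitions(self, params, life_table):
        m = build_transition_matrix(profile(), params, life_table)
        assert m[POST_AMI, AMI_YEAR] == m[POST_AMI, STROKE_YEAR] == 0.0
        assert m[POST_STROKE, AMI_YEAR] == m[POST_STROKE, STROKE_YEAR] == 0.0
        assert m[AMI_YEAR, STROKE_YEAR] == m[STROKE_YEAR, AMI_YEAR] == 0.0

    def test_treated_event_entries_never_exceed_untreated(self, params, life_table):
        for age in (45, 55, 65, 75):
            treated = build_transition_matrix(
                profile(age=age, sbp=140), params, life_table
            )
            untreated = build_transition_matrix(
                profile(age=age, sbp=147), params, life_table
            )
            assert treated[0, AMI_YEAR] <= untreated[0, AMI_YEAR]
            assert treated[0, STROKE_YEAR] <= untreated[0, STROKE_YEAR]

    def test_terminal_age_sends_everyone_to_dead(self, params, life_table):
        m = build_transition_matrix(profile(age=100), params, life_table)
        assert m[0, DEAD] == 1.0 and m[0, 0] == 0.0

    def test_overcommitted_event_probabilities_raise(self, params, life_table):
        from bpscreen.markov import _apply_risk_multipliers

        m = build_transition_matrix(profile(age=74), params, life_table)
        with pytest.raises(ValueError):
            _apply_risk_multipliers(m, {"ami": 500.0, "stroke": 500.0})
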