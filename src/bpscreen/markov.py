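"""20-year six-state Markov cohort model and incremental cost-effectiveness.

Each arm is a :class:`CohortSpec` of homogeneous strata (count, sex,
starting age, hypertension status).  Everyone starts Healthy; each annual
cycle applies the transition matrix built from the Framingham event risks
(at the stratum's blood-pressure level), background mortality at the
cohort's current age, case fatality and post-event added mortality.  State
costs and QALY weights accrue on start-of-cycle occupancy and both streams
are discounted at the annual rate (cycle 0 undiscounted).

The two arms differ only in how many detected hypertensives receive
treatment (lowering systolic BP from 147 to 140 mmHg) and in the annual
drug cost those strata accrue while alive; the model is linear in stratum
counts, so incremental results can equivalently be computed from the
"switcher" stratum alone (used by the sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .parameters import ParameterSet
from .risk_engine import (
    AMI_YEAR,
    DEAD,
    HEALTHY,
    POST_AMI,
    POST_STROKE,
    STROKE_YEAR,
    LifeTable,
    RiskProfile,
    build_transition_matrix,
)
from .short_term import CostLedger

__all__ = [
    "Stratum",
    "CohortSpec",
    "StateTrace",
    "CEResult",
    "run_cohort",
    "discounted_sum",
    "incremental_results",
    "build_arm_cohorts",
    "build_switcher_cohorts",
    "DEFAULT_START_AGE",
]

DEFAULT_START_AGE = 53.0  # cohort mean age 52.8, run as a point mass

_STATUS_SBP_FIELD = {
    "normotensive": "sbp_normotensive",
    "treated": "sbp_treated_hypertensive",
    "untreated": "sbp_untreated_hypertensive",
}


@dataclass(frozen=True)
class Stratum:
    count: float
    sex: str  # "male" | "female"
    age: float
    status: str  # "normotensive" | "treated" | "untreated"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("stratum count must be >= 0")
        if self.status not in _STATUS_SBP_FIELD:
            raise ValueError(f"unknown status: {self.status!r}")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class CohortSpec:
    label: str
    strata: tuple[Stratum, ...]

    @property
    def size(self) -> float:
        return sum(s.count for s in self.strata)

    def subset(self, sex: str) -> "CohortSpec":
        return CohortSpec(self.label, tuple(s for s in self.strata if s.sex == sex))


@dataclass
class StateTrace:
    """Occupancy and reward streams induced by a cohort over the horizon."""

    label: str
    strata: tuple[Stratum, ...]
    occupancy: np.ndarray  # (n_strata, horizon+1, 6), persons
    cost_stream: np.ndarray  # (horizon,), undiscounted SEK per cycle
    qaly_stream: np.ndarray  # (horizon,), undiscounted QALYs per cycle
    horizon: int
    discount_rate: float

    @property
    def total_cost(self) -> float:
        return discounted_sum(self.cost_stream, self.discount_rate)

    @property
    def total_qalys(self) -> float:
        return discounted_sum(self.qaly_stream, self.discount_rate)

    @property
    def life_years(self) -> float:
        """Undiscounted person-years alive over the horizon."""
        alive = self.occupancy[:, : self.horizon, :DEAD].sum(axis=(0, 2))
        return float(alive.sum())

    def occupancy_total(self) -> np.ndarray:
        """(horizon+1, 6) occupancy summed over strata."""
        return self.occupancy.sum(axis=0)


def discounted_sum(stream: Sequence[float], rate: float) -> float:
    """Present value of a per-cycle stream, cycle 0 undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    arr = np.asarray(stream, dtype=float)
    if arr.size == 0:
        return 0.0
    t = np.arange(arr.size)
    return float(np.sum(arr / (1.0 + rate) ** t))


def _apply_risk_multipliers(m: np.ndarray, mult: Mapping[str, float]) -> np.ndarray:
    """Scale Healthy->event entries, rebalancing the stay probability."""
    m = m.copy()
    m[HEALTHY, AMI_YEAR] = min(1.0, m[HEALTHY, AMI_YEAR] * mult.get("ami", 1.0))
    m[HEALTHY, STROKE_YEAR] = min(1.0, m[HEALTHY, STROKE_YEAR] * mult.get("stroke", 1.0))
    exit_p = m[HEALTHY, AMI_YEAR] + m[HEALTHY, STROKE_YEAR] + m[HEALTHY, DEAD]
    if exit_p > 1.0:
        raise ValueError("risk multipliers push Healthy exits above 1")
    m[HEALTHY, HEALTHY] = 1.0 - exit_p
    return m


def _reward_vectors(params: ParameterSet, status: str) -> tuple[np.ndarray, np.ndarray]:
    uc = params.unit_costs
    dec = params.qaly_decrements
    costs = np.array(
        [
            0.0,
            uc["ami_first_year"],
            uc["stroke_first_year"],
            uc["ami_post_annual"],
            uc["stroke_post_annual"],
            0.0,
        ]
    )
    qalys = np.array(
        [
            1.0,
            1.0 - dec["ami_year"],
            1.0 - dec["stroke_year"],
            1.0 - dec["post_ami"],
            1.0 - dec["post_stroke"],
            0.0,
        ]
    )
    if status == "treated":
        # annual drug cost accrues in every alive state
        drug = uc["drug_annual"]
        costs = costs + np.array([drug, drug, drug, drug, drug, 0.0])
    return costs, qalys


def run_cohort(
    cohort: CohortSpec,
    params: ParameterSet,
    table: LifeTable,
    *,
    horizon: int | None = None,
    discount_rate: float | None = None,
    risk_multipliers: Mapping[str, float] | None = None,
) -> StateTrace:
    """Propagate every stratum through the model and accumulate rewards."""
    horizon = params.horizon_years if horizon is None else int(horizon)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rate = params.discount_rate if discount_rate is None else discount_rate
    if rate < 0:
        raise ValueError("discount rate must be >= 0")

    n_s = len(cohort.strata)
    occ = np.zeros((n_s, horizon + 1, 6))
    cost_stream = np.zeros(horizon)
    qaly_stream = np.zeros(horizon)

    sex_key = {"male": "men", "female": "women"}
    for i, stratum in enumerate(cohort.strata):
        state = np.zeros(6)
        state[HEALTHY] = stratum.count
        occ[i, 0] = state
        costs_vec, qalys_vec = _reward_vectors(params, stratum.status)
        sbp = getattr(params, _STATUS_SBP_FIELD[stratum.status])
        ratio = params.tc_hdl_ratio[sex_key[stratum.sex]]
        for t in range(horizon):
            cost_stream[t] += state @ costs_vec
            qaly_stream[t] += state @ qalys_vec
            profile = RiskProfile(
                age=min(stratum.age + t, 100.0),
                sex=stratum.sex,
                sbp=sbp,
                tc_hdl_ratio=ratio,
            )
            m = build_transition_matrix(profile, params, table)
            if risk_multipliers:
                m = _apply_risk_multipliers(m, risk_multipliers)
            state = state @ m
            occ[i, t + 1] = state

    if params.half_cycle_correction:
        # average adjacent start-of-cycle rewards (trapezoid over occupancy)
        full_cost = np.zeros(horizon + 1)
        full_qaly = np.zeros(horizon + 1)
        for i, stratum in enumerate(cohort.strata):
            costs_vec, qalys_vec = _reward_vectors(params, stratum.status)
            full_cost += occ[i] @ costs_vec
            full_qaly += occ[i] @ qalys_vec
        cost_stream = 0.5 * (full_cost[:-1] + full_cost[1:])
        qaly_stream = 0.5 * (full_qaly[:-1] + full_qaly[1:])

    return StateTrace(
        label=cohort.label,
        strata=cohort.strata,
        occupancy=occ,
        cost_stream=cost_stream,
        qaly_stream=qaly_stream,
        horizon=horizon,
        discount_rate=rate,
    )


# ---------------------------------------------------------------------- #
# Arm construction


def _sex_split(params: ParameterSet, subgroup: str) -> dict[str, float]:
    if subgroup == "all":
        male = params.cohort_men / params.cohort_size
    elif subgroup == "men":
        male = 1.0
    elif subgroup == "women":
        male = 0.0
    else:
        raise ValueError(f"unknown subgroup: {subgroup!r}")
    return {"male": male, "female": 1.0 - male}


def build_arm_cohorts(
    params: ParameterSet,
    subgroup: str = "all",
    *,
    start_age: float = DEFAULT_START_AGE,
    screen_cases: float | None = None,
    comp_true: float | None = None,
) -> tuple[CohortSpec, CohortSpec]:
    """Full screening and no-screening cohorts for a subgroup.

    Detected hypertensives are split across sexes proportionally to the
    cohort's sex composition (sex-specific detection is not reported).
    Subgroup cohorts keep the full cohort size with a single sex, matching
    the published "assuming equal cohort size" sub-analysis.
    """
    cases = params.identified_cases_screening if screen_cases is None else screen_cases
    true_comp = (
        params.identified_cases_comparator_true if comp_true is None else comp_true
    )
    if not 0 <= true_comp <= cases <= params.cohort_size:
        raise ValueError("need 0 <= comparator true cases <= screen cases <= cohort")
    split = _sex_split(params, subgroup)

    def strata(treated: float, untreated: float) -> tuple[Stratum, ...]:
        normo = params.cohort_size - treated - untreated
        out = []
        for sex, frac in split.items():
            if frac == 0.0:
                continue
            for status, count in (
                ("treated", treated * frac),
                ("untreated", untreated * frac),
                ("normotensive", normo * frac),
            ):
                if count > 0:
                    out.append(Stratum(count=count, sex=sex, age=start_age, status=status))
        return tuple(out)

    screening = CohortSpec("screening", strata(treated=cases, untreated=0.0))
    comparator = CohortSpec(
        "no_screening", strata(treated=true_comp, untreated=cases - true_comp)
    )
    return screening, comparator


def build_switcher_cohorts(
    params: ParameterSet,
    subgroup: str = "all",
    *,
    start_age: float = DEFAULT_START_AGE,
    screen_cases: float | None = None,
    comp_true: float | None = None,
) -> tuple[CohortSpec, CohortSpec]:
    """Minimal cohorts holding only the people who differ between arms.

    The model is linear in stratum counts and identical strata cancel, so
    the arm difference equals the difference between these "switcher"
    cohorts (treated under screening, untreated otherwise).
    """
    cases = params.identified_cases_screening if screen_cases is None else screen_cases
    true_comp = (
        params.identified_cases_comparator_true if comp_true is None else comp_true
    )
    switchers = cases - true_comp
    split = _sex_split(params, subgroup)
    treat = tuple(
        Stratum(count=switchers * f, sex=sex, age=start_age, status="treated")
        for sex, f in split.items()
        if f > 0
    )
    untreat = tuple(
        Stratum(count=switchers * f, sex=sex, age=start_age, status="untreated")
        for sex, f in split.items()
        if f > 0
    )
    return CohortSpec("screening", treat), CohortSpec("no_screening", untreat)


# ---------------------------------------------------------------------- #
# Incremental results


@dataclass(frozen=True)
class CEResult:
    perspective: str
    subgroup: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    tag: str  # "normal" | "dominant" | "dominated" | "undefined"
    delta_cost_short_term: float = 0.0
    delta_cost_long_term: float = 0.0

    @property
    def delta_cost_eur(self) -> float:
        from .parameters import SEK_PER_EUR

        return self.delta_cost / SEK_PER_EUR


def _dominance(delta_cost: float, delta_qalys: float) -> str:
    if delta_qalys == 0.0 and delta_cost == 0.0:
        return "undefined"
    if delta_qalys > 0.0 and delta_cost > 0.0:
        return "normal"
    if delta_qalys >= 0.0 and delta_cost <= 0.0:
        return "dominant"
    if delta_qalys <= 0.0 and delta_cost >= 0.0:
        return "dominated"
    return "normal"  # cheaper and worse: a valid (south-west) trade-off


def incremental_results(
    screen: StateTrace,
    comp: StateTrace,
    short_term_ledgers: tuple[CostLedger, CostLedger] | None,
    perspective: str,
    subgroup: str = "all",
) -> CEResult:
    """Incremental cost, QALYs, ICER and dominance classification.

    ``short_term_ledgers`` is the (screening, no-screening) pair for the
    chosen perspective; its difference is added to the long-term
    (health-care) cost difference.  Pass ``None`` to compare the long-term
    model alone.
    """
    if screen.horizon != comp.horizon:
        raise ValueError("traces have different horizons")
    if screen.discount_rate != comp.discount_rate:
        raise ValueError("traces have different discount rates")
    delta_lt = screen.total_cost - comp.total_cost
    delta_st = 0.0
    if short_term_ledgers is not None:
        s_ledger, c_ledger = short_term_ledgers
        if {s_ledger.perspective, c_ledger.perspective} != {perspective}:
            raise ValueError("ledger perspectives do not match the requested one")
        delta_st = s_ledger.total - c_ledger.total
    delta_cost = delta_lt + delta_st
    delta_q = screen.total_qalys - comp.total_qalys
    tag = _dominance(delta_cost, delta_q)
    icer = delta_cost / delta_q if tag in ("normal",) and delta_q != 0 else None
    return CEResult(
        perspective=perspective,
        subgroup=subgroup,
        delta_cost=delta_cost,
        delta_qalys=delta_q,
        icer=icer,
        tag=tag,
        delta_cost_short_term=delta_st,
        delta_cost_long_term=delta_lt,
    )
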