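"""Short-term model: screening-cascade cost ledgers and cost per detected case.

The short-term window runs from screening until a hypertension diagnosis is
established.  Each arm's activity volumes (tests, visits, patient hours,
travel trips) are multiplied by unit costs into an itemised ledger, split
into health/dental-care lines (payer perspective) and non-health-care lines
— patient time and travel — which are added for the societal perspective.

Volumes not printed in the source material (primary-care visits, patient
hours, trips) are back-derived once from the published line totals divided
by the unit costs and frozen here as exact rational per-case constants, so
the packaged baseline reproduces the published ledger to the öre.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "ArmVolumes",
    "ScenarioVolumes",
    "CostLine",
    "CostLedger",
    "build_baseline_scenario",
    "build_scenario",
    "arm_cost_ledger",
    "cost_per_identified_case",
    "CasePerCostResult",
    "ledger_frame",
]

# Back-derived per-diagnosed-case cascade constants for the screening arm
# (numerator over the 170 baseline cases) and per-diagnosed constants for
# the opportunistic comparator (over its 61 diagnoses).
_SCREEN_PHC_VISITS = Fraction(812, 170)
_SCREEN_HOME_HOURS = Fraction(4102, 170)
_SCREEN_TRIPS = Fraction(1490, 170)
_PHC_HOURS_PER_VISIT = Fraction(3, 2)  # 1.5 h per primary-care visit
_DENTAL_HOURS_PER_SCREENEE = Fraction(1, 2)
_COMP_PHC_VISITS = Fraction(322, 61)
_COMP_PHC_HOURS = Fraction(3, 1)
_COMP_TRIPS = Fraction(4, 1)


@dataclass(frozen=True)
class ArmVolumes:
    """Counts of every costed activity in one arm."""

    dental_bp_tests: float
    diagnosed: float
    phc_bp_visits: float
    ecg: float
    lab: float
    diagnosis: float
    hours_dental: float
    hours_phc: float
    hours_home: float
    trips: float
    admin: bool

    def __post_init__(self) -> None:
        for name in (
            "dental_bp_tests", "diagnosed", "phc_bp_visits", "ecg", "lab",
            "diagnosis", "hours_dental", "hours_phc", "hours_home", "trips",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, k: float) -> "ArmVolumes":
        """All variable volumes multiplied by ``k`` (fixed admin flag kept)."""
        return ArmVolumes(
            dental_bp_tests=self.dental_bp_tests * k,
            diagnosed=self.diagnosed * k,
            phc_bp_visits=self.phc_bp_visits * k,
            ecg=self.ecg * k,
            lab=self.lab * k,
            diagnosis=self.diagnosis * k,
            hours_dental=self.hours_dental * k,
            hours_phc=self.hours_phc * k,
            hours_home=self.hours_home * k,
            trips=self.trips * k,
            admin=self.admin,
        )


@dataclass(frozen=True)
class ScenarioVolumes:
    screening: ArmVolumes
    no_screening: ArmVolumes

    def __post_init__(self) -> None:
        if self.no_screening.dental_bp_tests != 0 or self.no_screening.admin:
            raise ValueError(
                "the no-screening arm has no dental BP tests and no fixed "
                "administration cost"
            )

    def arm(self, name: str) -> ArmVolumes:
        try:
            return {"screening": self.screening, "no_screening": self.no_screening}[name]
        except KeyError:
            raise ValueError(f"unknown arm: {name!r}") from None


def build_scenario(
    params: ParameterSet,
    *,
    screen_cases: float | None = None,
    comp_diagnosed: float | None = None,
) -> ScenarioVolumes:
    """Cascade volumes for given detected-case counts.

    Diagnosed-driven volumes (work-ups, primary-care visits, home
    measurement, travel) scale linearly with the case counts; the dental
    screening step itself covers the whole cohort regardless.
    """
    cases = params.identified_cases_screening if screen_cases is None else screen_cases
    diag = params.comparator_total_diagnosed if comp_diagnosed is None else comp_diagnosed
    n = params.cohort_size
    screening = ArmVolumes(
        dental_bp_tests=n,
        diagnosed=cases,
        phc_bp_visits=float(cases * _SCREEN_PHC_VISITS),
        ecg=cases,
        lab=cases,
        diagnosis=cases,
        hours_dental=float(n * _DENTAL_HOURS_PER_SCREENEE),
        hours_phc=float(cases * _SCREEN_PHC_VISITS * _PHC_HOURS_PER_VISIT),
        hours_home=float(cases * _SCREEN_HOME_HOURS),
        trips=float(cases * _SCREEN_TRIPS),
        admin=True,
    )
    comparator = ArmVolumes(
        dental_bp_tests=0.0,
        diagnosed=diag,
        phc_bp_visits=float(diag * _COMP_PHC_VISITS),
        ecg=diag,
        lab=diag,
        diagnosis=diag,
        hours_dental=0.0,
        hours_phc=float(diag * _COMP_PHC_HOURS),
        hours_home=0.0,
        trips=float(diag * _COMP_TRIPS),
        admin=False,
    )
    return ScenarioVolumes(screening=screening, no_screening=comparator)


def build_baseline_scenario(params: ParameterSet) -> ScenarioVolumes:
    """The packaged baseline cascade (170 screen-detected, 61 comparator)."""
    return build_scenario(params)


# ---------------------------------------------------------------------- #
# Ledgers


@dataclass(frozen=True)
class CostLine:
    item: str
    section: str  # "health" | "non_health"
    volume: float
    unit_cost: float

    @property
    def total(self) -> float:
        return self.volume * self.unit_cost


@dataclass(frozen=True)
class CostLedger:
    arm: str
    perspective: str  # "payer" | "societal"
    lines: tuple[CostLine, ...]

    @property
    def subtotal_health(self) -> float:
        return sum(l.total for l in self.lines if l.section == "health")

    @property
    def subtotal_non_health(self) -> float:
        return sum(l.total for l in self.lines if l.section == "non_health")

    @property
    def total(self) -> float:
        if self.perspective == "payer":
            return self.subtotal_health
        return self.subtotal_health + self.subtotal_non_health


def arm_cost_ledger(
    scenario: ScenarioVolumes,
    params: ParameterSet,
    arm: str,
    perspective: str,
) -> CostLedger:
    """Itemised cost ledger for one arm under one perspective."""
    if perspective not in ("payer", "societal"):
        raise ValueError(f"unknown perspective: {perspective!r}")
    v = scenario.arm(arm)
    uc = params.unit_costs
    lines: list[CostLine] = []
    if v.admin:
        lines.append(CostLine("Fixed screening program cost", "health", 1.0, uc["screening_admin"]))
    if v.dental_bp_tests:
        lines.append(CostLine("BP test (dental care)", "health", v.dental_bp_tests, uc["dental_bp_test"]))
    lines.append(CostLine("BP test (primary care)", "health", v.phc_bp_visits, uc["phc_bp_test"]))
    lines.append(CostLine("ECG", "health", v.ecg, uc["ecg"]))
    lines.append(CostLine("Lab tests", "health", v.lab, uc["lab"]))
    lines.append(CostLine("Setting diagnosis", "health", v.diagnosis, uc["diagnosis"]))
    if perspective == "societal":
        lines.append(CostLine("Time use (dental care)", "non_health", v.hours_dental, uc["patient_hour"]))
        lines.append(CostLine("Time use (primary care)", "non_health", v.hours_phc, uc["patient_hour"]))
        lines.append(CostLine("Time use (BP test at home)", "non_health", v.hours_home, uc["patient_hour"]))
        lines.append(CostLine("Travel costs", "non_health", v.trips, uc["travel_trip"]))
    return CostLedger(arm=arm, perspective=perspective, lines=tuple(lines))


@dataclass(frozen=True)
class CasePerCostResult:
    """Incremental and within-arm cost per identified hypertension case."""

    perspective: str
    delta_cost: float
    delta_cases: float
    incremental_per_case: float | None  # None when the ICER is undefined
    screen_per_case: float | None
    comp_per_case: float | None
    tag: str  # "normal" | "undefined"


def cost_per_identified_case(
    screen: CostLedger,
    comp: CostLedger,
    cases_screen: float,
    cases_comp: float,
) -> CasePerCostResult:
    """(ΔSEK)/(Δ true-positive cases) plus within-arm average costs.

    Equal case counts yield a tagged undefined result rather than an
    exception: the ratio has no meaning when the outcome difference is zero.
    """
    if screen.perspective != comp.perspective:
        raise ValueError("ledgers must share a perspective")
    delta_cost = screen.total - comp.total
    delta_cases = cases_screen - cases_comp
    if delta_cases == 0:
        tag, per_case = "undefined", None
    else:
        tag, per_case = "normal", delta_cost / delta_cases
    return CasePerCostResult(
        perspective=screen.perspective,
        delta_cost=delta_cost,
        delta_cases=delta_cases,
        incremental_per_case=per_case,
        screen_per_case=screen.total / cases_screen if cases_screen else None,
        comp_per_case=comp.total / cases_comp if cases_comp else None,
        tag=tag,
    )


def ledger_frame(ledgers: Iterable[CostLedger]) -> pd.DataFrame:
    """One row per line item across ledgers, ready for CSV export."""
    rows = []
    for ledger in ledgers:
        for line in ledger.lines:
            rows.append(
                {
                    "arm": ledger.arm,
                    "perspective": ledger.perspective,
                    "section": line.section,
                    "item": line.item,
                    "volume": line.volume,
                    "unit_cost": line.unit_cost,
                    "total_sek": line.total,
                }
            )
    return pd.DataFrame(rows)
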