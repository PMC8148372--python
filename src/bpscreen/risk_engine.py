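"""Annual transition probabilities for the cardiovascular Markov model.

Three ingredients feed the six-state transition matrix:

* first-event risks of myocardial infarction and stroke from the
  Framingham parametric (accelerated-failure-time / Weibull) risk
  functions of Anderson, Odell, Wilson & Kannel (1991), embedded as
  published constants and evaluated as one-year risks;
* background all-cause mortality from a bundled sex-specific life table
  (a synthetic approximation of the Swedish 2017 national tables, see
  ``data/life_table_sweden_2017_synthetic.csv``);
* first-year case fatality and chronic added mortality after an event.

The states are Healthy, AMI-year, Stroke-year, Post-AMI, Post-Stroke and
Dead.  Event-year states are tunnel states: occupied for exactly one cycle,
leaving either to Dead (case fatality) or to the chronic post-event state.
Recurrent and cross-track events are excluded by design (a person who has
had an AMI can no longer have a modelled stroke, and vice versa).
"""

from __future__ import annotations

import functools
import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "HEALTHY",
    "AMI_YEAR",
    "STROKE_YEAR",
    "POST_AMI",
    "POST_STROKE",
    "DEAD",
    "RiskProfile",
    "LifeTable",
    "load_life_table",
    "annual_event_probability",
    "framingham_risk",
    "background_mortality",
    "build_transition_matrix",
    "NormalizationError",
]

STATES = ("healthy", "ami_year", "stroke_year", "post_ami", "post_stroke", "dead")
HEALTHY, AMI_YEAR, STROKE_YEAR, POST_AMI, POST_STROKE, DEAD = range(6)


class NormalizationError(ValueError):
    """Competing exit probabilities from a state exceed 1 (bad inputs)."""


@dataclass(frozen=True)
class RiskProfile:
    """Risk-factor profile for the Framingham equations.

    The evaluated population excludes diabetics (study exclusion criterion),
    so ``diabetic`` is pinned false; smoking prevalence and LVH status are
    not reported and default to false.
    """

    age: float
    sex: str  # "male" | "female"
    sbp: float
    tc_hdl_ratio: float
    smoker: bool = False
    diabetic: bool = field(default=False)
    lvh: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 30.0 <= self.age <= 100.0:
            raise ValueError(f"age {self.age} outside [30, 100]")
        if not 80.0 <= self.sbp <= 250.0:
            raise ValueError(f"SBP {self.sbp} outside [80, 250]")
        if self.tc_hdl_ratio <= 0:
            raise ValueError("TC/HDL ratio must be positive")
        if self.diabetic:
            raise ValueError("diabetic profiles are outside the modelled population")


# ---------------------------------------------------------------------- #
# Framingham parametric risk functions (Anderson et al. 1991).
#
# P(event within t years) = 1 - exp(-exp(u)),   u = (ln t - mu) / sigma,
# with mu a linear predictor in the transformed risk factors and
# sigma = exp(theta0 + theta1 * mu).  Coefficient order in `beta`:
#   const, female, ln(age), female*ln(age), female*ln(age)^2,
#   ln(SBP), smoker, ln(TC/HDL), diabetic, diabetic*female, LVH
#
# The CHD row is equivalent to the equation's alternative published
# parametrisation (a/m form with mu = 4.4181 + m and
# sigma = exp(-0.3155 - 0.2784 m)), which pins the merged constants below.
# The MI endpoint shares the coronary endpoint's Weibull dispersion
# (theta), applied to its own linear predictor; the stroke endpoint has a
# constant dispersion and no lipid term.
_ANDERSON_1991 = {
    "mi": {
        "beta": (
            11.4712, 10.5109, -0.7965, -5.4216, 0.7101,
            -0.6623, -0.2675, -0.4277, -0.1534, -0.1165, -0.1588,
        ),
        "theta": (0.9145, -0.2784),
    },
    "chd": {
        "beta": (
            15.5305, 28.4441, -1.4792, -14.4588, 1.8515,
            -0.9119, -0.2767, -0.7181, -0.1759, -0.1999, -0.5865,
        ),
        "theta": (0.9145, -0.2784),
    },
    "stroke": {
        "beta": (
            26.5116, 0.2019, -2.3741, 0.0, 0.0,
            -2.4643, -0.3914, 0.0, -0.3087, -0.2627, -0.2355,
        ),
        "theta": (-0.4312, 0.0),
    },
}

_AGE_VALID = (30.0, 74.0)  # published validity range of the equations


@functools.lru_cache(maxsize=65536)
def framingham_risk(profile: RiskProfile, endpoint: str, years: float = 1.0) -> float:
    """Probability of a first event within ``years`` for the given profile.

    Ages outside the published validity range are clamped to it (with a
    debug log): the cohort ages past 74 during a 20-30 year horizon and the
    equations are used at their boundary rather than extrapolated.
    """
    if endpoint not in _ANDERSON_1991:
        raise ValueError(f"unknown endpoint: {endpoint}")
    age = min(max(profile.age, _AGE_VALID[0]), _AGE_VALID[1])
    if age != profile.age:
        logger.debug("age %.1f clamped to %.1f for %s risk", profile.age, age, endpoint)
    female = 1.0 if profile.sex == "female" else 0.0
    la = math.log(age)
    x = (
        1.0,
        female,
        la,
        female * la,
        female * la * la,
        math.log(profile.sbp),
        1.0 if profile.smoker else 0.0,
        math.log(profile.tc_hdl_ratio),
        0.0,  # diabetic (excluded population)
        0.0,
        1.0 if profile.lvh else 0.0,
    )
    spec = _ANDERSON_1991[endpoint]
    mu = sum(b * xi for b, xi in zip(spec["beta"], x))
    theta0, theta1 = spec["theta"]
    sigma = math.exp(theta0 + theta1 * mu)
    u = (math.log(years) - mu) / sigma
    return 1.0 - math.exp(-math.exp(u))


def annual_event_probability(profile: RiskProfile, event: str, *, endpoint: str | None = None) -> float:
    """One-year first-event probability for ``event`` in {"ami", "stroke"}.

    ``endpoint`` selects the Framingham equation backing the AMI state
    ("mi", the default, or the broader "chd" endpoint).
    """
    if event == "ami":
        return framingham_risk(profile, endpoint or "mi", years=1.0)
    if event == "stroke":
        return framingham_risk(profile, "stroke", years=1.0)
    raise ValueError(f"unknown event: {event}")


# ---------------------------------------------------------------------- #
# Life table


@dataclass(frozen=True)
class LifeTable:
    """Sex- and age-indexed annual all-cause death probabilities."""

    ages: np.ndarray
    qx: dict[str, np.ndarray]  # sex -> probabilities aligned with `ages`

    def __post_init__(self) -> None:
        for sex, q in self.qx.items():
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"life-table probabilities outside [0,1] for {sex}")
            if q[-1] != 1.0:
                raise ValueError("final-age death probability must be 1")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: float, sex: str) -> float:
        if sex not in self.qx:
            raise KeyError(f"sex {sex!r} not in life table")
        if age > self.ages[-1]:
            return 1.0
        if age < self.ages[0]:
            raise ValueError(f"age {age} below life-table range")
        idx = int(np.searchsorted(self.ages, int(age)))
        return float(self.qx[sex][idx])


def load_life_table(path=None) -> LifeTable:
    """Read a life table from a 3-column CSV (age, sex, qx).

    With no argument, loads the bundled synthetic Swedish-2017
    approximation.
    """
    if path is None:
        path = (
            importlib.resources.files("bpscreen")
            / "data"
            / "life_table_sweden_2017_synthetic.csv"
        )
        with importlib.resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    expected = {"age", "sex", "qx"}
    if set(df.columns) != expected:
        raise ValueError(f"life-table CSV must have columns {sorted(expected)}")
    df = df.sort_values(["sex", "age"])
    ages = np.sort(df["age"].unique())
    qx = {}
    for sex, g in df.groupby("sex"):
        if not np.array_equal(g["age"].to_numpy(), ages):
            raise ValueError("life-table ages differ between sexes")
        qx[str(sex)] = g["qx"].to_numpy(dtype=float)
    return LifeTable(ages=ages, qx=qx)


def background_mortality(age: float, sex: str, table: LifeTable) -> float:
    """Annual all-cause death probability from the life table."""
    return table.q(age, sex)


# ---------------------------------------------------------------------- #
# Transition matrix


def build_transition_matrix(
    profile: RiskProfile,
    params: ParameterSet,
    table: LifeTable,
    *,
    at_risk: bool = True,
) -> np.ndarray:
    """Row-stochastic 6x6 annual transition matrix for one profile.

    ``at_risk=False`` zeroes the Framingham event risks (used for strata
    whose event risk the analysis does not model differently, and in
    degenerate test scenarios).
    """
    sex_key = "men" if profile.sex == "male" else "women"
    q = background_mortality(profile.age, profile.sex, table)
    if at_risk:
        p_ami = annual_event_probability(profile, "ami", endpoint=params.mi_endpoint)
        p_stroke = annual_event_probability(profile, "stroke")
    else:
        p_ami = p_stroke = 0.0

    if p_ami + p_stroke > 1.0:
        raise NormalizationError(
            f"event probabilities from Healthy sum to {p_ami + p_stroke:.4f} > 1"
        )
    # competing risks: background death takes priority, survivors face the
    # event risks — keeps the row stochastic up to the terminal age (q = 1)
    p_ami *= 1.0 - q
    p_stroke *= 1.0 - q
    exit_healthy = p_ami + p_stroke + q

    cf_ami = params.case_fatality_365d["ami"][sex_key]
    cf_stroke = params.case_fatality_365d["stroke"][sex_key]
    add_ami = params.added_mortality["post_ami"][sex_key]
    add_stroke = params.added_mortality["post_stroke"][sex_key]

    m = np.zeros((6, 6))
    m[HEALTHY, AMI_YEAR] = p_ami
    m[HEALTHY, STROKE_YEAR] = p_stroke
    m[HEALTHY, DEAD] = q
    m[HEALTHY, HEALTHY] = 1.0 - exit_healthy

    m[AMI_YEAR, DEAD] = cf_ami
    m[AMI_YEAR, POST_AMI] = 1.0 - cf_ami
    m[STROKE_YEAR, DEAD] = cf_stroke
    m[STROKE_YEAR, POST_STROKE] = 1.0 - cf_stroke

    d_pa = min(1.0, q + add_ami)
    m[POST_AMI, DEAD] = d_pa
    m[POST_AMI, POST_AMI] = 1.0 - d_pa
    d_ps = min(1.0, q + add_stroke)
    m[POST_STROKE, DEAD] = d_ps
    m[POST_STROKE, POST_STROKE] = 1.0 - d_ps

    m[DEAD, DEAD] = 1.0
    return m
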