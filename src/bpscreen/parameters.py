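"""Typed registry of model inputs and elicitation of PSA sampling distributions.

All monetary values are held internally in 2019 SEK; conversion to EUR
(1 EUR = 10.3 SEK) happens only at reporting time.  The packaged default
configuration (``data/table1_baseline.yaml``) carries the base-case unit
costs, transition inputs, QALY-weight decrements and modelling assumptions
of the screening evaluation, and every field can be overridden from a YAML
or JSON document with the same keys.

Point values come with uncertainty ranges expressed as "±20%" style relative
intervals (or an explicit standard error).  ``elicit_distribution`` turns a
(point, range, family) triple into a concrete sampling distribution by
moment matching, interpreting a ±r relative range as a central 95% interval
(sd = r·mean/1.96), the conventional elicitation in cost-effectiveness
practice when only a range is published.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

SEK_PER_EUR = 10.3

__all__ = [
    "ParameterSet",
    "DistributionSpec",
    "load_parameters",
    "default_parameters",
    "elicit_distribution",
    "ConfigurationError",
    "ValidationError",
    "ElicitationError",
    "SEK_PER_EUR",
]


class ConfigurationError(ValueError):
    """A required field is missing or the document cannot be parsed."""


class ValidationError(ValueError):
    """A field value violates its admissible range."""


class ElicitationError(ValueError):
    """A requested distribution cannot support the given point value."""


# Unit-cost items, SEK (2019).  Keys are stable identifiers used by the
# short-term ledger and the PSA.
UNIT_COST_KEYS = (
    "dental_bp_test",
    "phc_bp_test",
    "ecg",
    "lab",
    "diagnosis",
    "screening_admin",
    "ami_first_year",
    "ami_post_annual",
    "stroke_first_year",
    "stroke_post_annual",
    "drug_annual",
    "patient_hour",
    "travel_trip",
)


@dataclass
class ParameterSet:
    """Every model input: cohort, costs, transitions, utilities, assumptions.

    Probabilities are annual unless suffixed ``_365d`` (first-year case
    fatality).  ``added_mortality`` is the extra annual death probability in
    the chronic post-event states, added to background mortality.
    """

    cohort_size: int = 2025
    cohort_men: int = 930
    cohort_women: int = 1095
    discount_rate: float = 0.03
    horizon_years: int = 20
    unit_costs: dict[str, float] = field(default_factory=dict)
    case_fatality_365d: dict[str, dict[str, float]] = field(default_factory=dict)
    added_mortality: dict[str, dict[str, float]] = field(default_factory=dict)
    qaly_decrements: dict[str, float] = field(default_factory=dict)
    sbp_untreated_hypertensive: float = 147.0
    sbp_treated_hypertensive: float = 140.0
    sbp_normotensive: float = 131.0
    tc_hdl_ratio: dict[str, float] = field(default_factory=dict)
    identified_cases_screening: float = 170.0
    identified_cases_se: float = 17.0
    identified_cases_comparator_true: float = 46.0
    comparator_false_positives: float = 15.0
    comparator_total_diagnosed: float = 61.0
    sek_per_eur: float = SEK_PER_EUR
    mi_endpoint: str = "mi"  # Framingham endpoint for the AMI state: "mi" or "chd"
    half_cycle_correction: bool = False

    # ------------------------------------------------------------------ #

    def validate(self) -> "ParameterSet":
        if self.cohort_men + self.cohort_women != self.cohort_size:
            raise ValidationError(
                "cohort_men + cohort_women must equal cohort_size "
                f"({self.cohort_men} + {self.cohort_women} != {self.cohort_size})"
            )
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValidationError("discount_rate must lie in [0, 1]")
        for key in UNIT_COST_KEYS:
            if key not in self.unit_costs:
                raise ConfigurationError(f"missing unit cost: unit_costs.{key}")
            if self.unit_costs[key] < 0:
                raise ValidationError(f"unit_costs.{key} must be >= 0")
        for group, name in (
            (self.case_fatality_365d, "case_fatality_365d"),
            (self.added_mortality, "added_mortality"),
        ):
            for event, by_sex in group.items():
                for sex, p in by_sex.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValidationError(
                            f"{name}.{event}.{sex} = {p} outside [0, 1]"
                        )
        for state, d in self.qaly_decrements.items():
            if not 0.0 <= d <= 1.0:
                raise ValidationError(f"qaly_decrements.{state} = {d} outside [0, 1]")
        if not (
            self.sbp_normotensive
            < self.sbp_treated_hypertensive
            < self.sbp_untreated_hypertensive
        ):
            raise ValidationError(
                "expected sbp_normotensive < sbp_treated_hypertensive "
                "< sbp_untreated_hypertensive"
            )
        if self.mi_endpoint not in ("mi", "chd"):
            raise ValidationError("mi_endpoint must be 'mi' or 'chd'")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ParameterSet":
        """Deep-copied variant with top-level fields replaced (DSA/PSA helper)."""
        d = copy.deepcopy(self.to_dict())
        d.update(changes)
        return ParameterSet(**d).validate()

    def scaled_costs(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Variant with the given unit costs multiplied by per-key factors."""
        costs = dict(self.unit_costs)
        for key, f in factors.items():
            if key not in costs:
                raise KeyError(f"unknown unit cost: {key}")
            costs[key] = costs[key] * f
        return self.replace(unit_costs=costs)


# ---------------------------------------------------------------------- #
# Loading / serialisation


def _read_document(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    # YAML is a superset of JSON, so this also accepts .json content.
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"configuration root must be a mapping: {path}")
    return doc


def _baseline_document() -> dict[str, Any]:
    ref = importlib.resources.files("bpscreen") / "data" / "table1_baseline.yaml"
    return yaml.safe_load(ref.read_text())


def default_parameters() -> ParameterSet:
    """The packaged base case (the published input table, verbatim)."""
    return ParameterSet(**_baseline_document()).validate()


def load_parameters(
    source: str | Path | Mapping[str, Any] | None = None,
    *,
    use_defaults: bool = True,
) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    Parameters
    ----------
    source
        Path to a YAML/JSON document, or an already-parsed mapping.  ``None``
        returns the packaged baseline.
    use_defaults
        When true (default) missing fields fall back to the packaged
        baseline; when false every field must be present.
    """
    if source is None:
        return default_parameters()
    doc = _read_document(source)
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if use_defaults:
        base = _baseline_document()
        for key, value in doc.items():
            if isinstance(value, dict) and isinstance(base.get(key), dict):
                merged = copy.deepcopy(base[key])
                _deep_update(merged, value)
                base[key] = merged
            else:
                base[key] = value
        doc = base
    else:
        missing = known - set(doc)
        if missing:
            raise ConfigurationError(
                f"missing configuration fields: {sorted(missing)}"
            )
    return ParameterSet(**doc).validate()


def _deep_update(target: dict, updates: Mapping) -> None:
    for k, v in updates.items():
        if isinstance(v, Mapping) and isinstance(target.get(k), dict):
            _deep_update(target[k], v)
        else:
            target[k] = v


def serialize(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialise to YAML; round-trips bit-for-bit through ``load_parameters``."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------- #
# Distribution elicitation


@dataclass(frozen=True)
class DistributionSpec:
    """A concrete sampling distribution elicited from a point value.

    ``family`` is one of beta | gamma | normal | uniform | fixed.  ``mean``
    and ``sd`` are the moments of the elicited distribution; ``low``/``high``
    are the bounds for the uniform family.  ``shape_a``/``shape_b`` hold the
    family-specific parameters (beta a/b, gamma shape/scale).
    """

    family: str
    mean: float
    sd: float
    low: float | None = None
    high: float | None = None
    shape_a: float | None = None
    shape_b: float | None = None

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "fixed" or self.sd == 0.0:
            return np.full(size, self.mean) if size is not None else self.mean
        if self.family == "beta":
            x = rng.beta(self.shape_a, self.shape_b, size)
            if self.low is not None:  # rescaled beta (relative-risk multiplier)
                x = self.low + (self.high - self.low) * x
            return x
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size)
        raise ElicitationError(f"unknown family: {self.family}")

    def frozen(self):
        """The scipy frozen distribution (None for the fixed family)."""
        if self.family == "fixed" or self.sd == 0.0:
            return None
        return {
            "beta": lambda: stats.beta(self.shape_a, self.shape_b),
            "gamma": lambda: stats.gamma(self.shape_a, scale=self.shape_b),
            "normal": lambda: stats.norm(self.mean, self.sd),
            "uniform": lambda: stats.uniform(self.low, self.high - self.low),
        }[self.family]()


def _sd_from_range(point: float, rel_range: float) -> float:
    # ±r read as a central 95% interval: half-width r·|point| = 1.96·sd.
    return abs(rel_range * point) / 1.959963984540054


def elicit_distribution(
    point: float,
    family: str,
    *,
    rel_range: float | None = None,
    sd: float | None = None,
    bounds: tuple[float, float] | None = None,
) -> DistributionSpec:
    """Elicit a sampling distribution whose mean equals the base-case point.

    Exactly one of ``rel_range`` (e.g. 0.2 for "±20%"), ``sd`` (an explicit
    standard error) or ``bounds`` (uniform) determines the spread.
    """
    family = family.lower()
    if family == "uniform":
        if bounds is None:
            raise ElicitationError("uniform family requires explicit bounds")
        lo, hi = bounds
        if not lo <= point <= hi:
            raise ElicitationError(f"point {point} outside uniform bounds {bounds}")
        mean = 0.5 * (lo + hi)
        return DistributionSpec(
            "uniform", mean=mean, sd=(hi - lo) / math.sqrt(12.0), low=lo, high=hi
        )

    if sd is None:
        if rel_range is None:
            raise ElicitationError("need rel_range or sd to set the spread")
        sd = _sd_from_range(point, rel_range)

    if sd == 0.0:
        return DistributionSpec("fixed", mean=point, sd=0.0)

    if family == "normal":
        return DistributionSpec("normal", mean=point, sd=sd)

    if family == "gamma":
        if point <= 0:
            raise ElicitationError("gamma requires a positive point value")
        shape = (point / sd) ** 2
        scale = sd**2 / point
        return DistributionSpec("gamma", mean=point, sd=sd, shape_a=shape, shape_b=scale)

    if family == "beta":
        if not 0.0 < point < 1.0:
            raise ElicitationError("beta requires a point value strictly in (0, 1)")
        max_sd = math.sqrt(point * (1.0 - point))
        if sd >= max_sd:
            logger.warning(
                "beta sd %.4g infeasible for mean %.4g; shrunk to 99%% of max",
                sd,
                point,
            )
            sd = 0.99 * max_sd
        nu = point * (1.0 - point) / sd**2 - 1.0
        a, b = point * nu, (1.0 - point) * nu
        return DistributionSpec("beta", mean=point, sd=sd, shape_a=a, shape_b=b)

    if family == "fixed":
        return DistributionSpec("fixed", mean=point, sd=0.0)

    raise ElicitationError(f"unknown family: {family}")


def scaled_beta_multiplier(rel_range: float = 0.2) -> DistributionSpec:
    """A mean-1 relative-risk multiplier on [1-r, 1+r], Beta-shaped.

    Used for the event-risk uncertainty in the PSA where the published
    inputs name a beta family but give only a relative range: a symmetric
    Beta(a, a) is rescaled to [1-r, 1+r] with a chosen so the multiplier's
    sd equals r/1.96, matching the ±r-as-95%-interval convention.
    """
    sd = rel_range / 1.959963984540054
    unit_var = (sd / (2.0 * rel_range)) ** 2  # variance of the Beta(a, a) on [0, 1]
    a = (1.0 / (8.0 * unit_var)) - 0.5
    return DistributionSpec(
        "beta", mean=1.0, sd=sd, low=1.0 - rel_range, high=1.0 + rel_range,
        shape_a=a, shape_b=a,
    )


def sample_multiplier(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None
):
    """Sample a scaled-beta multiplier spec (beta on [low, high])."""
    u = rng.beta(spec.shape_a, spec.shape_b, size)
    return spec.low + (spec.high - spec.low) * u
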