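"""Sensitivity analyses: one-way (tornado) DSA, probabilistic SA, CE plane, CEAC.

The deterministic analysis perturbs one input group at a time (costs and
QALY decrements by ±20%, the horizon by ±50%, the discount rate across its
0-5% range, detected-case prevalence by ±20%) and records the resulting
ICER interval.  The probabilistic analysis draws joint parameter samples
from the elicited distributions (gamma for costs, beta for probabilities
and decrements, normal for the detected-case count, scaled-beta relative
multipliers for the Framingham event risks), re-evaluates the incremental
cost and QALYs per draw, and summarises the draws on the cost-effectiveness
plane and as a cost-effectiveness acceptability curve using the net
monetary benefit rule (cost-effective at willingness-to-pay λ iff
λ·ΔQALY − Δcost > 0, robust to sign changes in the denominator).

Both analyses exploit the model's linearity in stratum counts: the arm
difference equals the difference between "switcher" cohorts (the detected
hypertensives treated under screening but not otherwise), so each
evaluation propagates only the strata that differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import (
    CEResult,
    build_switcher_cohorts,
    incremental_results,
    run_cohort,
)
from .parameters import (
    DistributionSpec,
    ParameterSet,
    elicit_distribution,
    scaled_beta_multiplier,
)
from .risk_engine import LifeTable
from .short_term import arm_cost_ledger, build_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "TornadoEntry",
    "PSADraw",
    "evaluate_incremental",
    "one_way_dsa",
    "DSA_AXES",
    "run_psa",
    "ceac",
    "ce_plane_quadrants",
    "psa_frame",
]

DEFAULT_WTP_GRID = np.arange(0, 3_000_001, 25_000)


# ---------------------------------------------------------------------- #
# Single model evaluation


def evaluate_incremental(
    params: ParameterSet,
    table: LifeTable,
    *,
    perspective: str = "payer",
    subgroup: str = "all",
    horizon: int | None = None,
    discount_rate: float | None = None,
    screen_cases: float | None = None,
    risk_multipliers: Mapping[str, float] | None = None,
) -> CEResult:
    """Incremental cost, QALYs and ICER of screening vs no screening.

    ``screen_cases`` overrides the detected-case count; the comparator's
    true-positive and diagnosed counts scale with it (detection ratios
    held fixed).
    """
    base_cases = params.identified_cases_screening
    cases = base_cases if screen_cases is None else screen_cases
    comp_true = cases * params.identified_cases_comparator_true / base_cases
    comp_diag = cases * params.comparator_total_diagnosed / base_cases

    scenario = build_scenario(params, screen_cases=cases, comp_diagnosed=comp_diag)
    ledgers = (
        arm_cost_ledger(scenario, params, "screening", perspective),
        arm_cost_ledger(scenario, params, "no_screening", perspective),
    )
    screen, comp = build_switcher_cohorts(
        params, subgroup, screen_cases=cases, comp_true=comp_true
    )
    kwargs = dict(
        horizon=horizon, discount_rate=discount_rate, risk_multipliers=risk_multipliers
    )
    trace_s = run_cohort(screen, params, table, **kwargs)
    trace_c = run_cohort(comp, params, table, **kwargs)
    return incremental_results(trace_s, trace_c, ledgers, perspective, subgroup)


# ---------------------------------------------------------------------- #
# Deterministic (one-way) sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_icer: float
    high_icer: float

    @property
    def width(self) -> float:
        return abs(self.high_icer - self.low_icer)

    @property
    def lo(self) -> float:
        return min(self.low_icer, self.high_icer)

    @property
    def hi(self) -> float:
        return max(self.low_icer, self.high_icer)


def _axis_variants(params: ParameterSet, axis: str, rel: float = 0.2):
    """(low_kwargs, high_kwargs) pairs of evaluate_incremental overrides."""
    cases = params.identified_cases_screening
    if axis == "horizon":
        return (
            {"horizon": int(round(params.horizon_years * 0.5))},
            {"horizon": int(round(params.horizon_years * 1.5))},
        )
    if axis == "discount_rate":
        return ({"discount_rate": 0.0}, {"discount_rate": 0.05})
    if axis == "prevalence":
        return (
            {"screen_cases": cases * (1 - rel)},
            {"screen_cases": cases * (1 + rel)},
        )
    cost_groups = {
        "ami_costs": ("ami_first_year", "ami_post_annual"),
        "stroke_costs": ("stroke_first_year", "stroke_post_annual"),
        "drug_cost": ("drug_annual",),
    }
    if axis in cost_groups:
        keys = cost_groups[axis]
        return (
            {"params": params.scaled_costs({k: 1 - rel for k in keys})},
            {"params": params.scaled_costs({k: 1 + rel for k in keys})},
        )
    dec_groups = {
        "ami_decrement": ("ami_year", "post_ami"),
        "stroke_decrement": ("stroke_year", "post_stroke"),
    }
    if axis in dec_groups:
        keys = dec_groups[axis]

        def scaled(f: float) -> ParameterSet:
            dec = dict(params.qaly_decrements)
            for k in keys:
                dec[k] = dec[k] * f
            return params.replace(qaly_decrements=dec)

        return ({"params": scaled(1 - rel)}, {"params": scaled(1 + rel)})
    raise ValueError(f"unknown DSA axis: {axis!r}")


DSA_AXES = (
    "horizon",
    "prevalence",
    "ami_costs",
    "stroke_costs",
    "drug_cost",
    "ami_decrement",
    "stroke_decrement",
    "discount_rate",
)


def one_way_dsa(
    params: ParameterSet,
    table: LifeTable,
    axes: Sequence[str] = DSA_AXES,
    *,
    perspective: str = "payer",
    subgroup: str = "all",
    rel: float = 0.2,
) -> list[TornadoEntry]:
    """ICER interval per perturbed axis, sorted widest bar first."""
    entries = []
    for axis in axes:
        lo_kw, hi_kw = _axis_variants(params, axis, rel)
        icers = []
        for kw in (lo_kw, hi_kw):
            kw = dict(kw)
            p = kw.pop("params", params)
            res = evaluate_incremental(
                p, table, perspective=perspective, subgroup=subgroup, **kw
            )
            if res.icer is None:
                raise RuntimeError(f"axis {axis}: ICER undefined under perturbation")
            icers.append(res.icer)
        entries.append(TornadoEntry(axis, low_icer=icers[0], high_icer=icers[1]))
    return sorted(entries, key=lambda e: e.width, reverse=True)


# ---------------------------------------------------------------------- #
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSADraw:
    """One joint parameter sample and its incremental outcome pair."""

    index: int
    sampled: dict[str, float]
    delta_cost_payer: float
    delta_cost_societal: float
    delta_qalys: float
    seed: int  # master seed, for lineage

    def delta_cost(self, perspective: str) -> float:
        if perspective == "payer":
            return self.delta_cost_payer
        if perspective == "societal":
            return self.delta_cost_societal
        raise ValueError(f"unknown perspective: {perspective!r}")


def psa_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """The joint (independent) sampling distributions of the PSA.

    Costs are gamma, probabilities and decrements beta (±20% read as a
    central 95% interval), the detected-case count normal with its
    published standard error, and the event risks mean-one scaled-beta
    relative multipliers.  Fixed inputs (cohort sizes, discount rate,
    horizon, BP levels) never vary.
    """
    dists: dict[str, DistributionSpec] = {}
    for key, value in params.unit_costs.items():
        dists[f"cost.{key}"] = elicit_distribution(value, "gamma", rel_range=0.2)
    for event, by_sex in params.case_fatality_365d.items():
        for sex, p in by_sex.items():
            dists[f"cf.{event}.{sex}"] = elicit_distribution(p, "beta", rel_range=0.2)
    for state, by_sex in params.added_mortality.items():
        for sex, p in by_sex.items():
            dists[f"add.{state}.{sex}"] = elicit_distribution(p, "beta", rel_range=0.2)
    for state, d in params.qaly_decrements.items():
        dists[f"dec.{state}"] = elicit_distribution(d, "beta", rel_range=0.2)
    dists["cases"] = elicit_distribution(
        params.identified_cases_screening, "normal", sd=params.identified_cases_se
    )
    dists["riskmult.ami"] = scaled_beta_multiplier(0.2)
    dists["riskmult.stroke"] = scaled_beta_multiplier(0.2)
    return dists


def _apply_sample(params: ParameterSet, sample: Mapping[str, float]) -> ParameterSet:
    unit_costs = dict(params.unit_costs)
    cf = {e: dict(v) for e, v in params.case_fatality_365d.items()}
    add = {e: dict(v) for e, v in params.added_mortality.items()}
    dec = dict(params.qaly_decrements)
    for name, value in sample.items():
        head, _, rest = name.partition(".")
        if head == "cost":
            unit_costs[rest] = value
        elif head == "cf":
            event, sex = rest.split(".")
            cf[event][sex] = value
        elif head == "add":
            state, sex = rest.split(".")
            add[state][sex] = value
        elif head == "dec":
            dec[rest] = value
    return params.replace(
        unit_costs=unit_costs,
        case_fatality_365d=cf,
        added_mortality=add,
        qaly_decrements=dec,
    )


def run_psa(
    params: ParameterSet,
    table: LifeTable,
    n: int = 5000,
    seed: int = 0,
    *,
    subgroup: str = "all",
) -> list[PSADraw]:
    """``n`` independent joint draws, model re-evaluated per draw.

    A master :class:`numpy.random.SeedSequence` is spawned into per-draw
    substreams, so draw ``i`` is reproducible independently of order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = psa_distributions(params)
    children = np.random.SeedSequence(seed).spawn(n)
    draws: list[PSADraw] = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        sample = {name: float(spec.sample(rng)) for name, spec in dists.items()}
        # a pathological normal draw below the comparator floor is clipped
        sample["cases"] = float(np.clip(sample["cases"], 1.0, params.cohort_size))
        p_i = _apply_sample(params, sample)
        mult = {"ami": sample["riskmult.ami"], "stroke": sample["riskmult.stroke"]}
        res_p = evaluate_incremental(
            p_i,
            table,
            perspective="payer",
            subgroup=subgroup,
            screen_cases=sample["cases"],
            risk_multipliers=mult,
        )
        res_s = evaluate_incremental(
            p_i,
            table,
            perspective="societal",
            subgroup=subgroup,
            screen_cases=sample["cases"],
            risk_multipliers=mult,
        )
        draws.append(
            PSADraw(
                index=i,
                sampled=sample,
                delta_cost_payer=res_p.delta_cost,
                delta_cost_societal=res_s.delta_cost,
                delta_qalys=res_p.delta_qalys,
                seed=seed,
            )
        )
    return draws


def ceac(
    draws: Sequence[PSADraw],
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    *,
    perspective: str = "payer",
) -> pd.DataFrame:
    """P(cost-effective) by willingness to pay, via net monetary benefit."""
    if len(draws) == 0:
        raise ValueError("no PSA draws")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    dq = np.array([d.delta_qalys for d in draws])
    dc = np.array([d.delta_cost(perspective) for d in draws])
    prob = [(float(np.mean(lam * dq - dc > 0))) for lam in grid]
    return pd.DataFrame({"wtp_sek_per_qaly": grid, "probability": prob})


def ce_plane_quadrants(
    draws: Sequence[PSADraw], *, perspective: str = "payer"
) -> dict[str, int]:
    """Counts of draws per cost-effectiveness-plane quadrant."""
    dq = np.array([d.delta_qalys for d in draws])
    dc = np.array([d.delta_cost(perspective) for d in draws])
    return {
        "north_east": int(np.sum((dq > 0) & (dc > 0))),
        "north_west": int(np.sum((dq <= 0) & (dc > 0))),
        "south_west": int(np.sum((dq <= 0) & (dc <= 0))),
        "south_east": int(np.sum((dq > 0) & (dc <= 0))),
    }


def psa_frame(draws: Iterable[PSADraw]) -> pd.DataFrame:
    """Draws as a flat table (one row per draw), ready for CSV export."""
    rows = []
    for d in draws:
        row = {
            "index": d.index,
            "seed": d.seed,
            "delta_cost_payer": d.delta_cost_payer,
            "delta_cost_societal": d.delta_cost_societal,
            "delta_qalys": d.delta_qalys,
        }
        row.update(d.sampled)
        rows.append(row)
    return pd.DataFrame(rows)
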