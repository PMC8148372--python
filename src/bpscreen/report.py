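"""Pipeline orchestration: run every analysis and render paper-style outputs.

``run_full_analysis`` executes the short-term ledgers, the long-term
cohort comparisons (all/men/women × payer/societal), the tornado DSA and
the PSA with CE plane and CEAC, writing machine-readable CSV/JSON artifacts
plus SVG figures and a manifest (config hash, seed, versions) that
suffices to reproduce every output.

Display rounding follows reporting convention: ledger totals to whole SEK,
long-term incremental costs to the nearest 100,000 SEK; machine-readable
columns keep full precision.  EUR columns divide by the fixed 10.3
SEK/EUR rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "bpscreen"  # stable ids in SVG output
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .markov import build_arm_cohorts, incremental_results, run_cohort
from .parameters import ParameterSet, load_parameters, serialize
from .risk_engine import load_life_table
from .short_term import (
    arm_cost_ledger,
    build_baseline_scenario,
    cost_per_identified_case,
    ledger_frame,
)
from .uncertainty import (
    DEFAULT_WTP_GRID,
    ce_plane_quadrants,
    ceac,
    one_way_dsa,
    psa_frame,
    run_psa,
)

logger = logging.getLogger(__name__)

__all__ = ["run_full_analysis", "short_term_table", "long_term_table"]


def _eur(x: float, rate: float) -> float:
    return x / rate


def short_term_table(params: ParameterSet) -> pd.DataFrame:
    """Arm totals and cost per identified case, both perspectives."""
    scenario = build_baseline_scenario(params)
    rows = []
    for perspective in ("payer", "societal"):
        s = arm_cost_ledger(scenario, params, "screening", perspective)
        c = arm_cost_ledger(scenario, params, "no_screening", perspective)
        res = cost_per_identified_case(
            s,
            c,
            params.identified_cases_screening,
            params.identified_cases_comparator_true,
        )
        rows.append(
            {
                "perspective": perspective,
                "screening_total_sek": s.total,
                "no_screening_total_sek": c.total,
                "difference_sek": res.delta_cost,
                "incremental_cases": res.delta_cases,
                "cost_per_identified_case_sek": res.incremental_per_case,
                "screening_total_eur": _eur(s.total, params.sek_per_eur),
                "difference_eur": _eur(res.delta_cost, params.sek_per_eur),
            }
        )
    return pd.DataFrame(rows)


def long_term_table(params: ParameterSet, table=None) -> pd.DataFrame:
    """The six incremental cost-effectiveness rows (subgroup × perspective)."""
    if table is None:
        table = load_life_table()
    scenario = build_baseline_scenario(params)
    rows = []
    for subgroup in ("all", "men", "women"):
        screen, comp = build_arm_cohorts(params, subgroup)
        trace_s = run_cohort(screen, params, table)
        trace_c = run_cohort(comp, params, table)
        for perspective in ("societal", "payer"):
            ledgers = (
                arm_cost_ledger(scenario, params, "screening", perspective),
                arm_cost_ledger(scenario, params, "no_screening", perspective),
            )
            res = incremental_results(trace_s, trace_c, ledgers, perspective, subgroup)
            rows.append(
                {
                    "subgroup": subgroup,
                    "perspective": perspective,
                    "incremental_cost_sek": res.delta_cost,
                    "incremental_cost_sek_rounded_100k": round(res.delta_cost, -5),
                    "incremental_cost_eur": _eur(res.delta_cost, params.sek_per_eur),
                    "incremental_qalys": res.delta_qalys,
                    "icer_sek_per_qaly": res.icer,
                    "icer_eur_per_qaly": (
                        _eur(res.icer, params.sek_per_eur) if res.icer else None
                    ),
                    "dominance": res.tag,
                }
            )
    return pd.DataFrame(rows)


def _tornado_figure(entries, base_icer: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    names = [e.parameter for e in entries][::-1]
    for i, e in enumerate(entries[::-1]):
        ax.barh(i, e.hi - e.lo, left=e.lo, height=0.6, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, label="base case")
    ax.axvline(500_000, color="r", ls="--", lw=1, label="500,000 SEK/QALY")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("ICER (SEK per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _ce_plane_figure(draws, perspective: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    dq = [d.delta_qalys for d in draws]
    dc = [d.delta_cost(perspective) / 1e6 for d in draws]
    ax.scatter(dq, dc, s=6, alpha=0.35, edgecolors="none")
    lim = max(abs(x) for x in dq) * 1.1
    for wtp, style in ((500_000, "--"), (1_000_000, ":")):
        xs = [-lim, lim]
        ax.plot(xs, [x * wtp / 1e6 for x in xs], "r" + style, lw=1,
                label=f"{wtp:,} SEK/QALY")
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (million SEK)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _ceac_figure(curve: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp_sek_per_qaly"] / 1e6, curve["probability"])
    ax.set_xlabel("Willingness to pay (million SEK per QALY)")
    ax.set_ylabel("P(screening cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_full_analysis(
    config: str | Path | None,
    outdir: str | Path,
    seed: int = 0,
    *,
    n_psa: int = 5000,
    make_figures: bool = True,
) -> dict:
    """Run the whole pipeline and write artifacts under ``outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = load_parameters(config)
    life = load_life_table()
    outputs: list[str] = []

    def write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(name)

    scenario = build_baseline_scenario(params)
    ledgers = [
        arm_cost_ledger(scenario, params, arm, "societal")
        for arm in ("screening", "no_screening")
    ]
    write(ledger_frame(ledgers), "short_term_ledgers.csv")
    write(short_term_table(params), "short_term_results.csv")

    lt = long_term_table(params, life)
    write(lt, "long_term_results.csv")
    base_icer = float(
        lt.query("subgroup == 'all' and perspective == 'payer'")[
            "icer_sek_per_qaly"
        ].iloc[0]
    )

    entries = one_way_dsa(params, life)
    dsa_df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_low_input": [e.low_icer for e in entries],
            "icer_high_input": [e.high_icer for e in entries],
            "bar_width": [e.width for e in entries],
        }
    )
    write(dsa_df, "dsa_tornado.csv")

    draws = run_psa(params, life, n=n_psa, seed=seed)
    write(psa_frame(draws), "psa_draws.csv")
    curve = ceac(draws, DEFAULT_WTP_GRID)
    write(curve, "ceac.csv")
    quadrants = ce_plane_quadrants(draws)

    if make_figures:
        _tornado_figure(entries, base_icer, outdir / "tornado.svg")
        _ce_plane_figure(draws, "payer", outdir / "ce_plane.svg")
        _ceac_figure(curve, outdir / "ceac.svg")
        outputs += ["tornado.svg", "ce_plane.svg", "ceac.svg"]

    config_text = serialize(params)
    manifest = {
        "package": "bpscreen",
        "version": __version__,
        "seed": seed,
        "n_psa": n_psa,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "config_source": str(config) if config else "packaged baseline",
        "outputs": outputs,
        "ce_plane_quadrants": quadrants,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "resolved_config.yaml").write_text(config_text)
    logger.info("wrote %d artifacts to %s", len(outputs) + 2, outdir)
    return manifest
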