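# bpscreen

Cost-effectiveness analysis of a two-step opportunistic blood-pressure
screening programme offered during routine dental check-ups, compared with
care as usual.  The package is aimed at health economists and
epidemiologists who want a tested, scriptable re-implementation of this
kind of screening evaluation: a short-term cost-per-detected-case model of
the screening cascade, a 20-year Markov cohort model of the downstream
cardiovascular consequences, and the standard uncertainty toolkit (tornado
diagram, probabilistic sensitivity analysis, cost-effectiveness plane,
CEAC).

## The model

**Short term.**  2,025 previously unscreened adults aged 40–75 receive an
office blood-pressure test at the dental clinic; those at ≥140/≥90 mmHg
measure at home for a week, and home means ≥135/≥85 are referred to primary
care, yielding 170 confirmed hypertensives.  The comparator arm assumes
opportunistic detection of 61 people (3% incidence), of whom 46 are true
positives (25% white-coat).  Activity volumes × unit costs give per-arm
ledgers under a payer (health/dental care) and a societal (plus patient
time and travel) perspective, and the incremental cost-effectiveness ratio

  ICER = (Cost_screening − Cost_no-screening) / (Effect_screening − Effect_no-screening)

is reported per additional identified case.

**Long term.**  A six-state Markov cohort model — Healthy, AMI-year,
Stroke-year, Post-AMI, Post-Stroke, Dead — runs 20 annual cycles at a 3%
discount rate.  First-event risks come from the Framingham parametric
(Weibull) risk functions evaluated as one-year risks at the cohort's
current age, with treated hypertensives at SBP 140 mmHg instead of 147;
background mortality comes from a bundled sex-specific life table;
first-year case fatality and chronic added mortality follow the published
inputs.  QALY weights are 1 minus state decrements (AMI-year 0.25,
stroke-year 0.50, post-AMI 0.05, post-stroke 0.25).  The arms differ only
in how many detected hypertensives are treated (170 vs 46), so the QALY
gain comes from events averted among the 124 "switchers".

**Uncertainty.**  One-way DSA perturbs costs and decrements ±20%, the
horizon ±50% and the discount rate over 0–5%.  The PSA draws 5,000 joint
samples (gamma costs, beta probabilities/decrements with ±20% read as a
95% interval, Normal(170, 17) detected cases, mean-one scaled-beta risk
multipliers) and applies the net-monetary-benefit rule
(λ·ΔQALY − ΔCost > 0).

## Worked example

```python
from bpscreen import default_parameters, load_life_table, long_term_table, short_term_table

params = default_parameters()          # packaged baseline inputs (2019 SEK)
print(short_term_table(params))
print(long_term_table(params, load_life_table()))
```

The short-term screening-arm payer total is **710,086 SEK** against 115,017
without screening; the 595,069 SEK difference over 124 additional true
positives gives **4,799 SEK per identified case** (payer) and **12,799
SEK** societal.  The long-term comparison prints (per `examples/long_term_icer.py`):

```
   all / societal dCost  5.33 M SEK   dQALYs  1.74   ICER  3.06 M SEK/QALY
   all / payer    dCost  4.34 M SEK   dQALYs  1.74   ICER  2.49 M SEK/QALY
   men / societal dCost  5.26 M SEK   dQALYs  2.16   ICER  2.43 M SEK/QALY
   men / payer    dCost  4.26 M SEK   dQALYs  2.16   ICER  1.97 M SEK/QALY
 women / societal dCost  5.39 M SEK   dQALYs  1.38   ICER  3.91 M SEK/QALY
 women / payer    dCost  4.40 M SEK   dQALYs  1.38   ICER  3.19 M SEK/QALY
```

Screening buys ~1.7 discounted QALYs across the 2,025-person cohort at
~4.3 M SEK extra payer cost — an ICER of ~2.5 M SEK/QALY, far above the
500,000 SEK/QALY reference threshold, and no DSA perturbation brings it
below that threshold.  Men benefit more than women (higher untreated AMI
risk), so the all-male ICER is lowest.

The `examples/` scripts each exercise one capability (short-term ledgers,
long-term ICER, sensitivity analyses, synthetic cascade); `bpscreen --help`
exposes the same steps as a CLI, and `bpscreen run --out results/` writes
the full artifact set (CSV tables, SVG figures, run manifest).

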