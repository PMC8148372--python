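# Methods

## Scope and structure

`bpscreen` evaluates a two-step dental-setting hypertension screening
programme against opportunistic care as usual, in two stages: a short-term
cost model of the screening cascade (outcome: identified true-positive
hypertension cases) and a long-term six-state Markov cohort model
(outcome: discounted QALYs), with deterministic and probabilistic
sensitivity analyses on top.  All amounts are 2019 SEK; EUR values divide
by the fixed rate 10.3 at reporting time only.

## Short-term model

Each arm is a set of activity volumes multiplied by unit costs into an
itemised ledger.  Health/dental-care lines (the payer perspective) cover
the dental BP test (117 SEK × 2,025), primary-care BP visits (149 SEK),
ECG (75), laboratory panel (240), diagnosis work-up and a fixed programme
administration cost; non-health-care lines (added for the societal
perspective) value patient time at 160 SEK/h and travel at 6.5 SEK/trip.

Volumes that the source tables print only as line totals (primary-care
visits, patient hours, trips) are back-derived once as total ÷ unit cost
and frozen as exact rational per-case constants (e.g. 812 visits per 170
cases).  Two unit costs are stored de-rounded so the ledger reproduces the
published arithmetic to the öre: the diagnosis work-up at 784 SEK and the
administration cost at 165,343 SEK (printed rounded as 785 and 165,000 in
the input table, but used unrounded in the published ledger).  Ledger
identities (line total = volume × unit cost; societal = payer +
non-health) hold exactly, and differences between arms are computed from
arm totals (the published difference column is internally inconsistent and
is not reproduced).

## Long-term model

**States.**  Healthy → {AMI-year, Stroke-year} → {Post-AMI, Post-Stroke} →
Dead, with Dead absorbing.  Event-year states are one-cycle tunnels.  No
recurrent or cross-track events: a person who has had an AMI cannot later
have a modelled stroke, and vice versa.

**Transitions.**  Annual cycles.  From Healthy, background all-cause
mortality q(age, sex) takes priority and survivors face the one-year
Framingham first-event risks, i.e. the event entries are (1−q)·p.  (A
purely additive composition cannot remain row-stochastic at the life
table's terminal age where q = 1.)  Event-year exits are the 365-day case
fatality (AMI: men 0.144, women 0.173; stroke: men 0.102, women 0.144);
chronic post-event mortality is background plus an added annual risk
(post-AMI 0.018/0.017, post-stroke 0.074/0.061), capped at 1.

**Event risks.**  The Framingham parametric (accelerated-failure-time)
risk functions: P(event by t) = 1 − exp(−exp((ln t − μ)/σ)), with μ linear
in sex, ln age, ln SBP, smoking, ln(TC/HDL), diabetes and LVH, and
σ = exp(θ₀ + θ₁μ), evaluated at t = 1 each cycle at the cohort's current
age (clamped to the equations' published validity boundary of 74 when the
cohort ages past it).  The coronary coefficient row was cross-validated
against the equation's alternative published a/m parametrisation (the two
forms agree to rounding error; see `tests/_oracles.py`).  The myocardial
infarction endpoint — the default backing the AMI state, selectable via
`mi_endpoint: mi|chd` — uses its own linear predictor with the coronary
endpoint's dispersion parameters, a reconstruction choice that keeps
P(MI) ≤ P(CHD) across the valid domain (MI is a subset of coronary
disease); the stroke endpoint has constant dispersion and no lipid term.
The modelled population is diabetic-free (study exclusion criterion);
smoking and LVH default to false (prevalences unreported).  Systolic
pressure is used throughout: untreated hypertensives 147 mmHg, treated
140, normotensives 131, with TC/HDL 4.0 (men) and 3.2 (women).

**Background mortality.**  A bundled sex-specific life table
(`data/life_table_sweden_2017_synthetic.csv`) — a synthetic approximation
of the Swedish 2017 national tables built by monotone log-scale
interpolation through rounded published anchor probabilities at ages
40–90, Gompertz-slope extrapolation to 99 and q(100) = 1.  Any table with
the same 3-column schema (age, sex, qx) can be substituted.

**Cohorts.**  Both arms start entirely Healthy at age 53 (cohort mean
52.8), as point-mass strata by sex and treatment status.  The screening
arm treats all 170 detected hypertensives; the comparator treats 46 and
leaves 124 untreated; everything else is identical, and detected cases are
split across sexes in proportion to the cohort (930 men / 1,095 women; no
sex-specific detection is reported).  Single-sex subgroup analyses keep the
full cohort size.  The model is linear in stratum counts, so incremental
results equal the difference between the 124-person "switcher" cohorts;
the sensitivity analyses use that fast path, and a test pins its
equivalence to the full-arm difference.

**Rewards and discounting.**  Per cycle, start-of-cycle occupancy accrues
state costs (first event year 112,000 SEK for either event; post-AMI
2,670/yr; post-stroke 85,000/yr; treated strata additionally 2,150/yr drug
cost while alive) and QALYs (1 minus decrement; Dead contributes 0).  Both
streams are discounted at 3%/yr with cycle 0 undiscounted.  No half-cycle
correction by default (a config switch enables the trapezoid variant), in
line with common spreadsheet cohort-model practice.  Death within the
event year still accrues the full event-year cost and decrement —
the simplest reading of per-event first-year inputs.  Comparator
false positives accrue no long-term cost (no invented harm).  The
screening programme's short-term arm difference (595,069 SEK payer;
1,587,088 societal) is added to the long-term incremental cost for the
chosen perspective.

## Uncertainty analyses

**One-way DSA.**  Axes: horizon ±50% (10/30 years), discount rate 0–5%,
detected-case prevalence ±20%, AMI costs, stroke costs, drug cost, AMI and
stroke decrements ±20% (first-year and chronic values move together per
axis).  Varying the detected count scales the comparator's true/diagnosed
counts and the per-case short-term volumes proportionally (detection
ratios fixed).  Entries are sorted by ICER bar width; the horizon
dominates, and no perturbation brings the payer ICER below 500,000
SEK/QALY.

**PSA.**  5,000 joint independent draws.  Elicitation conventions:
"±20%" ranges are read as central 95% intervals, sd = 0.2·mean/1.96, the
standard CEA convention when only a range is published; costs are gamma
and probabilities/decrements beta by moment matching (with the sd shrunk
to 99% of the feasible maximum if a beta mean cannot support it); the
detected-case count is Normal(170, 17); the Framingham event risks get
per-endpoint relative multipliers on [0.8, 1.2], drawn from a symmetric
scaled beta with mean 1 and sd 0.2/1.96 (the published inputs name a beta
family for these risks but no variance).  Cohort sizes, the discount rate
and the horizon stay fixed (the discount rate is varied in the DSA only).
Sampling uses one master `SeedSequence` spawned into per-draw substreams,
so each draw is reproducible independently of evaluation order.  The
decision rule is net monetary benefit, λ·ΔQALY − ΔCost > 0, robust to
non-positive QALY differences; the CEAC reports the accepting share per λ
on a default grid of 0–3 M SEK in 25,000-SEK steps.

## Synthetic study emulator

`synthetic.generate_cohort` draws 2,025 individuals (930 men), ages
truncated-normal (52.8, 8.7) on [40, 75], sustained-hypertension
prevalence 170/2025, and a 3% white-coat rate among normotensives — set so
that roughly a quarter of office positives are white-coat, mirroring the
comparator's 25% assumption and implying ~226 expected office positives.
Blood-pressure values encode the classification exactly: sustained
hypertensives always exceed both thresholds (office means anchored near
147 mmHg), white-coats exceed only the office threshold, and home
measurement clears 86% of them (the published false-positive reduction);
the per-visit noise scales are tuning constants of the generator, not
study values.  The comparator arm detects Binomial(n, 0.03) people, 75%
true.  Cascade volumes reuse the back-derived per-case constants of the
short-term baseline, so simulated scenarios are exchangeable with the
packaged one.  What the generator does *not* emulate: continuous BP
distributions straddling the thresholds (sensitivity is 1 by
construction), within-person measurement correlation, seasonal or observer
effects, and longitudinal BP trajectories — so passing tests certify the
accounting and calibration of the pipeline, not screening test accuracy in
real populations.

## Numerical and design notes

- Transition rows sum to 1 within 1e-12; cohort occupancy is conserved to
  1e-9 per cycle; an individual-level Monte Carlo oracle (10⁵ people, same
  matrices) agrees with the cohort engine within 3 Monte Carlo SEs.
- ICERs are reported only for the "normal" quadrant; cheaper-and-better /
  costlier-and-worse draws carry dominance tags instead of ratios, and
  identical arms yield an explicit "undefined" tag rather than an
  exception or a division by zero.
- Money is kept at full precision internally; display rounding (whole SEK
  for ledgers, nearest 100,000 SEK for long-term costs) happens only in
  rendered tables.
- Life-table lookups above the terminal age return 1.0; ages are advanced
  as integers from the starting age.

## Known limitations

- The Framingham coefficient set is an embedded transcription; the
  coronary row is pinned by a published algebraic cross-check, while the
  MI row's dispersion is reconstructed (shared with the coronary endpoint)
  rather than independently certified.  Absolute event risks inherit the
  Framingham cohort's 1970s-80s US incidence levels.
- The published subgroup results imply a male/female QALY-gain ratio near
  5; under this model's setup (sex entering through the risk equations,
  case fatality, lipids and life table alone) the achievable differential
  is near 2, so female-cohort results should be read as conservative
  relative to the source.
- No heart failure, renal failure, atrial fibrillation or dementia
  sequelae; no recurrent events; treatment uptake and adherence are
  assumed complete and constant over the horizon.
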