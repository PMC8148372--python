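"""Twenty-year Markov cohort comparison: incremental QALYs and ICER.

Runs both arms of the six-state model (Healthy, AMI-year, Stroke-year,
Post-AMI, Post-Stroke, Dead) for the mixed cohort and the single-sex
subgroups, and prints incremental cost, QALYs and the ICER per perspective.
"""

from bpscreen import default_parameters, load_life_table, long_term_table

params = default_parameters()
life = load_life_table()

table = long_term_table(params, life)
for _, row in table.iterrows():
    icer = row["icer_sek_per_qaly"]
    print(
        f"{row['subgroup']:>6} / {row['perspective']:<8} "
        f"dCost {row['incremental_cost_sek'] / 1e6:5.2f} M SEK   "
        f"dQALYs {row['incremental_qalys']:5.2f}   "
        f"ICER {icer / 1e6:5.2f} M SEK/QALY"
    )

# Screening treats 124 extra hypertensives (SBP 147 -> 140 mmHg), averting
# a share of first AMI/stroke events over 20 years.  The QALY gain is a
# few QALYs across 2,025 people, while drug and programme costs add ~4M
# SEK, hence an ICER in the millions of SEK per QALY -- far above the
# 500,000 SEK/QALY threshold used in Swedish policy discussions.
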