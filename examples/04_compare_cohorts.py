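"""Stage-wise CNA-burden comparison between two tumor cohorts.

Emulates contrasting two cancer types whose CNA burdens differ: per tumor
stage (1-4) and per CNA mode, the cohorts' per-patient burdens are compared
with a Welch t-test and Bonferroni-corrected over the family of rows
tested (the family size m is printed alongside so the correction is
auditable).
"""

from gecna import SimulationConfig, compare_cohorts, generate_cohort

high_burden, _ = generate_cohort(
    SimulationConfig(n_patients=350, n_genes=800, mu_burden=500.0, seed=31)
)
low_burden, _ = generate_cohort(
    SimulationConfig(n_patients=350, n_genes=800, mu_burden=250.0, seed=32)
)

table = compare_cohorts(high_burden, low_burden)
cols = ["stage", "mode", "n_a", "n_b", "mean_a", "mean_b", "p_raw", "p_bonferroni", "m"]
print(table[cols].round({"mean_a": 0, "mean_b": 0}).to_string(index=False))
n_sig = int((table["p_bonferroni"] < 0.05).sum())
print(
    f"\n{n_sig}/{len(table)} stage/mode rows significant after Bonferroni:"
    " cohort A was simulated with twice cohort B's mean burden, so every"
    " tested row should separate."
)
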