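"""Generate a synthetic tumor cohort with planted CNA facilitator and
suppressor genes, and inspect its structure.

The generator emulates a cBioPortal-style study: expression z-scores,
GISTIC-type copy-number calls, clinical covariates with sub-staged tumor
stages, Cox-structured overall survival, and mutation flags. Planted genes
have their expression coupled to per-patient CNA burden; delta is the
expected burden separation (in burden SDs) between the gene's top-10 and
bottom-10 expression groups.
"""

from gecna import PlantedGene, SimulationConfig, generate_cohort
from gecna.burden import burden_table

config = SimulationConfig(
    n_patients=300,
    n_genes=1000,
    missing_gene_fraction=0.1,
    facilitators=[PlantedGene(3.0, "total", "FAC_A"), PlantedGene(2.5, "amp", "FAC_B")],
    suppressors=[PlantedGene(-3.0, "total", "SUP_A")],
    seed=1,
)
cohort, truth = generate_cohort(config)

print(f"cohort: {cohort.n_patients} patients x {len(cohort.expression.genes)} genes")
burdens = burden_table(cohort.cna)
print("per-patient CNA burden (counts of non-neutral gene calls):")
print(burdens[["total", "amp", "del"]].describe().loc[["mean", "std", "min", "max"]].round(1))
print("\nplanted truth set (what the screen should recover):")
print(truth.planted[["label", "mode", "delta"]])
n_bad = (cohort.expression.missing_mask.mean(axis=1) > 1 / 3).sum()
print(f"\n{n_bad} genes are missing in >1/3 of patients and will be filtered out")
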