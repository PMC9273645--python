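"""Gene-set over-representation of a screen hit list.

One-sided Fisher exact test per gene set, conditioned on the tested-gene
universe (the genes that survived the missingness filter, not the genome),
with Benjamini-Hochberg correction across sets.
"""

from gecna import GeneSetCollection, enrich

universe = [f"G{i:03d}" for i in range(200)]
collection = GeneSetCollection.from_dict(
    {
        "PATHWAY_ENRICHED": universe[:20],       # will overlap the hits heavily
        "PATHWAY_NEUTRAL": universe[100:130],
        "PATHWAY_SMALL": universe[190:196],
    },
    universe,
)
hits = universe[:12] + universe[150:153]  # 12 of 15 hits in the first set

table = enrich(hits, collection)
print(table[["set_size", "overlap", "odds_ratio", "p", "p_bh"]].to_string())
print(
    "\noverlap counts hits inside each set; p is the one-sided Fisher tail"
    " probability of seeing at least that overlap by chance, and p_bh the"
    " BH-adjusted value used at the 0.05 significance level."
)
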