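"""Check the screen's test statistic against published summary tables.

The package ships the group-level burden summaries (mean/SD at n=10 per
extreme-expression group) for 27 survival-critical genes reported from a
TCGA colorectal adenocarcinoma cohort. Recomputing the two-sided t-test
from those summaries reproduces the published p-values under the Welch
(unequal-variance) form of the test.
"""

from gecna import recompute_reference_pvalues

table = recompute_reference_pvalues(flavor="welch")
cols = ["category", "p_published", "p_recomputed", "rel_error"]
print(table[cols].to_string(float_format=lambda x: f"{x:.3g}"))
print(
    f"\nmax relative error (Welch): {table['rel_error'].max():.2%} -- every"
    " published p-value reproduces to well within the rounding of its"
    " printed inputs."
)
pooled = recompute_reference_pvalues(flavor="pooled")
print(
    f"max relative error if the pooled (classic Student) form is used"
    f" instead: {pooled['rel_error'].max():.0%}, showing the published"
    " analysis used the unequal-variance test."
)
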