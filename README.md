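# gecna

Screening tumor transcriptomes for genes whose expression associates with
copy-number-alteration (CNA) burden — and triaging the hits by survival
impact.

Genomic instability drives tumor evolution and drug resistance, but the
specific genes whose expression levels *facilitate* or *suppress* CNA
accumulation in a given organ are largely unknown. `gecna` implements an
expression-to-CNA screening protocol for cBioPortal-style cohorts
(gene × patient expression z-scores, GISTIC-type integer copy-number calls
in {−2,…,+2}, clinical and mutation tables), plus a synthetic-cohort
generator with a planted truth set so that every stage of the pipeline is
testable without external downloads.

## The screen

For each gene *g* with complete expression (genes missing in more than 1/3
of patients are excluded):

1. Rank patients by expression of *g*; take the top *k* = 10 (high group)
   and bottom *k* = 10 (low group).
2. Compute each patient's CNA burden — the count of genes with a
   non-neutral call — jointly (`total`, any call ≠ 0) and separately per
   type (`amp`: calls ≥ 1; `del`: calls ≤ −1).
3. Contrast the groups' burdens with a two-sided Welch *t*-test:
   *t* = (x̄_H − x̄_L) / √(s²_H/k + s²_L/k), Welch–Satterthwaite df.
4. Correct across the tested-gene family with Storey *q*-values
   (π₀ estimated on a λ-grid with a df=3 cubic smoothing spline).
5. Label genes with *q* < 0.05: **CNA facilitator** if the high-expression
   group carries more CNA, **CNA suppressor** if fewer.

A secondary *survival* screen fits, per significant gene, covariate-adjusted
Cox proportional-hazards models (covariates chosen from age / sex /
race[White,Other] / stage[1–4] by univariate Cox *p* < 0.05; Efron ties):
once with the continuous expression z-score and once with the binary
altered/unaltered status (altered = high-level amplification, homozygous
deletion, or mutation). Altered-group expression is contrasted with a
Wilcoxon rank-sum test. *Survival-critical* genes (expression Cox
*p* < 0.05) receive a hazard-ratio magnitude band (anchors ≈ 1.3 / 1.9 /
2.8, applied to max(HR, 1/HR)) and a drug-development direction
(inhibitor / enhancer) from the expression-direction × survival-direction
category.

Additional modules cover stage-wise burden comparison between two cohorts
(Welch + Bonferroni) and Fisher-exact gene-set over-representation of hit
lists against GMT collections (BH-corrected, conditioned on the
tested-gene universe).

## Worked example

```bash
python examples/02_run_screen.py
```

simulates a 400-patient × 1,500-gene cohort with four planted facilitators
and four planted suppressors (coupling strength δ = 3 burden-SDs between
the extreme groups) and screens it:

```
total: 10 significant genes at q<0.05 (pi0 estimate 0.940)
amp  :  0 significant genes at q<0.05 (pi0 estimate 1.000)
del  :  2 significant genes at q<0.05 (pi0 estimate 0.971)

significant genes in the total screen (planted truth: 4 FAC, 4 SUP):
          direction  mean_high  mean_low      t         p         q
gene
FAC2    facilitator      877.1     177.0  10.15  0.000002  0.001221
SUP0     suppressor      205.0     876.5  -8.76  0.000003  0.001221
...
```

`mean_high`/`mean_low` are the average CNA burdens of the 10 highest- and
10 lowest-expressing patients; a facilitator's high expressors carry more
CNA. The `q` column is the Storey FDR-adjusted p-value used at the 0.05
significance level. All eight planted genes are recovered with the correct
direction; occasional extra hits are the screen's controlled false
discoveries.

The package also ships the published group-level burden summaries for 27
survival-critical genes from a 592-patient TCGA colorectal adenocarcinoma
cohort; `python examples/06_published_worked_examples.py` recomputes every
printed p-value from its printed means/SDs to within 0.43% under the Welch
test (and shows the pooled-variance form disagrees by up to 82%).

A thin CLI mirrors the library (`gecna simulate | screen | survival |
compare | enrich | all`); see `gecna --help`.

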