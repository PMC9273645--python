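# Methods

## The screening model

The pipeline asks, gene by gene, whether extreme expression predicts tumor
CNA burden. Burden is the per-patient count of genes carrying a
non-neutral GISTIC-style call; the magnitude threshold `m` (default 1,
i.e. any non-neutral call) is exposed because high-level events (|call| =
2) matter separately for altered/unaltered status. Counting is gene-level:
the input matrix is gene × patient, and no segment-length or
fraction-genome-altered weighting is attempted.

The extreme-group design (top-10 vs bottom-10 expressors out of the full
cohort) deliberately trades sample size for effect enrichment: with a few
hundred patients, splitting at the median would dilute causal coupling,
while the tails concentrate it. The group contrast is a two-sided
two-sample t-test on burdens. The default is the **Welch**
(unequal-variance) form with Welch–Satterthwaite degrees of freedom; the
pooled (classic Student) form is available by flag. The Welch default is
empirical: the published 27-gene worked-example table shipped in
`gecna.reference` reproduces its printed p-values to ≤ 0.4% relative error
under Welch, while the pooled form deviates by up to 82% (see
`examples/06_published_worked_examples.py`, which prints both). With
k = 10 per group and burden SDs that routinely differ two-fold between
groups, the unequal-variance form is also the statistically safer choice.

Ties in expression are broken by patient id under a stable sort, so the
screen is deterministic and invariant to input column order (patients are
put in canonical sorted order during cohort alignment).

Genes missing in more than 1/3 of patients are excluded before testing; by
default retained genes must additionally be complete in all patients
(configurable). Genes skipped for other reasons (fewer than 2k usable
patients) are excluded from the multiple-testing family rather than
carried as untested hypotheses, and the skip reasons are logged.

## Multiple testing

Screen p-values are corrected per mode family (`total`, `amp`, `del` are
three separate families) with Storey q-values. π₀ is estimated as
π₀(λ) = #{p > λ} / (m(1−λ)) on the grid λ = 0, 0.05, …, 0.95, smoothed
with a **natural cubic smoothing spline at 3 effective degrees of freedom**
(Green–Silverman formulation; penalty found by bisection on the smoother
trace) and evaluated at λ = 0.95, clipped to (0, 1]. An unconstrained
cubic polynomial was rejected: it is boundary-unstable, leaving the
uniform-null π₀ estimate outside [0.9, 1] in ~12% of simulations at
m = 2000, versus ~7% for the spline — matching the behavior of the
canonical df=3 spline smoother in R (`smooth.spline`), against which the
implementation was verified. q-values are π₀-scaled step-up values made
monotone in p. Benjamini–Hochberg is available as an alternative, and
Bonferroni is used where a fixed small family is tested (the stage-wise
cohort comparison, which prints its family size m so any correction
convention can be audited).

## Survival triage

Candidate covariates are age (years), sex, race collapsed to
White/Other, and tumor stage collapsed from sub-staged strings ("Stage
IIIB" → 3) to ordinal 1–4 by roman/arabic prefix matching. Selection is by
univariate Cox p < 0.05; on realistic simulations this selects age and
stage, the covariates with genuine effects. Patients with missing required
fields or unparseable stage are excluded complete-case, so every gene fit
with the same covariate set sees the identical patient list unless the
gene itself has missing expression.

Per gene, two adjusted Cox models are fit with lifelines (Efron tie
handling, the dominant default in survival software): the continuous
expression z-score (per-unit HR) and the binary altered/unaltered status
(altered ⇔ call = ±2 or mutation flag; any mutation counts — the flag
table does not distinguish silent from non-silent). Degenerate fits
(constant predictor, < 2 events, non-convergence) yield flagged records
with HR absent, never exceptions. No multiple-testing correction is
applied in the survival screen (raw p < 0.05 defines survival-critical);
a correction flag exists but is off by default, matching the protocol's
two-stage logic in which the FDR control lives in the primary screen.

Hazard-ratio magnitudes are banded against the anchors 1.3 / 1.9 / 2.8
(small / medium / large two-group effects), applied symmetrically to
protective effects via 1/HR: `none` (HR = 1), `sub-small` (< 1.3),
`small-medium` [1.3, 1.9), `medium-large` [1.9, 2.8), `large` (≥ 2.8),
with an `actionable` flag at the 1.3 line. The four
expression-direction × survival-direction categories map to drug
directions: inhibitor where lower/absent expression associates with
improved survival (categories a and d), enhancer otherwise (b and c).

## The synthetic cohort generator

The generator produces the data the screen assumes, plus ground truth; it
defines the conditions under which the test suite's statements hold.

- **Burden.** Per-patient amplification and deletion counts are drawn as
  *independent* negative-binomial components with sizes θ·p_amp and
  θ·(1−p_amp) and a shared success probability, so that total = amp + del
  is exactly NB(mean μ_B = 400, dispersion θ = 6) while the two components
  are independent. A single latent total split binomially was rejected:
  under NB overdispersion the split components are ~0.97-correlated, so a
  gene coupled to one CNA type would light up the other type's screen
  purely through burden correlation, contradicting the mode-specificity
  the screen is designed to detect. Defaults give burden mean 400 and SD
  ≈ 165 at the default 2,000 genes (roughly the relative spread seen in
  real CRC burden distributions, scaled down from a ~20k-gene genome for
  desk-scale runs; burdens are capped at n_genes with a logged warning if
  the configuration makes that cap bind).
- **Call realization.** Each patient's amp (del) count is assigned to
  uniformly sampled distinct gene positions with magnitude +1/−1, a
  configurable fraction (default 0.1) upgraded to ±2 ("high-level",
  feeding altered status). Genomic position, segment structure, and
  mutation signatures are deliberately not modeled — the screen only ever
  sees counts.
- **Planted coupling.** A planted gene's expression is
  α·standardize(burden) + √(1−α²)·noise, then z-scored. The coupling
  strength δ is defined as the expected burden separation (in burden SDs)
  between the gene's top-k and bottom-k expression groups; α =
  δ / (2·E[upper k/n normal tail]) (clipped at 0.995), which makes δ = 3
  achievable and directly interpretable against the screen's own contrast.
  Defining δ as a one-sided tail shift was rejected as it would demand
  correlations above 1 for δ ≥ 2.5 at k = 10, n = 600. Suppressors are
  facilitators with negated α, so negating all couplings exactly swaps the
  screen's labels (verified as a property test).
- **Missingness.** A configured fraction of genes (never planted ones, so
  the truth set survives filtering) is made missing in a uniform 40–80% of
  patients — always beyond the 1/3 exclusion cutoff.
- **Clinical and survival.** Age ~ N(66, 11) clipped to [30, 90]; stages
  1–4 with probabilities (0.18, 0.38, 0.28, 0.16) and random sub-stage
  letters; race frequencies roughly mirroring a US cancer cohort.
  Survival is exponential with rate λ₀·exp(β_age(age−66) +
  β_stage(stage−2) + Σ β_g·expr_g), λ₀ = 0.01/month, β_age = 0.03/yr,
  β_stage = 0.35 — chosen so that age and stage, but not sex or race, are
  selected by the univariate screen on typical cohorts. Censoring is
  independent exponential; its rate is solved by bisection on
  E[c/(c + r_i)] to hit the configured censoring fraction (default 0.3).
  Proportional hazards hold exactly by construction, so Cox
  parameter-recovery tests measure estimation error, not model
  misspecification.
- **Determinism.** One global seed spawns per-stage child streams
  (burden, expression, clinical, survival, mutation, missingness), so
  partial pipelines are reproducible and adding a stage never perturbs an
  earlier one.

What the generator does **not** emulate — gene–gene expression
correlation beyond shared burden coupling, segment-level CNA structure,
non-proportional hazards, informative censoring, batch effects — bounds
what the passing tests show: they validate the statistical machinery and
its calibration under the stated model, not robustness of the protocol on
real tumor data.

## Problem sizes and numerical choices

Stochastic suites use fixed seed blocks: null calibration runs 25 cohorts
of 300 patients × 2,000 genes; planted recovery 25 cohorts of 600 ×
2,000 with 20 facilitators at δ = 3; Cox recovery 50 replicates at
n = 1,000. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances while keeping the full suite and the acceptance
script in the tens of seconds. Degenerate contrasts are handled explicitly:
both groups constant with equal means gives t = 0, p = 1; constant groups
with unequal means gives the smallest positive double and a flag rather
than an exception. Storey q-values of p = 0 are 0 by construction.
Hypothesis-based property tests run derandomized.

## Known limitations

- The enrichment module is a generic Fisher-exact over-representation
  test; it does not attempt pathway topology, causal networks, or
  activation z-scores.
- The mutation table is a plain patient × gene boolean; MAF-level
  consequence filtering is out of scope.
- Whether a published q-value family spans modes jointly or per mode is a
  protocol ambiguity; this implementation corrects per mode, recorded in
  the output metadata.
- The stage-wise two-cohort comparison implements the machinery (Welch +
  Bonferroni with explicit m); cross-cancer results additionally require
  two real cohorts as input.
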