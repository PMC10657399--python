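# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic cohort they are exercised on, and
the numerical choices made where the design was genuinely open. Every
number quoted here is computed by the test suite or `scripts/acceptance.py`.

## Cohort structure and stratification

Samples are HER2-low (IHC 1+ or 2+ with negative ISH) or HER2-0 (IHC 0);
HER2-positive samples (IHC 3+ or ISH-positive) are rejected at load. ER
status is three-valued — positive (≥ 10 % stained cells), low (1–9 %),
negative — and for every stratified analysis ER-low is merged into
ER-positive, giving two strata. Samples without recorded ER status are
excluded from stratified tests and models; the exclusion is counted in the
run manifest. ER is the central confounder: its distribution differs
between HER2 groups, so unadjusted per-gene comparisons largely reflect ER
biology.

## Variant filtering and oncogenicity

Tumor-only panels call germline polymorphisms alongside somatic mutations.
The filter retains a variant iff it is absent from both gnomAD and ClinVar
or its COSMIC occurrence count is ≥ 2 ("seen more than once"; a count of 1
does not rescue, and the rescue overrides both database flags jointly).
Database membership arrives as precomputed columns — the package never
queries the databases, since snapshots are version-pinned upstream. Two
deliberate readings are documented rather than guessed away: ClinVar
presence is treated literally as a flag (no benign/pathogenic distinction
is available in the inputs), and the TMB denominator uses the full filter
including the ClinVar clause.

Oncogenicity of a retained mutation is the union of a label branch
(oncogenic / likely_oncogenic / predicted_oncogenic) and a loss-of-function
branch (nonsense, frameshift or splice in a TSG); synonymous variants are
never oncogenic but do count toward TMB. CNVs are oncogenic only as
oncogene high amplifications (> 6 called copies) or TSG two-copy
deletions; all other CNV events, including hemideletions, are VUS. All
events are restricted to genes present on all three panel versions so
frequencies are comparable across assay generations.

## TMB and the hypermutation threshold

TMB = (germline-filtered mutation count) / (panel footprint in Mb). The
per-version footprints are configuration values (defaults 0.75 / 0.83 /
1.32 Mb); no authoritative sizes are published, and every TMB scales
inversely with them (a doubled footprint exactly halves TMB, which the
tests assert).

The hypermutation threshold is found by sorting log1p(TMB) and fitting an
exact two-segment **linear** least-squares model of the sorted curve
against rank (each segment its own line, minimum segment size 2 % of the
cohort, O(n) via prefix sums, ties to the smaller index). The threshold is
the midpoint on the raw scale between the samples flanking the boundary. A
piecewise-constant split was considered and rejected: the 1-D two-means
split of a unimodal skewed distribution lands near the body's center, not
at a small tail, whereas the two-line fit finds the inflection where the
slowly rising body gives way to the rapidly increasing tail. On planted
mixtures (lognormal body, 7 % uniform 20–60 tail, n = 1000) the detector
returns thresholds of roughly 13–17 mut/Mb, consistent with the shipped
fallback of 15 used when a cohort is smaller than 20 samples or has no
variance. Classification is strictly greater-than. Any threshold detector
sweeps some of the body's upper flank into the tail, so the detected
hypermutated fraction slightly exceeds the generative tail fraction
(≈ 9–11 % vs 7 % at default settings) while recall of true tail samples is
complete; tests therefore check calibration on the latent tail indicator
and full sensitivity of the detection, not equality of the two fractions.

## Purity-corrected ERBB2 copy counts

Under the two-population contamination model a segment with tumor copy
number CN in a specimen of purity p has depth ratio
(p·CN + 2(1−p)) / 2, so

    CN = (2 · 2^L − 2(1 − p)) / p,   L = segment log2 ratio.

This inverse returns exactly 2 at L = 0 for every purity. An alternative
literal reading of the published expression, 2^L + 1 in place of 2 · 2^L,
is available behind `variant="plus_one"` for comparison; the two agree
only at L = 0, and the default is the algebraic inverse of the standard
model (round-trip identity to 1e-9 over CN ∈ [0.5, 12], p ∈ [0.2, 1] is
asserted). Without a matched normal there is no ploidy correction: outputs
are *relative* copy counts, recorded as such in the manifest. Negative
computed copies are floored at 0 with a flag. When a gene spans several
segments the overlap-length-weighted mean log2 ratio is used
(deterministic, order-independent). Counts are binned at < 1.5
(hemideletion), [1.5, 2.5] (no change, closed interval), > 2.5 (gain).
Samples are ineligible — excluded with an enumerated reason, never
silently — when purity is unrecorded, no segment covers the gene, or the
IHC value was recorded as NOS below 2+.

## Stratified tests

**Generalized CMH.** For a 2 × K × S table the general-association
statistic sums, over strata, the centered category-count vector of group 1
and its exact hypergeometric covariance, and refers the quadratic form to
chi-square on K−1 df. With one stratum and K = 2 it reduces to the
(N−1)-scaled Mantel–Haenszel chi-square (no continuity correction
anywhere); the implementation was cross-checked against R's
`mantelhaen.test` to machine precision. A correlation-type variant with
equally spaced category scores (1 df) is available for ordered categories
such as IHC 0/1+/2+; the nominal general-association form is the default
used for the 3-level copy-count categories. Strata with a zero group
margin are dropped with a warning.

At small per-stratum counts (tens of samples) the permutation null of the
statistic is discrete, with point masses up to ~0.07, and the chi-square
reference is additionally anticonservative in the middle of the
distribution; per-table agreement between the asymptotic and permutation
p-value to 0.02 is therefore only achieved at larger strata (at ~500 per
stratum the maximum discrepancy observed is < 0.01). The test suite
records both facts.

**Stratified Kruskal–Wallis.** Observations receive midranks within their
stratum; per-group rank sums pooled over strata form a linear statistic
whose exact permutation mean and covariance (sampling without replacement
within strata) give a quadratic form on (groups − 1) df. With a single
stratum this equals the tie-corrected Kruskal–Wallis statistic (two
groups: the squared tie-corrected rank-sum z). Singleton strata are
dropped with a warning. Empirical type-I error at α = 0.05 over 1000 null
replicates (n = 200, two strata with different base distributions) falls
in (0.035, 0.065).

**Baseline comparisons.** Chi-square (no correction) for categorical
variables, Welch t for continuous, two-sided Wilcoxon rank-sum for
durations; single-level columns are skipped with a note.

## Enrichment modeling

For each gene and event class (any mutation, oncogenic mutation, oncogenic
CNV) the per-sample event indicator is modeled by maximum-likelihood
logistic regression on three 0/1 predictors: HER2-low, ER-positive
(ER-low merged in), and a background-burden category — hypermutation
status for mutation classes, and for CNV classes a high/low split of the
per-sample count of high amplifications plus deep deletions at a cutoff
chosen by the same changepoint scan used for TMB. Mutation genes enter
only if altered in strictly more than 4 % of either subcohort; CNV genes
are exempt (oncogenic CNVs are rare). The HER2 coefficient is reported as
an odds ratio with Wald 95 % CI and two-tailed Wald p; model relevance is
gated by a likelihood-ratio test against the intercept-only null at
BH-FDR q < 0.05 (a covariates-only null is selectable). Wald coefficient
p-values were chosen over a drop-one LRT after checking calibration: on a
global-null simulation (100 genes, n = 1000) the screen's any-discovery
rate is 0.050 with Wald p, 0.070 with LRT p. Fits that fail to converge
within 500 Newton iterations, hit separation (detected as |logit| > 15 or
non-finite standard errors), or have a constant outcome are excluded from
results and listed in the manifest with a reason — no silent drops.
Coefficient and gate p-values are BH-corrected separately within each
event-class family. BH itself is a NaN-aware wrapper over statsmodels'
step-up implementation, verified against the brute-force definition.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes, with one
latent truth row per sample so parameter recovery is well-posed:

* HER2-low prevalence 0.469; ER triple (positive, low, negative) per HER2
  class (0.768/0.037/0.195 in HER2-low vs 0.610/0.038/0.352 in HER2-0),
  ~0.6 % missing ER; specimen types 22.9 % primary / 2.3 % recurrence /
  74.8 % metastasis; panel versions 6.0/25.8/68.2 %.
* Per-gene mutation probabilities per (HER2, ER) cell for a TP53 / PIK3CA /
  CDH1 / GATA3 / ESR1 / MTOR / MAP3K1 / NF1 tier, plus high-amplification
  rates for CCND1 (13.2 %), FGFR1 (11 %), MYC (6.1 %) and a PTEN deep-del
  rate; an optional per-gene HER2 log-odds plants a direct effect on top.
* TMB: latent lognormal body (median 8.34 mut/Mb, log-SD 0.35) with a 7 %
  uniform tail on 20–60 mut/Mb. The body median is set so the
  *post-filter* TMB median lands near 7.3–7.6 (the germline filter removes
  c·(1−r) ≈ 11 % of variants at default contamination c = 0.15 and rescue
  r = 0.25); the log-SD reflects that counting noise dominates TMB spread
  at ~1 Mb panels (Poisson CV ≈ 0.3). The tail gives the changepoint
  detector a real inflection.
* Purity = 0.2 + 0.8·Beta(2, 2) — supported exactly on [0.2, 1],
  mirroring a minimum-cellularity inclusion rule; ~10 % of samples have
  purity masked and ~5 % lack the ERBB2 segment, driving the eligibility
  logic.
* ERBB2: true copies are truncated-normal (means 2.05 HER2-low / 1.79
  HER2-0, SD 0.55, floor 0.5), observed as
  log2((p·CN + 2(1−p))/2) + N(0, 0.1) — the exact forward model of the
  estimator, so recovery is an identity up to noise. The within-group SD
  is not an observed quantity; 0.55 was chosen so the implied hemideletion
  rate in the low-copy group (Φ((1.5−1.79)/0.55) ≈ 0.30) matches the
  ~31 % such cohorts show. The implied gain rates (~20 %) are somewhat
  higher than reported cohorts (~9–18 %) — a single-SD truncated normal
  cannot match both tails, and the hemideleted tail was chosen as the
  anchor because it is the replicated finding.
* Every variant (driver or passenger) carries gnomAD/ClinVar flags with
  probability c and, if flagged, a COSMIC count ≥ 2 with probability r.

What the generator deliberately does **not** model: read-level noise,
subclonality and clonal evolution, mutational signatures, gene–gene
correlation beyond the shared covariates, site-specific panel content, or
ploidy. Passing tests therefore demonstrate correctness of the estimators
and tests under the stated generative assumptions — not robustness to
misspecification on real tumors.

All randomness flows through one `numpy` Generator seeded from the config;
identical configs give byte-identical tables.

## Sizes and determinism

The acceptance script analyzes one n = 1039 cohort (~5 s). The test suite
uses cohorts of 120–1039 samples, 20 seeds for the copy-count recovery
check, 100 replicates for the FDR screen and 1000 replicates for rank-test
calibration, chosen to keep the full suite around a minute on one CPU
while leaving Monte-Carlo error well inside the asserted bands. Determinism
contracts: fixed seeds everywhere, mergesort for every sort that feeds
output files, and a counts ledger (samples_in = excluded + analyzed) that
is asserted at each pipeline stage.

## Known limitations

* Copy counts are relative to tumor ploidy; no allele-specific inference.
* The hypermutation threshold is cohort-dependent by construction; two
  cohorts of the same tumors with different TMB tails can disagree.
* The enrichment screen treats genes independently; co-mutation structure
  is not modeled (and is absent from the generator).
* Separation is reported as non-convergence rather than handled by
  penalized (Firth) regression; rare events in small subcohorts therefore
  drop out of the results (visibly, via the manifest).
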