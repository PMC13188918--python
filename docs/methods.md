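# Methods

This note documents the statistical procedures, the synthetic-data
model, the defaults and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Input model

The pipeline operates downstream of assembly, binning and annotation.
Its inputs are plain TSV/CSV tables: a MAG catalog (taxonomy, genome
length, completion %, redundancy %, rRNA/tRNA content), a sample sheet
for the three-substrate rearing design (day-0 substrate, day-6
substrate, day-6 gut), a MAG × sample mean-coverage matrix, a MAG ×
KEGG-module completeness matrix in [0, 1], a gene table with COG
function/category/pathway and optional KEGG-module annotations plus
per-sample coverage and total read counts, and per-gut-sample host
phenotypes (survival fraction, feed conversion ratio). Module, gene
and phenotype tables are optional; stages that need a missing table
refuse to run rather than improvising.

## Quality tiering

A bin is a medium-quality draft genome at completion ≥ 50 % and
redundancy < 10 %; high quality additionally requires completion
> 90 %, redundancy < 5 %, all of the 5S/16S/23S rRNA genes and ≥ 18
tRNAs. Boundaries: completion exactly 50 counts as medium; redundancy
exactly 10 counts as below medium. These follow the community MIMAG
convention for single-copy-gene-based estimates.

## Normalization

* **MAG abundance (TPM scheme).** Mean coverage is divided by genome
  length in kilobases and each sample column is rescaled to sum to a
  constant (default 10⁶; the constant is a config knob since any
  positive scale cancels in rank- and ratio-based downstream tests).
  All-zero samples stay all-zero rather than becoming NaN.
* **Gene coverage.** Scaled to counts per million of the sample's
  total reads. The constant again only fixes units.
* **Relative abundance.** Columns rescaled to sum to 1; used for the
  presence threshold and Hill numbers (which are scale-invariant, so
  TPM vs relative input gives identical diversity — asserted in the
  suite).
* **Aggregation.** Genus-level (or any rank) abundance is the sum of
  member MAG rows; MAGs lacking the rank are pooled under
  `unassigned`, so column sums are conserved.

## Diversity and ordination

Hill numbers are computed over the nonzero support of each sample:
`D_q = (Σ p_i^q)^{1/(1−q)}` for q ≠ 1, `exp(−Σ p_i ln p_i)` at q = 1,
and the support size at q = 0. The profile reports D0, D1, D2 per
sample; D_q is non-increasing in q, which the suite property-tests.

Ordination uses classical metric scaling (PCoA) of the Jaccard
distance between sample presence/absence profiles, with presence
defined by the same 10⁻⁴ relative-abundance threshold as the
prevalence analysis (one threshold, config-exposed — there is no
reason for the ordination to use a different one). Numerical choices:

* the Gower-centered matrix is symmetrized before `eigh`;
* eigenvalues below `max|λ|·10⁻¹²` are treated as zero;
* binary distances are generally non-Euclidean, so negative
  eigenvalues can occur; the default drops them and computes percent
  variance over the positive spectrum, and a Lingoes correction
  (adding the smallest negative eigenvalue's magnitude to squared
  off-diagonal distances) is available as a config alternative;
* "scaling and centering" of presence/absence data is realized by the
  double-centering inside PCoA itself; z-scoring a binary matrix
  before a binary distance is ill-defined and deliberately not done.

Two empty samples are at Jaccard distance 0 by convention.

## Gut-related MAG rule

Presence is *strictly* above the relative-abundance threshold
(default 10⁻⁴). A MAG is gut-related iff its prevalence over all gut
samples pooled across substrates is ≥ the prevalence threshold
(default 0.75) *and* it is present in no day-0 substrate sample.
Day-6 substrate samples play no role. The ≥/> boundary choice is
config-exposed (`inclusive`); with 13–15 gut samples no achievable
fraction equals 0.75 exactly, so the choice only matters on synthetic
designs. Prevalence is pooled, not per-substrate, because the rule is
meant to define one gut-associated set for the whole experiment.

Note that the gut-related set is not monotone in the presence
threshold in full generality (raising the threshold can clear a MAG's
day-0 presence), although it is monotone under the generator's
structural design, where gut MAGs have hard zeros at day 0; the suite
tests monotonicity there.

## Metabolic completion index

`MCI = mean(module completeness over ALL catalog modules) /
(completion/100)`. Averaging over all modules (zeros included) keeps
the index comparable across MAGs; a detected-modules-only variant is
available (`nonzero_only`). Dividing by the completion fraction
credits an incomplete assembly toward its estimated full metabolic
potential, so values above 1 are possible and expected for incomplete
genomes. Sample capacity is the sum of MCI over present MAGs (same
presence threshold), and the mean over present MAGs is reported
alongside; both are correlated with phenotypes because the choice
between them is ambiguous and cheap to keep.

## Enrichment

Module occurrence (completeness ≥ 0.75, the usual module-detection
convention of annotation pipelines; config-exposed) is tested between
MAG groups with the score test of the intercept-only binomial GLM
against the group-indicator alternative. The statistic has the closed
form `Σ_g N_g (p_g − p̄)² / (p̄(1−p̄))` with df = G − 1, which for two
groups equals the Pearson chi-square of the 2×2 table exactly — the
suite verifies this identity on 1,000 random tables. The closed form
is used instead of iterative GLM fitting because they coincide for
this design and the closed form is deterministic. Degenerate pooled
proportions (feature absent or ubiquitous) give statistic 0, p 1.
Direction is the group with the highest occurrence proportion;
exact ties resolve to the lexicographically first group and are
flagged ambiguous. BH-adjusted q-values are computed across features;
significant = score > 2 and q < 0.05, and a q < 0.07 tier is reported
alongside without being privileged.

## Differential abundance

* **MAGs.** Wilcoxon rank-sum per MAG for each of the three substrate
  pairs among gut samples. Exact null distribution when both groups
  have ≤ 7 observations and no ties, else the normal approximation
  with continuity and tie correction; a statistic exactly at its null
  center reports p = 1. Exactness matters at n = 4–5. Tiers:
  suggestive at p.adj < 0.1, significant at p.adj < 0.05.
* **COG functions.** Depth-normalized gene coverage summed per COG
  function; Welch t-tests by default (variance homogeneity is only
  checked advisorily; Student's variant is a flag). Significant =
  p.adj < 0.05 and |log2 FC| > 1, with fold changes computed on group
  means after adding a pseudocount of half the smallest nonzero
  aggregated coverage — large enough to prevent infinite fold changes,
  small enough not to dominate real values (config-exposed).
* **COG categories.** Dunn's test: pooled ranks with average ties,
  variance term `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, pairwise
  `z = Δmean rank / SE`, two-sided normal p, BH across the three pairs
  per category.
* **BH families.** One substrate pair × one feature class; permuting
  sample order leaves all results unchanged.
* **Assumption checks.** Shapiro–Wilk per group (n ≥ 3; constant
  groups reported not-applicable) and median-centered Levene. Purely
  advisory; they never gate a test. When all absolute deviations from
  the group medians are zero the Levene statistic is 0/0; it is
  reported as 0 (p = 1) when the group spreads agree and infinite
  otherwise.

## Phenotype correlation

Each gut sample maps to its replicate's survival and conversion
(per-sample points, never substrate averages). A module's feature
value is the mean depth-normalized coverage of genes annotated to the
module *and* belonging to gut-related MAGs; day-0 and day-6 substrate
baselines are returned for reference lines. An abundance-weighted
module-completeness variant is a possible alternative reading and is
not implemented as the default. Pearson r, OLS slope/intercept and
the two-sided t-distributed p (n − 2 df) are reported; zero-variance
features are flagged undefined rather than given a number. The module
screen reports BH q per phenotype alongside raw p as an interpretive
aid — the screen is exploratory and no threshold is privileged.
Capacity correlations are computed for both the all-MAG and the
gut-related-MAG capacity tables so the contrast between them is always
visible as a reported pair, not an asserted outcome.

## Synthetic data model

The generator reproduces the experimental design: per substrate, 1
day-0 sample, 3 day-6 substrate samples and 5 gut samples by default
(the plan validates against the 2–3 / 4–5 ranges of the design), 150
MAGs, 120 modules, 400 COG functions. All randomness flows from one
seed through named streams (one per table), so adding a table never
perturbs the others and a seed fully reproduces a dataset.

* **Abundance.** Log-normal per MAG with substrate-specific log-means
  (SD 1) and a structural presence mask — skewed, zero-inflated data,
  which is what the nonparametric tests downstream assume. 40 % of
  MAGs are gut-related: structurally absent from every day-0 sample,
  present in ≥ 90 % of gut samples (guaranteed by construction, per
  the configured minimum), and boosted ×20 in gut samples. Non-gut
  MAGs occupy their home substrates and at most 60 % of gut samples —
  below the 75 % rule by construction, so at zero noise the planted
  set is exactly recoverable, and added noise can only remove
  presence, never create false gut-related calls.
* **Modules.** Completeness is Beta-distributed: ≥ 0.75 when the
  module is planted present, < 0.75 otherwise, so occurrence at the
  0.75 threshold recovers the planted pattern. Twenty enriched modules
  occur with probability 0.9 in gut-related and 0.1 in other MAGs;
  the rest share a per-module baseline probability in both groups.
* **Genes.** Two genes per (MAG, present module) plus 15 unannotated
  genes per MAG; coverage follows MAG presence with per-gene
  log-normal rates and multiplicative noise. Twenty-five planted COG
  functions are shifted ×4 in brewery gut samples. A ×2 shift sits
  exactly on the |log2 FC| > 1 significance boundary and cannot be
  recovered reliably at n = 5, so the default effect is placed clear
  of the boundary; the fold is a config knob.
* **Phenotypes.** Survival (base 0.6) and conversion (base 1.5) are
  linear in the standardized per-sample mean coverage of one planted
  module each (+0.12 per SD for survival, −0.30 per SD for
  conversion), plus Gaussian noise scaled by the global `noise_sd`;
  survival is clipped to [0.01, 0.99]. Per-sample module activity
  multipliers (log-normal, SD 0.5) give the feature real variance
  across gut samples.
* **Nulled conditions.** `SyntheticConfig.nulled()` removes every
  planted effect (gut boost ×1, equal occurrence probabilities, no
  phenotype slopes, no COG shifts) while keeping the structural
  design, for type-I-error checks.

Effect sizes are synthetic choices made for comfortable statistical
power at n = 4–5 gut replicates, not estimates of any real system.
What passing recovery tests shows is that the pipeline's decision
rules correctly invert the generative model at these effect sizes; it
does not show field performance on real metagenomes, where MAG
catalogs are incomplete, coverage estimates are correlated across
samples, presence is not structurally zero, and phenotype noise is
larger. The generator also omits read-level artifacts, compositional
coupling between MAGs beyond closure, and phylogenetic correlation of
module content.

## Problem sizes

The test suite and acceptance script use 20 seeds for recovery and
null-rate estimates, 1,000 random tables/vectors for the oracle
equivalence checks, and 1,000 features for the type-I pipelines —
sizes at which the whole suite runs in about a minute on one CPU while
keeping Monte-Carlo noise on the reported rates well below the margins
they are compared against.

## Known limitations

* The Rao closed form covers the one-factor binomial design used here;
  covariate-adjusted enrichment would need the iterative GLM.
* Negative-eigenvalue handling in PCoA changes percent-variance
  denominators between tools; comparisons across packages must fix the
  same policy (the scikit-bio cross-check in the suite does).
* The exact Wilcoxon path requires tie-free data; with ties the normal
  approximation is used even at small n.
* The module–phenotype screen treats gut samples as independent
  replicates; with 13–15 points per correlation, p-values are fragile
  to single samples, which is why q-values are reported but no
  significance claim is built in.
* `evaluate_recovery` reports precision 1.0 when nothing is predicted
  (vacuous truth); interpret precision together with recall.
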