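# gutmags

Downstream analytics for genome-resolved metagenomics of reared insect
larvae: given a catalog of metagenome-assembled genomes (MAGs) with
per-sample coverage, KEGG-module completeness, COG-annotated gene
coverage and host performance data, the package quantifies how gut and
substrate microbiomes differ across rearing substrates and how
microbial functional capacity relates to host performance.

The target design is a larval rearing experiment on three waste- or
by-product-based substrates (brewery, bran/grass, sludge): each
substrate is sampled at day 0 (before larvae) and day 6, and larval
guts are dissected at day 6 (4–5 replicates per substrate). Typical
questions: which MAGs are resident in the gut rather than carried over
from feed? Which metabolic modules are enriched in those gut-related
genomes? Does the community's metabolic capacity predict larval
survival and feed conversion?

## What it computes

* **Normalization** — MAG mean coverage is length-normalized and
  sum-normalized per sample (TPM scheme,
  `x_i / (L_i/10³) / Σ_j rate_j × 10⁶`); gene coverage is scaled to
  counts per million of total sample reads; relative abundance for
  presence/absence work.
* **Diversity** — Hill effective numbers
  `D_q = (Σ p_i^q)^{1/(1−q)}` (richness at q = 0, exponential Shannon
  at q = 1, inverse Simpson at q = 2) per sample.
* **Ordination** — classical PCoA of the Jaccard (binary) distance
  between sample presence/absence profiles, with percent variance per
  axis.
* **Gut-related MAGs** — presence = relative abundance > 10⁻⁴; a MAG
  is gut-related when present in ≥ 75 % of gut samples (pooled across
  substrates) and in no day-0 substrate sample.
* **Metabolic completion index (MCI)** — per MAG, mean KEGG-module
  completeness divided by the genome completion fraction; summed or
  averaged over the MAGs present in a sample to give its metabolic
  capacity.
* **Functional enrichment** — binomial-GLM Rao score test of module
  occurrence (completeness ≥ 0.75) between gut-related and other MAGs:
  `X² = Σ_g N_g (p_g − p̄)² / (p̄(1−p̄))`, df = G−1, with
  Benjamini–Hochberg q-values; significant = score > 2 and q < 0.05
  (a q < 0.07 tier is also reported).
* **Differential abundance** — Wilcoxon rank-sum per MAG (exact for
  small tie-free groups), Welch t-tests per COG function with a
  |log2 FC| > 1 filter, Dunn's rank test per COG category; BH
  adjustment within each substrate pair × feature class; Shapiro–Wilk
  and Levene checks are advisory.
* **Phenotype correlation** — Pearson r and OLS regression of larval
  survival and feed conversion on per-sample mean module coverage
  (genes in gut-related MAGs) and on metabolic capacity.
* **Synthetic data** — a generator reproducing the experimental design
  with planted gut-related MAGs, enriched modules, substrate-shifted
  COGs, and module–phenotype effects, so every stage can be scored
  against known truth (`evaluate_recovery`).

## Worked example

```python
import gutmags as gm

config = gm.SyntheticConfig(seed=42)          # the default study design
dataset, truth = gm.generate_dataset(config)
result = gm.run_pipeline(dataset, gm.RunConfig(seed=42))

print("MAGs:", len(dataset.catalog), "| samples:", len(dataset.samples))
print("medium-or-better quality MAGs:", result.catalog_summary["medium_or_better"])
print("gut-related MAGs:", int(result.classification.table["gut_related"].sum()),
      "(planted:", len(truth.gut_related_mag_ids), ")")
print("PCoA percent variance, PC1/PC2: "
      f"{result.pcoa.percent_variance[0]:.2f} / {result.pcoa.percent_variance[1]:.2f}")
gut = result.diversity[result.diversity.sample_type == "gut_day6"]
day0 = result.diversity[result.diversity.sample_type == "substrate_day0"]
print(f"mean MAG richness D0: gut {gut.D0.mean():.1f} vs day-0 substrate {day0.D0.mean():.1f}")
print("modules enriched in gut-related MAGs (score > 2, q < 0.05):",
      int(result.enrichment["significant"].sum()))
report = gm.evaluate_recovery(truth, result.classification.gut_related_ids,
                              result.enrichment, result.module_correlations, seed=42)
print("recovery:", report.as_dict())
```

Output:

```
MAGs: 150 | samples: 27
medium-or-better quality MAGs: 141
gut-related MAGs: 60 (planted: 60 )
PCoA percent variance, PC1/PC2: 38.44 / 17.86
mean MAG richness D0: gut 85.8 vs day-0 substrate 47.3
modules enriched in gut-related MAGs (score > 2, q < 0.05): 22
recovery: {'gut_precision': 1.0, 'gut_recall': 1.0, 'enrichment_precision': 0.909..., 'enrichment_recall': 1.0, 'phenotype_sign_agreement': 1.0}
```

All 60 planted gut-related MAGs are recovered with no false positives;
all 20 planted enriched modules are flagged (two extra calls give the
0.91 precision); both planted module–phenotype effects come back with
the correct sign. Gut samples are far richer than the day-0 substrate,
and the first PCoA axis separates sample types — the qualitative
pattern the design plants.

The same stages are available from the shell:

```sh
gutmags synth --seed 42 --out data/
gutmags run-all data/ --out run/ --seed 42
gutmags classify-gut data/ --out gut.tsv --prevalence 0.75
```

Every threshold (presence 10⁻⁴, prevalence 0.75, module occurrence
0.75, enrichment score 2 and q 0.05/0.07, p.adj tiers 0.1/0.05,
|log2 FC| 1) is a named `RunConfig` key, overridable with
`--set key=value`.

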