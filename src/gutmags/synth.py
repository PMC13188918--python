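"""Synthetic dataset generator with planted, recoverable ground truth.

The generator emulates the rearing design the pipeline targets: three
substrates, one day-0 substrate sample each, 2-3 day-6 substrate
samples, 4-5 day-6 gut samples per substrate, and a catalog of ~150
MAGs.  It plants three kinds of signal and records them in a
``SyntheticTruth`` so downstream stages can be scored:

* a set of gut-related MAGs, absent from every day-0 substrate sample,
  occupying at least a configured fraction of gut samples, and boosted
  in abundance there by a multiplicative gut effect;
* a set of enriched KEGG modules whose occurrence probability differs
  between gut-related MAGs and the rest;
* module-phenotype effects: survival and conversion are linear in the
  (standardized) per-sample mean gene coverage of chosen modules, plus
  Gaussian noise, so correlation screens can be checked for sign.

Abundances are log-normal per MAG with substrate-specific means and a
structural presence mask (skewed, zero-inflated data, matching the
nonparametric tests used downstream).  Non-gut MAGs are capped below
the gut-prevalence decision boundary by construction, so at zero noise
the planted gut set is exactly recoverable.  Every table draws from
its own named pseudo-random stream derived from one seed, so adding a
table never perturbs the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    CoverageMatrix,
    CoverageState,
    Dataset,
    GeneFunctionTable,
    MagRecord,
    ModuleCompletenessMatrix,
    PhenotypeTable,
    SampleRecord,
    SUBSTRATES,
)

_COG_CATEGORIES = ("C", "E", "G", "I", "J", "K", "L", "M", "P", "V")
_BACTERIAL_PHYLA = (
    ("Pseudomonadota", 0.345),
    ("Actinomycetota", 0.338),
    ("Bacillota", 0.176),
    ("Bacteroidota", 0.110),
    ("Campylobacterota", 0.031),
)
_GENERA = (
    "Microbacterium", "Leucobacter", "Enterococcus", "Sphingobacterium",
    "Alcaligenes", "Lactococcus", "Providencia", "Stenotrophomonas",
    "Weissella", "Pseudochrobactrum", "Bordetella", "Pantoea",
    "Morganella", "Vagococcus", "Comamonas", "Empedobacter",
    "Cellulosimicrobium", "Paenibacillus", "Acinetobacter", "Brevundimonas",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass(frozen=True)
class ReplicatePlan:
    """Samples per substrate: day-0, day-6 substrate, day-6 gut."""

    day0: int = 1
    day6_substrate: int = 3
    gut: int = 5

    def validate(self) -> None:
        if self.day0 != 1:
            raise ValueError("design uses exactly 1 day-0 sample per substrate")
        if not (2 <= self.day6_substrate <= 3):
            raise ValueError("day-6 substrate replicates must lie in [2, 3]")
        if not (4 <= self.gut <= 5):
            raise ValueError("gut replicates must lie in [4, 5]")


@dataclass(frozen=True)
class PhenotypeEffect:
    """A planted linear effect of one module on one phenotype.

    ``slope`` is in phenotype units per standard deviation of the
    module's per-sample mean gene coverage; ``module_id`` None lets the
    generator pick an enriched module."""

    module_id: Optional[str]
    phenotype: str
    slope: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_mags: int = 150
    n_modules: int = 120
    n_cog_functions: int = 400
    replicates: ReplicatePlan = field(default_factory=ReplicatePlan)
    fraction_gut_related: float = 0.4
    gut_effect: float = 20.0
    gut_prevalence_min: float = 0.9
    enriched_module_count: int = 20
    enriched_presence: tuple[float, float] = (0.9, 0.1)
    phenotype_effects: Optional[tuple[PhenotypeEffect, ...]] = None
    n_shifted_cogs: int = 25
    cog_shift_fold: float = 4.0
    shifted_substrate: str = "brewery"
    noise_sd: float = 0.3
    mu_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        self.replicates.validate()
        if not (0.0 <= self.fraction_gut_related <= 1.0):
            raise ValueError("fraction_gut_related must lie in [0, 1]")
        for p in self.enriched_presence:
            if not (0.0 <= p <= 1.0):
                raise ValueError("enriched_presence probabilities must lie in [0, 1]")
        if not (0.75 <= self.gut_prevalence_min <= 1.0):
            raise ValueError("gut_prevalence_min must lie in [0.75, 1]")
        for n in (self.n_mags, self.n_modules, self.n_cog_functions):
            if n <= 0:
                raise ValueError("counts must be positive")
        if self.enriched_module_count > self.n_modules:
            raise ValueError("more enriched modules than modules")
        if self.n_shifted_cogs > self.n_cog_functions:
            raise ValueError("more shifted COGs than COG functions")
        if self.gut_effect <= 0 or self.cog_shift_fold <= 0:
            raise ValueError("multiplicative effects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.shifted_substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.shifted_substrate!r}")
        for eff in self.phenotype_effects or ():
            if eff.phenotype not in ("survival", "conversion"):
                raise ValueError(f"unknown phenotype {eff.phenotype!r}")

    def nulled(self) -> "SyntheticConfig":
        """Conditions with every planted effect removed (type-I checks)."""
        return replace(
            self,
            gut_effect=1.0,
            enriched_presence=(0.5, 0.5),
            phenotype_effects=(),
            n_shifted_cogs=0,
        )


@dataclass
class SyntheticTruth:
    """What was planted, for recovery scoring."""

    gut_related_mag_ids: set[str]
    enriched_module_ids: set[str]
    phenotype_effects: tuple[PhenotypeEffect, ...]
    shifted_cog_ids: set[str]
    seed: int


def _make_samples(plan: ReplicatePlan) -> list[SampleRecord]:
    samples = []
    for substrate in SUBSTRATES:
        for i in range(1, plan.day0 + 1):
            samples.append(SampleRecord(f"d0_sub_{substrate}_{i}",
                                        "substrate_day0", substrate, i))
        for i in range(1, plan.day6_substrate + 1):
            samples.append(SampleRecord(f"d6_sub_{substrate}_{i}",
                                        "substrate_day6", substrate, i))
        for i in range(1, plan.gut + 1):
            samples.append(SampleRecord(f"gut_{substrate}_{i}",
                                        "gut_day6", substrate, i))
    return samples


def _make_catalog(config: SyntheticConfig, gut_ids: set[str],
                  mag_ids: list[str]) -> list[MagRecord]:
    rng = _rng(config.seed, "catalog")
    n = config.n_mags
    n_archaea = min(2, n)
    n_euk = min(int(round(0.1 * n)), n - n_archaea)
    domains = (["archaea"] * n_archaea + ["eukaryote"] * n_euk
               + ["bacteria"] * (n - n_archaea - n_euk))
    rng.shuffle(domains)
    phyla, weights = zip(*_BACTERIAL_PHYLA)
    weights = np.asarray(weights) / sum(weights)

    records = []
    for mag_id, domain in zip(mag_ids, domains):
        completion = float(rng.uniform(55.0, 100.0))
        redundancy = float(rng.uniform(10.0, 15.0)) if rng.random() < 0.05 \
            else float(rng.uniform(0.0, 9.5))
        taxonomy = {}
        if domain == "bacteria":
            taxonomy["phylum"] = str(rng.choice(phyla, p=weights))
            if rng.random() > 0.05:  # a few MAGs lack a genus assignment
                taxonomy["genus"] = str(rng.choice(_GENERA))
        records.append(
            MagRecord(
                mag_id=mag_id,
                domain=domain,
                taxonomy=taxonomy,
                genome_length=int(rng.integers(1_500_000, 6_000_000)),
                completion=completion,
                redundancy=redundancy,
                n_contigs=int(rng.integers(10, 400)),
                n50=int(rng.integers(10_000, 500_000)),
                has_5s=bool(rng.random() < 0.6),
                has_16s=bool(rng.random() < 0.7),
                has_23s=bool(rng.random() < 0.7),
                n_trnas=int(rng.integers(5, 25)),
            )
        )
    return records


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one complete dataset and its planted truth, reproducibly."""
    config.validate()
    seed = config.seed
    plan = config.replicates
    samples = _make_samples(plan)
    sample_ids = [s.sample_id for s in samples]
    gut_sample_ids = [s.sample_id for s in samples if s.sample_type == "gut_day6"]
    n_gut_samples = len(gut_sample_ids)

    mag_ids = [f"MAG_{i + 1:04d}" for i in range(config.n_mags)]
    module_ids = [f"M{i + 1:04d}" for i in range(config.n_modules)]
    cog_ids = [f"COG{i + 1:04d}" for i in range(config.n_cog_functions)]

    rng_assign = _rng(seed, "assignments")
    n_gut_mags = int(round(config.n_mags * config.fraction_gut_related))
    gut_set = set(rng_assign.choice(mag_ids, size=n_gut_mags, replace=False))
    enriched = set(rng_assign.choice(module_ids,
                                     size=config.enriched_module_count,
                                     replace=False))
    shifted_cogs = set(rng_assign.choice(cog_ids, size=config.n_shifted_cogs,
                                         replace=False))

    catalog = _make_catalog(config, gut_set, mag_ids)

    # --- MAG abundance: structural presence mask, then log-normal values
    rng_occ = _rng(seed, "occupancy")
    rng_mu = _rng(seed, "abundance_means")
    rng_noise = _rng(seed, "abundance_noise")
    sub_index = {s: i for i, s in enumerate(SUBSTRATES)}
    mu = rng_mu.normal(0.0, config.mu_sd, size=(config.n_mags, len(SUBSTRATES)))

    presence = np.zeros((config.n_mags, len(sample_ids)), dtype=bool)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    gut_cols = [col[sid] for sid in gut_sample_ids]
    # Non-gut MAGs may occupy at most 60% of gut samples so the planted
    # gut set is separable from colonizers at the 75% prevalence rule.
    nongut_cap = int(math.floor(0.6 * n_gut_samples))
    min_gut_occ = int(math.ceil(config.gut_prevalence_min * n_gut_samples))

    for i, mag_id in enumerate(mag_ids):
        if mag_id in gut_set:
            for s in samples:
                j = col[s.sample_id]
                if s.sample_type == "substrate_day6" and rng_occ.random() < 0.5:
                    presence[i, j] = True
            k = max(int(rng_occ.binomial(n_gut_samples, 0.97)), min_gut_occ)
            chosen = rng_occ.choice(gut_cols, size=k, replace=False)
            presence[i, chosen] = True
        else:
            home = rng_occ.random(len(SUBSTRATES)) < 0.6
            if not home.any():
                home[rng_occ.integers(len(SUBSTRATES))] = True
            for s in samples:
                j = col[s.sample_id]
                if s.sample_type in ("substrate_day0", "substrate_day6"):
                    if home[sub_index[s.substrate]] and rng_occ.random() < 0.9:
                        presence[i, j] = True
            k = min(int(rng_occ.binomial(n_gut_samples, 0.3)), nongut_cap)
            if k > 0:
                chosen = rng_occ.choice(gut_cols, size=k, replace=False)
                presence[i, chosen] = True

    values = np.zeros((config.n_mags, len(sample_ids)))
    noise = rng_noise.normal(0.0, 1.0, size=values.shape)
    for j, s in enumerate(samples):
        m = mu[:, sub_index[s.substrate]]
        v = 5.0 * np.exp(m + config.noise_sd * noise[:, j])
        if s.sample_type == "gut_day6":
            boost = np.array([config.gut_effect if mid in gut_set else 1.0
                              for mid in mag_ids])
            v = v * boost
        values[:, j] = np.where(presence[:, j], v, 0.0)
    coverage = CoverageMatrix(
        values=pd.DataFrame(values, index=mag_ids, columns=sample_ids),
        state=CoverageState.RAW,
    )

    # --- module completeness with planted occurrence enrichment
    rng_mod = _rng(seed, "modules")
    p_gut, p_other = config.enriched_presence
    base_p = rng_mod.beta(2.0, 2.0, size=config.n_modules)
    occ = np.zeros((config.n_mags, config.n_modules), dtype=bool)
    is_gut = np.array([m in gut_set for m in mag_ids])
    for k, mod in enumerate(module_ids):
        if mod in enriched:
            p_vec = np.where(is_gut, p_gut, p_other)
        else:
            p_vec = np.full(config.n_mags, base_p[k])
        occ[:, k] = rng_mod.random(config.n_mags) < p_vec
    completeness = np.where(
        occ,
        0.75 + 0.25 * rng_mod.beta(2.0, 1.0, size=occ.shape),
        0.75 * rng_mod.beta(1.5, 3.0, size=occ.shape),
    )
    modules = ModuleCompletenessMatrix(
        values=pd.DataFrame(completeness, index=mag_ids, columns=module_ids)
    )

    # --- gene table: module-annotated genes plus unannotated background
    rng_gene = _rng(seed, "genes")
    gene_mag_idx: list[int] = []
    gene_module: list[str] = []
    genes_per_module = 2
    extra_genes_per_mag = 15
    for i in range(config.n_mags):
        for k in range(config.n_modules):
            if occ[i, k]:
                gene_mag_idx.extend([i] * genes_per_module)
                gene_module.extend([module_ids[k]] * genes_per_module)
        gene_mag_idx.extend([i] * extra_genes_per_mag)
        gene_module.extend([""] * extra_genes_per_mag)
    n_genes = len(gene_mag_idx)
    gene_mag_idx = np.asarray(gene_mag_idx)
    cog_idx = rng_gene.integers(0, config.n_cog_functions, size=n_genes)
    gene_cog = np.asarray(cog_ids)[cog_idx]
    gene_cat = np.asarray(
        [_COG_CATEGORIES[i % len(_COG_CATEGORIES)] for i in cog_idx]
    )
    base_rate = np.exp(rng_gene.normal(np.log(5.0), 0.5, size=n_genes))

    shift_rows = np.isin(gene_cog, list(shifted_cogs))
    shifted_gut_cols = [
        col[s.sample_id] for s in samples
        if s.sample_type == "gut_day6" and s.substrate == config.shifted_substrate
    ]

    # realized phenotype effects (pick enriched modules when unspecified)
    if config.phenotype_effects is None:
        pool = sorted(enriched)
        rng_pheno_pick = _rng(seed, "phenotype_modules")
        picks = rng_pheno_pick.choice(pool, size=2, replace=False)
        effects: tuple[PhenotypeEffect, ...] = (
            PhenotypeEffect(str(picks[0]), "survival", 0.12),
            PhenotypeEffect(str(picks[1]), "conversion", -0.30),
        )
    else:
        effects = tuple(
            eff if eff.module_id is not None
            else replace(eff, module_id=sorted(enriched)[idx % len(enriched)])
            for idx, eff in enumerate(config.phenotype_effects)
        )

    rng_act = _rng(seed, "module_activity")
    activity = np.ones((n_genes, len(sample_ids)))
    gene_module_arr = np.asarray(gene_module)
    for eff in effects:
        rows = gene_module_arr == eff.module_id
        if not rows.any():
            continue
        act = np.exp(rng_act.normal(0.0, 0.5, size=n_gut_samples))
        for a, j in zip(act, gut_cols):
            activity[rows, j] *= a

    gnoise = np.exp(config.noise_sd
                    * rng_gene.normal(0.0, 1.0, size=(n_genes, len(sample_ids))))
    gcov = presence[gene_mag_idx, :] * base_rate[:, None] * activity * gnoise
    if shift_rows.any() and shifted_gut_cols:
        gcov[np.ix_(shift_rows, shifted_gut_cols)] *= config.cog_shift_fold

    rng_depth = _rng(seed, "depth")
    total_reads = pd.Series(
        rng_depth.integers(800_000, 1_200_000, size=len(sample_ids)),
        index=sample_ids, name="total_reads",
    )

    gene_frame = pd.DataFrame(
        {
            "gene_id": [f"gene_{i + 1:06d}" for i in range(n_genes)],
            "mag_id": [mag_ids[i] for i in gene_mag_idx],
            "cog_function": gene_cog,
            "cog_category": gene_cat,
            "cog_pathway": ["PWY_" + c for c in gene_cat],
            "kegg_module": gene_module,
        }
    )
    for j, sid in enumerate(sample_ids):
        gene_frame[sid] = gcov[:, j]
    genes = GeneFunctionTable(genes=gene_frame, total_reads=total_reads,
                              normalized=False)

    # --- phenotypes: linear in standardized module coverage + noise
    rng_ph = _rng(seed, "phenotypes")
    norm_factor = (1e6 / total_reads.loc[gut_sample_ids].to_numpy(float))
    pheno = pd.DataFrame(
        {
            "sample_id": gut_sample_ids,
            "survival": np.full(n_gut_samples, 0.6),
            "conversion": np.full(n_gut_samples, 1.5),
        }
    )
    for eff in effects:
        rows = (gene_module_arr == eff.module_id) & np.isin(
            np.asarray([mag_ids[i] for i in gene_mag_idx]), list(gut_set)
        )
        if not rows.any():
            continue
        x = gcov[np.ix_(rows, gut_cols)].mean(axis=0) * norm_factor
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        pheno[eff.phenotype] = pheno[eff.phenotype] + eff.slope * z
    pheno["survival"] += config.noise_sd * 0.1 * rng_ph.normal(size=n_gut_samples)
    pheno["conversion"] += config.noise_sd * 0.3 * rng_ph.normal(size=n_gut_samples)
    pheno["survival"] = pheno["survival"].clip(0.01, 0.99)
    pheno["conversion"] = pheno["conversion"].clip(0.01, None)
    phenotypes = PhenotypeTable(values=pheno)

    dataset = Dataset(
        catalog=catalog,
        samples=samples,
        coverage=coverage,
        modules=modules,
        genes=genes,
        phenotypes=phenotypes,
    )
    truth = SyntheticTruth(
        gut_related_mag_ids=gut_set,
        enriched_module_ids=enriched,
        phenotype_effects=effects,
        shifted_cog_ids=shifted_cogs,
        seed=seed,
    )
    return dataset, truth


@dataclass
class RecoveryReport:
    """Precision/recall of planted structure, serializable as a dict."""

    gut_precision: float
    gut_recall: float
    enrichment_precision: Optional[float] = None
    enrichment_recall: Optional[float] = None
    phenotype_sign_agreement: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "gut_precision": self.gut_precision,
            "gut_recall": self.gut_recall,
            "enrichment_precision": self.enrichment_precision,
            "enrichment_recall": self.enrichment_recall,
            "phenotype_sign_agreement": self.phenotype_sign_agreement,
        }


def _precision_recall(predicted: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def evaluate_recovery(
    truth: SyntheticTruth,
    gut_predicted: set[str],
    enrichment: Optional[pd.DataFrame] = None,
    correlations: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    ``enrichment`` is the module-enrichment table (significant =
    score > 2 and q < 0.05); ``correlations`` the module-phenotype
    screen.  ``seed`` must match the truth's seed when given; results
    from a different dataset cannot be scored.  Precision is 1.0 by
    convention when nothing is predicted.
    """
    if seed is not None and seed != truth.seed:
        raise ValueError(
            f"results seed {seed} does not match truth seed {truth.seed}"
        )
    gut_p, gut_r = _precision_recall(set(gut_predicted), truth.gut_related_mag_ids)
    report = RecoveryReport(gut_precision=gut_p, gut_recall=gut_r)

    if enrichment is not None:
        called = set(enrichment.index[enrichment["significant"]])
        enr_p, enr_r = _precision_recall(called, truth.enriched_module_ids)
        report.enrichment_precision = enr_p
        report.enrichment_recall = enr_r

    if correlations is not None and truth.phenotype_effects:
        agree = []
        for eff in truth.phenotype_effects:
            sel = correlations[
                (correlations["feature"] == eff.module_id)
                & (correlations["phenotype"] == eff.phenotype)
                & (~correlations["undefined"])
            ]
            if sel.empty:
                agree.append(0.0)
            else:
                r = float(sel["pearson_r"].iloc[0])
                agree.append(1.0 if np.sign(r) == np.sign(eff.slope) else 0.0)
        report.phenotype_sign_agreement = float(np.mean(agree)) if agree else None
    return report
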