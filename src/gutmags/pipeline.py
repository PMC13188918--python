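"""End-to-end orchestration: load -> normalize -> diversity/ordination ->
gut classification -> metabolic capacity -> enrichment -> differential ->
phenotype correlation, with a JSON run manifest.

Every stage writes its output tables to the run directory exactly once
and never mutates another stage's inputs, so re-running with the same
config and seed reproduces byte-identical numeric outputs (only the
manifest timestamp differs).
"""

from __future__ import annotations

import datetime
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import diversity as div
from . import differential as diff
from . import enrichment as enr
from . import gut as gut_mod
from . import mci as mci_mod
from . import normalize as norm
from . import phenotype as pheno_mod
from .datatypes import CoverageState, Dataset
from .io import load_dataset, validation_report, write_manifest
from .quality import classify_mimag, summarize_catalog


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    presence_threshold: float = 1e-4
    prevalence_threshold: float = 0.75
    prevalence_inclusive: bool = True
    module_occurrence_threshold: float = 0.75
    enrichment_score_threshold: float = 2.0
    enrichment_q_threshold: float = 0.05
    p_adj_suggestive: float = 0.1
    p_adj_significant: float = 0.05
    lfc_threshold: float = 1.0
    tpm_scale: float = 1e6
    negative_eigenvalue_policy: str = "drop"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.presence_threshold < 1.0):
            raise ValueError("presence_threshold must lie in [0, 1)")
        if not (0.0 < self.prevalence_threshold <= 1.0):
            raise ValueError("prevalence_threshold must lie in (0, 1]")
        if not (0.0 < self.module_occurrence_threshold <= 1.0):
            raise ValueError("module_occurrence_threshold must lie in (0, 1]")
        for t in (self.enrichment_q_threshold, self.p_adj_suggestive,
                  self.p_adj_significant):
            if not (0.0 < t < 1.0):
                raise ValueError("q / p_adj thresholds must lie in (0, 1)")
        if self.lfc_threshold < 0 or self.enrichment_score_threshold < 0:
            raise ValueError("score and fold-change thresholds must be >= 0")
        if self.tpm_scale <= 0:
            raise ValueError("tpm_scale must be positive")


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    dataset: Dataset
    catalog_summary: dict
    mimag: pd.Series
    tpm: "norm.CoverageMatrix"
    relative: "norm.CoverageMatrix"
    diversity: pd.DataFrame
    pcoa: div.PcoaResult
    classification: gut_mod.GutClassification
    mci: Optional[pd.Series] = None
    capacity_all: Optional[pd.DataFrame] = None
    capacity_gut: Optional[pd.DataFrame] = None
    enrichment: Optional[pd.DataFrame] = None
    mag_differential: Optional[pd.DataFrame] = None
    cog_differential: Optional[pd.DataFrame] = None
    category_differential: Optional[pd.DataFrame] = None
    module_correlations: Optional[pd.DataFrame] = None
    capacity_correlations: Optional[pd.DataFrame] = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    dataset: Dataset,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str | os.PathLike] = None,
) -> PipelineResult:
    """Run every stage the dataset's tables allow.

    Stages needing the module, gene or phenotype table are skipped (not
    faked) when that table is absent.  When ``out_dir`` is given, each
    stage's table is written as TSV and a JSON manifest records the
    config, seed, and per-stage row counts.
    """
    config = config or RunConfig()
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed,
                      "stages": {}, "census": validation_report(dataset)}

    def _save(name: str, frame: pd.DataFrame, **kwargs) -> None:
        manifest["stages"][name] = {"rows": int(len(frame))}
        if out is not None:
            frame.to_csv(out / f"{name}.tsv", sep="\t", **kwargs)

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    # quality overview
    mimag = _stage("mimag", lambda: classify_mimag(dataset.catalog))
    summary = _stage("catalog_summary", lambda: summarize_catalog(dataset.catalog))
    _save("mimag", mimag.to_frame(), index_label="mag_id")
    manifest["catalog_summary"] = summary

    # normalization
    lengths = pd.Series({m.mag_id: m.genome_length for m in dataset.catalog})
    tpm = _stage("tpm_normalize",
                 lambda: norm.tpm_normalize(dataset.coverage, lengths,
                                            scale=config.tpm_scale))
    rel = _stage("relative_abundance", lambda: norm.relative_abundance(tpm))
    _save("coverage_tpm", tpm.values, index_label="mag_id")

    # diversity and ordination
    profile = _stage("diversity",
                     lambda: div.diversity_profile(rel, dataset))
    _save("diversity", profile.table)
    presence = _stage(
        "presence",
        lambda: gut_mod.presence_matrix(rel, config.presence_threshold),
    )
    dist = _stage("binary_distance", lambda: div.binary_distance(presence))
    ord_res = _stage(
        "pcoa",
        lambda: div.pcoa(dist, config.negative_eigenvalue_policy),
    )
    _save("pcoa_coordinates", ord_res.coordinates, index_label="sample_id")
    manifest["pcoa_percent_variance"] = [float(v) for v in ord_res.percent_variance]

    # gut classification
    classification = _stage(
        "classify_gut",
        lambda: gut_mod.classify_gut_related(
            presence, dataset.samples,
            prevalence_threshold=config.prevalence_threshold,
            presence_threshold=config.presence_threshold,
            inclusive=config.prevalence_inclusive,
        ),
    )
    _save("gut_classification", classification.table)
    manifest["n_gut_related"] = int(classification.table["gut_related"].sum())

    result = PipelineResult(
        dataset=dataset, catalog_summary=summary, mimag=mimag, tpm=tpm,
        relative=rel, diversity=profile.table, pcoa=ord_res,
        classification=classification,
    )

    # metabolic capacity and enrichment need the module table
    if dataset.modules is not None:
        mci_series = _stage(
            "mci", lambda: mci_mod.mci_table(dataset.modules, dataset.catalog)
        )
        _save("mci", mci_series.to_frame(), index_label="mag_id")
        result.mci = mci_series
        result.capacity_all = _stage(
            "capacity_all",
            lambda: mci_mod.sample_metabolic_capacity(mci_series, presence),
        )
        result.capacity_gut = _stage(
            "capacity_gut",
            lambda: mci_mod.sample_metabolic_capacity(
                mci_series, presence, classification.gut_related_ids
            ),
        )
        _save("capacity_all", result.capacity_all)
        _save("capacity_gut", result.capacity_gut)
        result.enrichment = _stage(
            "enrichment",
            lambda: enr.enrichment_by_gut_class(
                dataset.modules, classification,
                occurrence_threshold=config.module_occurrence_threshold,
                score_threshold=config.enrichment_score_threshold,
                q_threshold=config.enrichment_q_threshold,
            ),
        )
        _save("enrichment", result.enrichment)

    # MAG-level differential abundance
    result.mag_differential = _stage(
        "wilcoxon_mags",
        lambda: diff.wilcoxon_pairwise(tpm, dataset.samples),
    )
    _save("mag_differential", result.mag_differential, index=False)

    # COG-level differential needs the gene table
    genes_norm = None
    if dataset.genes is not None:
        genes_norm = _stage(
            "depth_normalize", lambda: norm.depth_normalize_genes(dataset.genes)
        )
        result.cog_differential = _stage(
            "ttest_cogs",
            lambda: diff.ttest_cog_differential(
                genes_norm, dataset.samples, lfc_threshold=config.lfc_threshold
            ),
        )
        _save("cog_differential", result.cog_differential, index=False)
        cat_sums = norm.aggregate_genes_by(genes_norm, "cog_category")
        result.category_differential = _stage(
            "dunn_categories",
            lambda: diff.dunn_category_test(cat_sums, dataset.samples),
        )
        _save("category_differential", result.category_differential, index=False)

    # phenotype correlation needs genes + phenotypes
    if genes_norm is not None and dataset.phenotypes is not None:
        result.module_correlations = _stage(
            "module_correlations",
            lambda: pheno_mod.module_phenotype_screen(
                dataset, genes_norm, classification
            ),
        )
        _save("module_correlations", result.module_correlations, index=False)
        if result.capacity_all is not None:
            gut_ids = dataset.samples_of("gut_day6")
            result.capacity_correlations = _stage(
                "capacity_correlations",
                lambda: pheno_mod.capacity_phenotype_correlations(
                    result.capacity_all, result.capacity_gut,
                    dataset.phenotypes, gut_ids,
                ),
            )
            _save("capacity_correlations", result.capacity_correlations,
                  index=False)

    if out is not None:
        manifest["timestamp"] = datetime.datetime.now().isoformat()
        write_manifest(out / "manifest.json", **manifest)
    return result
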