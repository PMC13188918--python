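"""Correlating microbial functional capacity with host performance.

Per gut sample, a functional feature is either the mean depth-
normalized coverage of the genes annotated to one KEGG module within
the gut-related MAGs, or the summed/mean metabolic capacity (MCI) of a
sample.  Each feature is related to larval survival (fraction of eggs
reaching larva/pupa) and feed conversion (dry larval mass per dry
substrate mass lost) with Pearson correlation and ordinary least
squares, one point per gut replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    Dataset,
    GeneFunctionTable,
    GutClassification,
    PhenotypeTable,
    SampleRecord,
)
from .enrichment import bh_adjust

PHENOTYPES = ("survival", "conversion")


@dataclass
class ModuleCoverage:
    """Per-sample mean module coverage plus substrate baselines."""

    per_sample: pd.Series          # all samples
    baseline_day0: float           # mean over day-0 substrate samples
    baseline_day6_substrate: float # mean over day-6 substrate samples


def module_sample_coverage(
    genes: GeneFunctionTable,
    classification: GutClassification,
    module_id: str,
    samples: list[SampleRecord],
) -> ModuleCoverage:
    """Mean normalized coverage of a module's genes in gut-related MAGs.

    Per sample, the mean is over genes annotated to ``module_id`` that
    belong to gut-related MAGs.  The day-0 and day-6 substrate
    baselines (the dashed reference lines of the correlation plots)
    average the per-sample means over those sample groups.
    """
    if not genes.normalized:
        raise ValueError("gene table must be depth-normalized first")
    gut_ids = classification.gut_related_ids
    mask = (genes.genes["kegg_module"] == module_id) & genes.genes["mag_id"].isin(
        gut_ids
    )
    if not mask.any():
        raise ValueError(
            f"module {module_id!r} has no annotated genes in gut-related MAGs"
        )
    sample_ids = genes.sample_ids
    per_sample = genes.genes.loc[mask, sample_ids].mean(axis=0)
    per_sample.name = module_id

    day0 = [s.sample_id for s in samples if s.sample_type == "substrate_day0"]
    day6 = [s.sample_id for s in samples if s.sample_type == "substrate_day6"]
    return ModuleCoverage(
        per_sample=per_sample,
        baseline_day0=float(per_sample[day0].mean()) if day0 else float("nan"),
        baseline_day6_substrate=float(per_sample[day6].mean()) if day6 else float("nan"),
    )


def correlate_with_phenotype(
    x: pd.Series,
    phenotypes: PhenotypeTable,
    phenotype: str,
    feature: str = "feature",
) -> dict:
    """Pearson r plus OLS slope/intercept of phenotype on feature ``x``.

    ``x`` is indexed by gut sample_id.  Needs >= 3 paired observations;
    zero variance in either variable is flagged 'undefined' with no
    numeric correlation.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    pheno = phenotypes.values.set_index("sample_id")[phenotype]
    common = [s for s in x.index if s in pheno.index]
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    xv = x.loc[common].to_numpy(float)
    yv = pheno.loc[common].to_numpy(float)
    base = {"feature": feature, "phenotype": phenotype, "n": len(common)}
    if np.std(xv) == 0.0 or np.std(yv) == 0.0:
        return {**base, "undefined": True, "pearson_r": None, "slope": None,
                "intercept": None, "p": None}
    fit = stats.linregress(xv, yv)
    return {
        **base,
        "undefined": False,
        "pearson_r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p": float(fit.pvalue),
    }


def module_phenotype_screen(
    dataset: Dataset,
    genes: GeneFunctionTable,
    classification: GutClassification,
    modules: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Correlate every qualifying module with survival and conversion.

    Modules without genes in gut-related MAGs are skipped.  BH q-values
    are reported per phenotype alongside raw p (the screen is
    exploratory; no threshold is privileged).
    """
    if dataset.phenotypes is None:
        raise ValueError("dataset has no phenotype table")
    gut_ids = [s.sample_id for s in dataset.samples if s.sample_type == "gut_day6"]
    if modules is None:
        annotated = genes.genes.loc[
            genes.genes["mag_id"].isin(classification.gut_related_ids), "kegg_module"
        ]
        modules = sorted(set(annotated) - {""})
    rows = []
    for module_id in modules:
        try:
            cov = module_sample_coverage(genes, classification, module_id,
                                         dataset.samples)
        except ValueError:
            continue
        x = cov.per_sample[gut_ids]
        for phenotype in PHENOTYPES:
            row = correlate_with_phenotype(x, dataset.phenotypes, phenotype,
                                           feature=module_id)
            row["baseline_day0"] = cov.baseline_day0
            row["baseline_day6_substrate"] = cov.baseline_day6_substrate
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for phenotype in PHENOTYPES:
        sel = (out["phenotype"] == phenotype) & (~out["undefined"])
        if sel.any():
            out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"].to_numpy(float))
    return out


def capacity_phenotype_correlations(
    capacity_all: pd.DataFrame,
    capacity_gut: pd.DataFrame,
    phenotypes: PhenotypeTable,
    gut_sample_ids: list[str],
) -> pd.DataFrame:
    """Summed and mean metabolic capacity vs both phenotypes, for the
    all-MAG and gut-related-MAG capacity tables (the paired contrast is
    always reported; neither outcome is asserted)."""
    rows = []
    for label, table in (("all", capacity_all), ("gut_related", capacity_gut)):
        for measure in ("summed_capacity", "mean_capacity"):
            x = table.loc[[s for s in gut_sample_ids if s in table.index], measure]
            for phenotype in PHENOTYPES:
                row = correlate_with_phenotype(
                    x, phenotypes, phenotype, feature=f"{measure}[{label}]"
                )
                row["mag_subset"] = label
                row["measure"] = measure
                rows.append(row)
    return pd.DataFrame(rows)
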