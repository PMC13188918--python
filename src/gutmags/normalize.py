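"""Coverage and gene-coverage normalizations.

MAG abundance starts as mean read coverage per genome.  Before
analysis it is length-normalized and sum-normalized with the standard
transcripts-per-million (TPM) scheme: coverage is divided by genome
length in kilobases, then each sample column is scaled so the rates
sum to a fixed constant (1e6 by default).  Gene coverage is
depth-normalized to counts per million using per-sample total read
counts.  Relative abundance (columns summing to 1) feeds presence /
prevalence analyses, and genus-level aggregation sums member MAG rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GENE_ANNOTATION_COLUMNS,
    TAXONOMY_RANKS,
    CoverageMatrix,
    CoverageState,
    GeneFunctionTable,
    MagRecord,
)


def tpm_normalize(coverage: CoverageMatrix, lengths: pd.Series,
                  scale: float = 1e6) -> CoverageMatrix:
    """Length-normalize then sum-normalize mean coverage (TPM scheme).

    ``lengths`` maps mag_id to genome length in bases.  Per sample,
    rate_i = coverage_i / (length_i / 1000) and the output is
    rate_i / sum(rates) * scale.  All-zero samples stay all-zero.
    """
    if coverage.state is not CoverageState.RAW:
        raise ValueError(f"expected raw mean coverage, got {coverage.state.value}")
    missing = set(coverage.mag_ids) - set(lengths.index)
    if missing:
        raise ValueError(f"no genome length for mag_id(s): {sorted(missing)[:5]}")
    lens = lengths.loc[coverage.mag_ids].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive genome length for {bad!r}")
    rates = coverage.values.div(lens / 1000.0, axis=0)
    sums = rates.sum(axis=0)
    out = rates.div(sums.where(sums > 0, 1.0), axis=1) * scale
    out.loc[:, sums == 0] = 0.0
    return CoverageMatrix(values=out, state=CoverageState.SUM_NORMALIZED)


def relative_abundance(coverage: CoverageMatrix) -> CoverageMatrix:
    """Scale each sample column to sum to 1; zero columns are preserved."""
    sums = coverage.values.sum(axis=0)
    out = coverage.values.div(sums.where(sums > 0, 1.0), axis=1)
    out.loc[:, sums == 0] = 0.0
    return CoverageMatrix(values=out, state=CoverageState.RELATIVE)


def depth_normalize_genes(genes: GeneFunctionTable,
                          scale: float = 1e6) -> GeneFunctionTable:
    """Scale gene coverage to counts per million of total sample reads."""
    if genes.normalized:
        raise ValueError("gene table is already depth-normalized")
    sample_ids = genes.sample_ids
    missing = set(sample_ids) - set(genes.total_reads.index)
    if missing:
        raise ValueError(f"total_reads missing for sample(s): {sorted(missing)[:5]}")
    out = genes.genes.copy()
    factors = scale / genes.total_reads.loc[sample_ids].astype(float)
    out[sample_ids] = out[sample_ids].mul(factors, axis=1)
    return GeneFunctionTable(genes=out, total_reads=genes.total_reads, normalized=True)


def aggregate_by_taxon(coverage: CoverageMatrix, catalog: list[MagRecord],
                       rank: str) -> pd.DataFrame:
    """Sum MAG rows per taxon at ``rank``; empty ranks become 'unassigned'."""
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r}")
    labels = {m.mag_id: (m.rank(rank) or "unassigned") for m in catalog}
    missing = set(coverage.mag_ids) - set(labels)
    if missing:
        raise ValueError(f"catalog lacks mag_id(s): {sorted(missing)[:5]}")
    groups = pd.Series({m: labels[m] for m in coverage.mag_ids})
    return coverage.values.groupby(groups).sum()


def aggregate_genes_by(genes: GeneFunctionTable, by: str) -> pd.DataFrame:
    """Sum normalized gene coverage per annotation level ('cog_function',
    'cog_category', 'cog_pathway' or 'kegg_module') across samples."""
    if by not in GENE_ANNOTATION_COLUMNS or by in ("gene_id", "mag_id"):
        raise ValueError(f"cannot aggregate genes by {by!r}")
    sample_ids = genes.sample_ids
    df = genes.genes[[by] + sample_ids]
    df = df[df[by] != ""]
    return df.groupby(by)[sample_ids].sum()
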