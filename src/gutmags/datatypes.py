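"""Core containers shared by every analysis stage.

The pipeline operates on a small set of tabular objects: a MAG catalog
(one record per metagenome-assembled genome with taxonomy and assembly
quality), a sample sheet describing the rearing design (substrate type,
day-0 / day-6 substrate, day-6 larval gut), a MAG x sample coverage
matrix with an explicit normalization state, a MAG x KEGG-module
completeness matrix, a long gene table with COG annotations and
per-sample coverage, and per-replicate host phenotypes (survival and
feed conversion).  Matrices are pandas DataFrames wrapped in light
dataclasses so that the normalization state and cross-references travel
with the numbers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")

DOMAINS = ("archaea", "bacteria", "eukaryote")
SAMPLE_TYPES = ("substrate_day0", "substrate_day6", "gut_day6")
SUBSTRATES = ("brewery", "bran_grass", "sludge")


class CoverageState(str, enum.Enum):
    """Normalization state of a coverage matrix."""

    RAW = "raw_mean_coverage"
    LENGTH_NORMALIZED = "length_normalized"
    SUM_NORMALIZED = "sum_normalized"
    RELATIVE = "relative"


@dataclass(frozen=True)
class MagRecord:
    """Identity, taxonomy and assembly quality of one MAG.

    ``completion`` and ``redundancy`` are percentages estimated from
    single-copy core genes; ``has_5s``/``has_16s``/``has_23s`` and
    ``n_trnas`` feed the MIMAG quality tiering.  Missing taxonomy ranks
    are encoded as empty strings.
    """

    mag_id: str
    domain: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    genome_length: int = 1
    completion: float = 0.0
    redundancy: float = 0.0
    n_contigs: int = 1
    n50: int = 0
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False
    n_trnas: int = 0
    unbinned: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.taxonomy) - set(TAXONOMY_RANKS)
        if unknown:
            raise ValueError(f"unknown taxonomy rank(s) {sorted(unknown)}")
        # canonical form: only non-empty ranks are stored
        object.__setattr__(
            self, "taxonomy", {r: v for r, v in self.taxonomy.items() if v}
        )
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.mag_id}")
        if not (0.0 <= self.completion <= 100.0):
            raise ValueError(
                f"completion {self.completion} outside [0, 100] for {self.mag_id}"
            )
        if self.redundancy < 0:
            raise ValueError(f"negative redundancy for {self.mag_id}")
        if self.genome_length <= 0:
            raise ValueError(f"genome_length must be positive for {self.mag_id}")
        if self.n_contigs < 1:
            raise ValueError(f"n_contigs must be >= 1 for {self.mag_id}")
        if self.n_trnas < 0:
            raise ValueError(f"n_trnas must be >= 0 for {self.mag_id}")

    def rank(self, name: str) -> str:
        if name not in TAXONOMY_RANKS:
            raise KeyError(f"unknown taxonomy rank {name!r}")
        return self.taxonomy.get(name, "")


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample of the rearing experiment."""

    sample_id: str
    sample_type: str
    substrate: str
    replicate: int

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class CoverageMatrix:
    """MAG x sample abundance grid plus its normalization state."""

    values: pd.DataFrame
    state: CoverageState = CoverageState.RAW

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "mag_id"
        self.values.columns.name = None
        if (self.values.to_numpy() < 0).any():
            bad = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                "negative coverage at row "
                f"{self.values.index[bad[0]]!r}, column {self.values.columns[bad[1]]!r}"
            )
        if self.state is CoverageState.RELATIVE:
            sums = self.values.sum(axis=0).to_numpy()
            ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
            if not ok.all():
                raise ValueError("relative coverage columns must each sum to 1 or 0")

    @property
    def mag_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, state: CoverageState) -> "CoverageMatrix":
        return CoverageMatrix(values=values, state=state)


@dataclass
class ModuleCompletenessMatrix:
    """MAG x KEGG-module completeness fractions in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "mag_id"
        self.values.columns.name = None
        arr = self.values.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("module completeness entries must lie in [0, 1]")

    @property
    def module_ids(self) -> list[str]:
        return list(self.values.columns)


GENE_ANNOTATION_COLUMNS = (
    "gene_id",
    "mag_id",
    "cog_function",
    "cog_category",
    "cog_pathway",
    "kegg_module",
)


@dataclass
class GeneFunctionTable:
    """Per-gene COG/KEGG annotations with per-sample coverage.

    ``genes`` is wide: the annotation columns above followed by one
    float column per sample.  ``total_reads`` maps sample_id to the
    sequencing depth used for counts-per-million normalization.
    ``normalized`` records whether depth normalization was applied.
    """

    genes: pd.DataFrame
    total_reads: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in GENE_ANNOTATION_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table is missing columns {missing}")
        if (self.total_reads <= 0).any():
            bad = self.total_reads.index[self.total_reads <= 0][0]
            raise ValueError(f"total_reads must be positive (sample {bad!r})")
        cov = self.genes[self.sample_ids].to_numpy()
        if (cov < 0).any():
            raise ValueError("gene coverage must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.genes.columns if c not in GENE_ANNOTATION_COLUMNS]


@dataclass
class PhenotypeTable:
    """Per gut-sample host phenotypes: survival fraction, conversion ratio."""

    values: pd.DataFrame  # columns: sample_id, survival, conversion

    def __post_init__(self) -> None:
        required = {"sample_id", "survival", "conversion"}
        if not required.issubset(self.values.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.values["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in phenotype table")
        surv = self.values["survival"].to_numpy(float)
        if ((surv < 0) | (surv > 1)).any():
            raise ValueError("survival must be a fraction in [0, 1]")
        if (self.values["conversion"].to_numpy(float) < 0).any():
            raise ValueError("conversion must be nonnegative")


@dataclass
class Dataset:
    """A complete (or partial) set of input tables, cross-validated."""

    catalog: list[MagRecord]
    samples: list[SampleRecord]
    coverage: CoverageMatrix
    modules: Optional[ModuleCompletenessMatrix] = None
    genes: Optional[GeneFunctionTable] = None
    phenotypes: Optional[PhenotypeTable] = None

    @property
    def mag_ids(self) -> list[str]:
        return [m.mag_id for m in self.catalog]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_of(self, sample_type: str | None = None,
                   substrate: str | None = None) -> list[str]:
        """Sample ids filtered by type and/or substrate."""
        out = []
        for s in self.samples:
            if sample_type is not None and s.sample_type != sample_type:
                continue
            if substrate is not None and s.substrate != substrate:
                continue
            out.append(s.sample_id)
        return out

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "sample_type": s.sample_type,
                    "substrate": s.substrate,
                    "replicate": s.replicate,
                }
                for s in self.samples
            ]
        )

    def catalog_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.catalog:
            row = {
                "mag_id": m.mag_id,
                "domain": m.domain,
                **{r: m.rank(r) for r in TAXONOMY_RANKS},
                "genome_length": m.genome_length,
                "completion": m.completion,
                "redundancy": m.redundancy,
                "n_contigs": m.n_contigs,
                "n50": m.n50,
                "has_5s": m.has_5s,
                "has_16s": m.has_16s,
                "has_23s": m.has_23s,
                "n_trnas": m.n_trnas,
                "unbinned": m.unbinned,
            }
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class GutClassification:
    """Per-MAG prevalence evidence and the gut-related verdict."""

    table: pd.DataFrame  # index mag_id; gut_prevalence, start_prevalence, gut_related
    presence_threshold: float
    prevalence_threshold: float

    @property
    def gut_related_ids(self) -> set[str]:
        return set(self.table.index[self.table["gut_related"]])


__all__ = [
    "TAXONOMY_RANKS",
    "DOMAINS",
    "SAMPLE_TYPES",
    "SUBSTRATES",
    "CoverageState",
    "MagRecord",
    "SampleRecord",
    "CoverageMatrix",
    "ModuleCompletenessMatrix",
    "GeneFunctionTable",
    "GENE_ANNOTATION_COLUMNS",
    "PhenotypeTable",
    "Dataset",
    "GutClassification",
    "replace",
]
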