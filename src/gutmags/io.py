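"""Reading, validating and writing the tabular inputs and outputs.

All tables are plain UTF-8 text with a mandatory header row; tab is the
preferred delimiter and comma is accepted (auto-detected from the
header line).  A dataset lives in one directory with fixed file names:

    catalog.tsv       MAG catalog (taxonomy + assembly quality)
    samples.tsv       sample sheet (sample_type, substrate, replicate)
    coverage.tsv      MAG x sample mean coverage (mag_id key column)
    modules.tsv       MAG x KEGG-module completeness  [optional]
    genes.tsv         gene annotations + per-sample coverage  [optional]
    total_reads.tsv   per-sample sequencing depth  [with genes.tsv]
    phenotypes.tsv    survival / conversion per gut sample  [optional]

``load_dataset`` validates every cross-reference (duplicate ids,
unknown samples, negative values) and logs a per-group sample census.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .datatypes import (
    GENE_ANNOTATION_COLUMNS,
    TAXONOMY_RANKS,
    CoverageMatrix,
    CoverageState,
    Dataset,
    GeneFunctionTable,
    MagRecord,
    ModuleCompletenessMatrix,
    PhenotypeTable,
    SampleRecord,
)

logger = logging.getLogger(__name__)

TABLE_FILES = {
    "catalog": "catalog.tsv",
    "samples": "samples.tsv",
    "coverage": "coverage.tsv",
    "modules": "modules.tsv",
    "genes": "genes.tsv",
    "total_reads": "total_reads.tsv",
    "phenotypes": "phenotypes.tsv",
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)


def _to_bool(value: str, context: str) -> bool:
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"cannot parse boolean {value!r} in {context}") from None


def read_catalog(path: Path) -> list[MagRecord]:
    df = _read_table(path)
    records: list[MagRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        mag_id = row["mag_id"]
        if mag_id in seen:
            raise ValueError(f"duplicate mag_id {mag_id!r} in catalog")
        seen.add(mag_id)
        records.append(
            MagRecord(
                mag_id=mag_id,
                domain=row["domain"],
                taxonomy={r: row.get(r, "") for r in TAXONOMY_RANKS},
                genome_length=int(row["genome_length"]),
                completion=float(row["completion"]),
                redundancy=float(row["redundancy"]),
                n_contigs=int(row.get("n_contigs", 1) or 1),
                n50=int(row.get("n50", 0) or 0),
                has_5s=_to_bool(row.get("has_5s", "false"), f"catalog {mag_id}"),
                has_16s=_to_bool(row.get("has_16s", "false"), f"catalog {mag_id}"),
                has_23s=_to_bool(row.get("has_23s", "false"), f"catalog {mag_id}"),
                n_trnas=int(row.get("n_trnas", 0) or 0),
                unbinned=_to_bool(row.get("unbinned", "false"), f"catalog {mag_id}"),
            )
        )
    return records


def read_samples(path: Path) -> list[SampleRecord]:
    df = _read_table(path)
    records: list[SampleRecord] = []
    seen_ids: set[str] = set()
    seen_keys: set[tuple] = set()
    for _, row in df.iterrows():
        rec = SampleRecord(
            sample_id=row["sample_id"],
            sample_type=row["sample_type"],
            substrate=row["substrate"],
            replicate=int(row["replicate"]),
        )
        if rec.sample_id in seen_ids:
            raise ValueError(f"duplicate sample_id {rec.sample_id!r}")
        key = (rec.sample_type, rec.substrate, rec.replicate)
        if key in seen_keys:
            raise ValueError(f"duplicate sample key {key}")
        seen_ids.add(rec.sample_id)
        seen_keys.add(key)
        records.append(rec)
    return records


def read_matrix(path: Path, key: str = "mag_id") -> pd.DataFrame:
    df = _read_table(path)
    if key not in df.columns:
        raise ValueError(f"{path} lacks key column {key!r}")
    if df[key].duplicated().any():
        dup = df.loc[df[key].duplicated(), key].iloc[0]
        raise ValueError(f"duplicate {key} {dup!r} in {path.name}")
    out = df.set_index(key)
    return out.astype(float)


def load_dataset(directory: str | os.PathLike,
                 paths: Optional[Mapping[str, str | os.PathLike]] = None) -> Dataset:
    """Load and cross-validate a dataset directory.

    ``paths`` may override individual table locations.  The module,
    gene and phenotype tables are optional; stages that need a missing
    table refuse to run rather than improvising.
    """
    directory = Path(directory)
    loc = {k: directory / v for k, v in TABLE_FILES.items()}
    if paths:
        loc.update({k: Path(v) for k, v in paths.items()})

    catalog = read_catalog(loc["catalog"])
    samples = read_samples(loc["samples"])
    mag_ids = {m.mag_id for m in catalog}
    sample_ids = {s.sample_id for s in samples}

    cov = read_matrix(loc["coverage"])
    unknown_mags = set(cov.index) - mag_ids
    if unknown_mags:
        raise ValueError(
            f"coverage rows reference unknown mag_id(s): {sorted(unknown_mags)[:5]}"
        )
    unknown_samples = set(cov.columns) - sample_ids
    if unknown_samples:
        raise ValueError(
            f"coverage columns reference unknown sample_id(s): {sorted(unknown_samples)[:5]}"
        )
    coverage = CoverageMatrix(values=cov, state=CoverageState.RAW)

    modules = None
    if loc["modules"].exists():
        mod = read_matrix(loc["modules"])
        unknown = set(mod.index) - mag_ids
        if unknown:
            raise ValueError(
                f"module rows reference unknown mag_id(s): {sorted(unknown)[:5]}"
            )
        modules = ModuleCompletenessMatrix(values=mod)

    genes = None
    if loc["genes"].exists():
        gdf = _read_table(loc["genes"])
        missing = [c for c in GENE_ANNOTATION_COLUMNS if c not in gdf.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        cov_cols = [c for c in gdf.columns if c not in GENE_ANNOTATION_COLUMNS]
        unknown = set(cov_cols) - sample_ids
        if unknown:
            raise ValueError(
                f"gene table columns reference unknown sample_id(s): {sorted(unknown)[:5]}"
            )
        unknown = set(gdf["mag_id"]) - mag_ids
        if unknown:
            raise ValueError(
                f"gene table references unknown mag_id(s): {sorted(unknown)[:5]}"
            )
        gdf[cov_cols] = gdf[cov_cols].astype(float)
        tr = _read_table(loc["total_reads"]).set_index("sample_id")["total_reads"]
        tr = tr.astype(int)
        missing_depth = set(cov_cols) - set(tr.index)
        if missing_depth:
            raise ValueError(
                f"total_reads missing for sample(s): {sorted(missing_depth)[:5]}"
            )
        genes = GeneFunctionTable(genes=gdf, total_reads=tr, normalized=False)

    phenotypes = None
    if loc["phenotypes"].exists():
        pdf = _read_table(loc["phenotypes"])
        pdf["survival"] = pdf["survival"].astype(float)
        pdf["conversion"] = pdf["conversion"].astype(float)
        unknown = set(pdf["sample_id"]) - sample_ids
        if unknown:
            raise ValueError(
                f"phenotype table references unknown sample_id(s): {sorted(unknown)[:5]}"
            )
        phenotypes = PhenotypeTable(values=pdf)

    ds = Dataset(
        catalog=catalog,
        samples=samples,
        coverage=coverage,
        modules=modules,
        genes=genes,
        phenotypes=phenotypes,
    )
    census = validation_report(ds)
    logger.info("loaded dataset: %s", json.dumps(census))
    return ds


def validation_report(ds: Dataset) -> dict:
    """Counts per sample type and substrate plus table shapes."""
    census: dict = {"n_mags": len(ds.catalog), "samples": {}}
    for s in ds.samples:
        key = f"{s.sample_type}/{s.substrate}"
        census["samples"][key] = census["samples"].get(key, 0) + 1
    census["n_modules"] = (
        len(ds.modules.module_ids) if ds.modules is not None else 0
    )
    census["n_genes"] = len(ds.genes.genes) if ds.genes is not None else 0
    census["n_phenotype_rows"] = (
        len(ds.phenotypes.values) if ds.phenotypes is not None else 0
    )
    return census


def write_dataset(ds: Dataset, directory: str | os.PathLike) -> None:
    """Write all tables of ``ds`` in the layout ``load_dataset`` reads.

    Floats are serialized with ``repr`` round-trip precision so a
    write/read cycle reproduces every numeric cell bit for bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ds.catalog_frame().to_csv(directory / TABLE_FILES["catalog"], sep="\t", index=False)
    ds.sample_frame().to_csv(directory / TABLE_FILES["samples"], sep="\t", index=False)
    ds.coverage.values.to_csv(
        directory / TABLE_FILES["coverage"], sep="\t", index_label="mag_id"
    )
    if ds.modules is not None:
        ds.modules.values.to_csv(
            directory / TABLE_FILES["modules"], sep="\t", index_label="mag_id"
        )
    if ds.genes is not None:
        ds.genes.genes.to_csv(directory / TABLE_FILES["genes"], sep="\t", index=False)
        ds.genes.total_reads.rename("total_reads").to_csv(
            directory / TABLE_FILES["total_reads"], sep="\t", index_label="sample_id"
        )
    if ds.phenotypes is not None:
        ds.phenotypes.values.to_csv(
            directory / TABLE_FILES["phenotypes"], sep="\t", index=False
        )


def write_manifest(path: str | os.PathLike, **entries) -> None:
    """JSON run manifest (inputs, config, seed, package version)."""
    from . import __version__

    payload = {"package_version": __version__, **entries}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
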