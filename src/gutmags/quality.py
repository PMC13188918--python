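"""MIMAG-style quality tiering and catalog summaries.

A bin qualifies as a medium-quality draft genome at >= 50% completion
and < 10% redundancy.  High quality additionally requires > 90%
completion, < 5% redundancy, all three rRNA genes (5S, 16S, 23S) and
at least 18 tRNAs.  Everything else is below medium.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .datatypes import MagRecord

QUALITY_LABELS = ("high", "medium", "below_medium")


def classify_mimag_record(mag: MagRecord) -> str:
    """Quality label for a single MAG; pure function of the quality fields."""
    if (
        mag.completion > 90.0
        and mag.redundancy < 5.0
        and mag.has_5s
        and mag.has_16s
        and mag.has_23s
        and mag.n_trnas >= 18
    ):
        return "high"
    if mag.completion >= 50.0 and mag.redundancy < 10.0:
        return "medium"
    return "below_medium"


def classify_mimag(catalog: list[MagRecord]) -> pd.Series:
    """Per-MAG quality label in {high, medium, below_medium}."""
    return pd.Series(
        {m.mag_id: classify_mimag_record(m) for m in catalog}, name="mimag_quality"
    ).loc[[m.mag_id for m in catalog]]


def summarize_catalog(catalog: list[MagRecord]) -> dict:
    """Counts by domain, bacterial phylum percentages and MIMAG tiers.

    Phylum percentages are computed over bacterial MAGs only; MAGs with
    an empty phylum are excluded from the percentage denominator and
    tallied under ``unassigned`` counts.
    """
    if not catalog:
        raise ValueError("empty catalog")
    domains = Counter(m.domain for m in catalog)
    quality = Counter(classify_mimag_record(m) for m in catalog)

    bacteria = [m for m in catalog if m.domain == "bacteria"]
    phylum_counts = Counter(m.rank("phylum") for m in bacteria if m.rank("phylum"))
    n_assigned = sum(phylum_counts.values())
    phylum_pct = {
        ph: 100.0 * n / n_assigned for ph, n in phylum_counts.items()
    } if n_assigned else {}

    return {
        "n_mags": len(catalog),
        "domain_counts": dict(domains),
        "mimag_counts": {label: quality.get(label, 0) for label in QUALITY_LABELS},
        "medium_or_better": quality.get("high", 0) + quality.get("medium", 0),
        "bacterial_phylum_counts": dict(phylum_counts),
        "bacterial_phylum_percent": phylum_pct,
        "bacteria_unassigned_phylum": len(bacteria) - n_assigned,
    }
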