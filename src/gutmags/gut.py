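"""Presence, prevalence, and the gut-related MAG decision rule.

A MAG counts as present in a sample when its relative abundance
strictly exceeds a threshold (default 1e-4).  A MAG is gut-related
when it is present in at least 75% of day-6 larval gut samples
(pooled across substrates) and in none of the day-0 substrate
samples.  Day-6 substrate samples play no role in the rule.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import (
    CoverageMatrix,
    CoverageState,
    GutClassification,
    SampleRecord,
)

DEFAULT_PRESENCE_THRESHOLD = 1e-4
DEFAULT_PREVALENCE_THRESHOLD = 0.75


def presence_matrix(coverage: CoverageMatrix,
                    threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> pd.DataFrame:
    """Boolean MAG x sample grid: value strictly above ``threshold``."""
    if coverage.state is not CoverageState.RELATIVE:
        raise ValueError("presence_matrix expects a relative-abundance matrix")
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    return coverage.values > threshold


def prevalence(presence: pd.DataFrame, sample_ids: list[str]) -> pd.Series:
    """Per-MAG fraction of the given samples in which it is present."""
    if not sample_ids:
        raise ValueError("empty sample subset")
    missing = set(sample_ids) - set(presence.columns)
    if missing:
        raise ValueError(f"unknown sample_id(s): {sorted(missing)[:5]}")
    return presence[sample_ids].mean(axis=1)


def classify_gut_related(
    presence: pd.DataFrame,
    samples: list[SampleRecord],
    prevalence_threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    inclusive: bool = True,
) -> GutClassification:
    """Apply the prevalence rule for gut-related MAGs.

    ``inclusive`` controls the boundary at the prevalence threshold
    (>= when True, strict > otherwise); with real replicate counts no
    achievable fraction sits exactly on 0.75, so the choice only
    matters on synthetic designs.
    """
    gut_ids = [s.sample_id for s in samples if s.sample_type == "gut_day6"]
    start_ids = [s.sample_id for s in samples if s.sample_type == "substrate_day0"]
    if not gut_ids:
        raise ValueError("no gut_day6 samples in the design")
    if not start_ids:
        raise ValueError("no substrate_day0 samples in the design")

    gut_prev = prevalence(presence, gut_ids)
    start_prev = prevalence(presence, start_ids)
    if inclusive:
        meets = gut_prev >= prevalence_threshold
    else:
        meets = gut_prev > prevalence_threshold
    verdict = meets & (start_prev == 0.0)

    table = pd.DataFrame(
        {
            "gut_prevalence": gut_prev,
            "start_prevalence": start_prev,
            "gut_related": verdict,
        }
    )
    table.index.name = "mag_id"
    return GutClassification(
        table=table,
        presence_threshold=presence_threshold,
        prevalence_threshold=prevalence_threshold,
    )
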