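"""Group-wise functional enrichment via a binomial-GLM Rao score test.

For each binary feature (a KEGG module being present in a MAG, by
default completeness >= 0.75) the occurrence across MAGs is tested
against a MAG grouping (gut-related vs not).  The score (Lagrange
multiplier) test of the intercept-only binomial model against the
group-indicator alternative has the closed form

    X^2 = sum_g N_g (p_g - pbar)^2 / (pbar (1 - pbar)),  df = G - 1,

which for two groups is exactly the Pearson chi-square statistic of
the 2x2 occurrence table.  P-values come from the chi-square upper
tail and are Benjamini-Hochberg adjusted across features.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GutClassification, ModuleCompletenessMatrix

DEFAULT_OCCURRENCE_THRESHOLD = 0.75
DEFAULT_SCORE_THRESHOLD = 2.0
DEFAULT_Q_THRESHOLD = 0.05
SECONDARY_Q_THRESHOLD = 0.07


def rao_score_test(occurrence: Sequence[bool] | np.ndarray,
                   groups: Sequence) -> tuple[float, int, float]:
    """Rao score test of equal occurrence probability across groups.

    Returns (statistic, df, p).  A degenerate pooled proportion (all
    zeros or all ones) yields statistic 0 and p 1.
    """
    occ = np.asarray(occurrence, dtype=bool)
    grp = np.asarray(groups)
    if occ.shape != grp.shape:
        raise ValueError("occurrence and groups must have equal length")
    levels, inverse = np.unique(grp, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    n_g = np.bincount(inverse)
    k_g = np.bincount(inverse, weights=occ.astype(float))
    pbar = occ.mean()
    df = int(levels.size - 1)
    if pbar <= 0.0 or pbar >= 1.0:
        return 0.0, df, 1.0
    p_g = k_g / n_g
    stat = float(np.sum(n_g * (p_g - pbar) ** 2) / (pbar * (1.0 - pbar)))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def occurrence_from_modules(modules: ModuleCompletenessMatrix,
                            threshold: float = DEFAULT_OCCURRENCE_THRESHOLD
                            ) -> pd.DataFrame:
    """Feature x MAG boolean occurrence: completeness >= ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("occurrence threshold must lie in (0, 1]")
    return (modules.values >= threshold).T


def functional_enrichment(
    occurrence: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Enrichment of every feature (rows) across a MAG grouping.

    ``occurrence`` is boolean feature x MAG; ``groups`` maps mag_id to
    a group label.  Output rows carry the Rao statistic (enrichment
    score), raw p, BH q, the group with the highest occurrence
    proportion, per-group proportions, and significance flags at the
    primary (score > 2 and q < 0.05) and secondary (q < 0.07) tiers.
    """
    grp = pd.Series(groups)
    mags = [m for m in occurrence.columns if m in grp.index]
    if len(mags) < len(occurrence.columns):
        missing = set(occurrence.columns) - set(mags)
        raise ValueError(f"no group for mag_id(s): {sorted(missing)[:5]}")
    labels = grp.loc[mags]
    counts = labels.value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("need >= 2 non-empty MAG groups")

    rows = []
    for feature, occ in occurrence[mags].iterrows():
        stat, df, p = rao_score_test(occ.to_numpy(), labels.to_numpy())
        props = occ.groupby(labels).mean()
        best = props.sort_index().idxmax()  # lexicographic tie-break
        tied = (props == props.max()).sum() > 1
        row = {
            "feature_id": feature,
            "enrichment_score": stat,
            "df": df,
            "p": p,
            "associated_group": best,
            "ambiguous_direction": bool(tied),
        }
        row.update({f"proportion_{g}": props[g] for g in props.index})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["enrichment_score"] > score_threshold) & (
        out["q"] < q_threshold
    )
    out["significant_q07"] = out["q"] < SECONDARY_Q_THRESHOLD
    return out.sort_values(["q", "enrichment_score"], ascending=[True, False])


def enrichment_by_gut_class(
    modules: ModuleCompletenessMatrix,
    classification: GutClassification,
    occurrence_threshold: float = DEFAULT_OCCURRENCE_THRESHOLD,
    **kwargs,
) -> pd.DataFrame:
    """Module enrichment between gut-related and other MAGs."""
    occ = occurrence_from_modules(modules, occurrence_threshold)
    groups = classification.table["gut_related"].map(
        {True: "gut_related", False: "other"}
    )
    return functional_enrichment(occ, groups, **kwargs)
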