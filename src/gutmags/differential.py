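"""Pairwise differential abundance across substrates.

Three feature levels, matching how gut microbiome shifts are usually
reported: MAG abundance (Wilcoxon rank-sum, robust to the skewed,
zero-inflated distributions of coverage data), COG-function coverage
(Welch t-tests on depth-normalized summed gene coverage with a log2
fold-change filter), and COG-category coverage (Dunn's post-hoc test
on pooled ranks).  P-values are Benjamini-Hochberg adjusted within
one substrate pair x one feature class.  Levene and Shapiro-Wilk
checks are advisory only and never gate a test.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CoverageMatrix,
    CoverageState,
    GeneFunctionTable,
    SampleRecord,
    SUBSTRATES,
)
from .enrichment import bh_adjust
from .normalize import aggregate_genes_by

SUBSTRATE_PAIRS = tuple(itertools.combinations(SUBSTRATES, 2))

TIER_SUGGESTIVE = 0.1
TIER_SIGNIFICANT = 0.05


def _tier(p_adj: float) -> str:
    if p_adj < TIER_SIGNIFICANT:
        return "significant"
    if p_adj < TIER_SUGGESTIVE:
        return "suggestive"
    return "none"


def pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero value; 1.0 if everything is zero."""
    nz = values[values > 0]
    return float(nz.min() / 2.0) if nz.size else 1.0


def _log2_fc(mean_a: float, mean_b: float, eps: float) -> float:
    return float(np.log2((mean_a + eps) / (mean_b + eps)))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact when both groups have <= 7 observations and there are no
    ties, otherwise the normal approximation with continuity and tie
    correction.  A statistic at its null center reports p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    if u == x.size * y.size / 2.0:
        return u, 1.0
    return u, float(res.pvalue)


def _gut_samples_by_substrate(samples: list[SampleRecord]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {s: [] for s in SUBSTRATES}
    for s in samples:
        if s.sample_type == "gut_day6":
            groups[s.substrate].append(s.sample_id)
    return groups


def wilcoxon_pairwise(
    coverage: CoverageMatrix,
    samples: list[SampleRecord],
    feature_set: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of every MAG between each substrate pair.

    Uses the day-6 gut samples of each substrate; BH adjustment is
    applied within each substrate pair's family of MAGs.
    """
    if coverage.state not in (CoverageState.SUM_NORMALIZED, CoverageState.RELATIVE):
        raise ValueError("wilcoxon_pairwise expects normalized abundances")
    groups = _gut_samples_by_substrate(samples)
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"substrate group {name!r} has < 2 gut samples")
    features = list(feature_set) if feature_set is not None else coverage.mag_ids
    eps = pseudocount(coverage.values.loc[features].to_numpy())

    frames = []
    for sub_a, sub_b in SUBSTRATE_PAIRS:
        rows = []
        for mag in features:
            a = coverage.values.loc[mag, groups[sub_a]].to_numpy()
            b = coverage.values.loc[mag, groups[sub_b]].to_numpy()
            u, p = wilcoxon_rank_sum(a, b)
            rows.append(
                {
                    "feature_id": mag,
                    "group_a": sub_a,
                    "group_b": sub_b,
                    "statistic": u,
                    "p": p,
                    "log2_fc": _log2_fc(a.mean(), b.mean(), eps),
                }
            )
        fam = pd.DataFrame(rows)
        fam["p_adj"] = bh_adjust(fam["p"].to_numpy())
        frames.append(fam)
    out = pd.concat(frames, ignore_index=True)
    out["tier"] = out["p_adj"].map(_tier)
    out["significant"] = out["p_adj"] < TIER_SIGNIFICANT
    return out


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test; degenerate equal constants give p = 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def ttest_cog_differential(
    genes: GeneFunctionTable,
    samples: list[SampleRecord],
    pair: tuple[str, str] | None = None,
    lfc_threshold: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-COG-function t-tests between gut samples of substrate pairs.

    Gene coverage must be depth-normalized; it is summed per COG
    function and sample, then each substrate pair is tested (Welch by
    default).  Significant = BH-adjusted p < 0.05 and |log2 FC| > 1,
    with the fold change computed on means after adding a pseudocount
    of half the smallest nonzero aggregated coverage.
    """
    if not genes.normalized:
        raise ValueError("gene table must be depth-normalized first")
    table = aggregate_genes_by(genes, "cog_function")
    groups = _gut_samples_by_substrate(samples)
    pairs = [pair] if pair is not None else list(SUBSTRATE_PAIRS)
    eps = pseudocount(table.to_numpy())

    frames = []
    for sub_a, sub_b in pairs:
        ids_a, ids_b = groups[sub_a], groups[sub_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(f"substrate pair {(sub_a, sub_b)} lacks gut samples")
        rows = []
        for cog, row in table.iterrows():
            a = row[ids_a].to_numpy()
            b = row[ids_b].to_numpy()
            if equal_var:
                res = stats.ttest_ind(a, b, equal_var=True)
                t, p = float(res.statistic), float(res.pvalue)
                if np.isnan(t):
                    t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            else:
                t, p = welch_t_test(a, b)
            rows.append(
                {
                    "feature_id": cog,
                    "group_a": sub_a,
                    "group_b": sub_b,
                    "statistic": t,
                    "p": p,
                    "log2_fc": _log2_fc(a.mean(), b.mean(), eps),
                }
            )
        fam = pd.DataFrame(rows)
        fam["p_adj"] = bh_adjust(fam["p"].to_numpy())
        frames.append(fam)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = (out["p_adj"] < TIER_SIGNIFICANT) & (
        out["log2_fc"].abs() > lfc_threshold
    )
    out["tier"] = np.where(out["significant"], "significant", "none")
    return out


def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on Kruskal-Wallis pooled ranks.

    Ranks are pooled over all groups with average ties; the tie
    correction sum(t^3 - t) / (12 (N - 1)) is subtracted from the
    variance term N (N + 1) / 12.  Two-sided normal p-values; all
    identical values yield z = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    values = [np.asarray(groups[g], float) for g in names]
    sizes = [v.size for v in values]
    if min(sizes) < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, n in zip(names, sizes):
        mean_ranks[g] = ranks[start:start + n].mean()
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    var = N * (N + 1) / 12.0 - tie_term

    rows = []
    for g_a, g_b in itertools.combinations(names, 2):
        n_a = values[names.index(g_a)].size
        n_b = values[names.index(g_b)].size
        se = np.sqrt(var * (1.0 / n_a + 1.0 / n_b)) if var > 0 else 0.0
        diff = mean_ranks[g_a] - mean_ranks[g_b]
        z = diff / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0
        rows.append({"group_a": g_a, "group_b": g_b, "z": z, "p": p})
    return pd.DataFrame(rows)


def dunn_category_test(
    category_sums: pd.DataFrame,
    samples: list[SampleRecord],
) -> pd.DataFrame:
    """Dunn tests of per-sample summed COG-category coverage between the
    gut samples of the three substrates; BH across the 3 pairs per
    category."""
    groups = _gut_samples_by_substrate(samples)
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"substrate group {name!r} has < 2 gut samples")
    frames = []
    for category, row in category_sums.iterrows():
        res = dunn_test({g: row[ids].to_numpy() for g, ids in groups.items()})
        res.insert(0, "category", category)
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p_adj"] < TIER_SIGNIFICANT
    return out


def check_assumptions(groups: Mapping[str, np.ndarray]) -> dict:
    """Advisory Shapiro-Wilk (per group) and Levene (median-centered)
    checks; constant groups are reported as not applicable."""
    shapiro = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        if vals.size < 3 or np.all(vals == vals[0]):
            shapiro[name] = None
        else:
            shapiro[name] = float(stats.shapiro(vals).pvalue)
    arrays = [np.asarray(v, float) for v in groups.values()]
    try:
        lev = stats.levene(*arrays, center="median")
        levene_stat, levene_p = float(lev.statistic), float(lev.pvalue)
        if np.isnan(levene_stat):
            # zero within-group spread of |x - median|: the statistic is
            # 0/0; report 0 when the group spreads agree, inf otherwise
            z = [np.abs(a - np.median(a)) for a in arrays]
            means = np.array([zi.mean() for zi in z])
            if np.allclose(means, means[0]):
                levene_stat, levene_p = 0.0, 1.0
            else:
                levene_stat, levene_p = float("inf"), 0.0
    except ValueError:
        levene_stat, levene_p = None, None
    return {
        "shapiro_p": shapiro,
        "levene_statistic": levene_stat,
        "levene_p": levene_p,
    }
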