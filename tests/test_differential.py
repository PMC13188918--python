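"""Wilcoxon, Welch, and Dunn differential tests plus assumption checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gutmags as gm
from gutmags.differential import (
    check_assumptions,
    dunn_category_test,
    dunn_test,
    ttest_cog_differential,
    welch_t_test,
    wilcoxon_pairwise,
    wilcoxon_rank_sum,
)


def exact_wilcoxon_p(x, y):
    """Enumerate every assignment of pooled values to the two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").statistic
    center = n1 * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = stats.mannwhitneyu(pooled[mask], pooled[~mask],
                               alternative="two-sided",
                               method="exact").statistic
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_extreme_separation_exact_p(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        u, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_pairwise_bookkeeping(self, default_dataset, pipeline_result):
        ds, _ = default_dataset
        table = pipeline_result.mag_differential
        assert len(table) == len(ds.catalog) * 3
        pairs = set(map(tuple, table[["group_a", "group_b"]].drop_duplicates()
                        .itertuples(index=False)))
        assert pairs == {("brewery", "bran_grass"), ("brewery", "sludge"),
                         ("bran_grass", "sludge")}

    def test_small_group_rejected(self, default_dataset):
        ds, _ = default_dataset
        trimmed = [s for s in ds.samples
                   if not (s.sample_type == "gut_day6"
                           and s.substrate == "sludge" and s.replicate > 1)]
        cov = gm.CoverageMatrix(values=ds.coverage.values,
                                state=gm.CoverageState.SUM_NORMALIZED)
        with pytest.raises(ValueError, match="sludge"):
            wilcoxon_pairwise(cov, trimmed)


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_equal_groups_give_p_one(self):
        t, p = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_log2_fold_change_of_four(self, mini_dataset):
        # means 8 vs 2 with a negligible pseudocount -> log2 FC ~ 2
        genes = mini_dataset.genes
        from gutmags.differential import _log2_fc, pseudocount
        eps = 1e-9
        assert _log2_fc(8.0, 2.0, eps) == pytest.approx(2.0, abs=1e-6)
        assert _log2_fc(2.0, 8.0, eps) == pytest.approx(-2.0, abs=1e-6)

    def test_log2_fc_antisymmetry(self, pipeline_result):
        table = pipeline_result.cog_differential
        fwd = table[(table["group_a"] == "brewery")
                    & (table["group_b"] == "bran_grass")]
        fwd = fwd.set_index("feature_id")["log2_fc"]
        # recompute with groups swapped
        ds = pipeline_result.dataset
        from gutmags.normalize import depth_normalize_genes
        genes = depth_normalize_genes(ds.genes)
        rev = ttest_cog_differential(genes, ds.samples,
                                     pair=("bran_grass", "brewery"))
        rev = rev.set_index("feature_id")["log2_fc"]
        assert np.allclose(fwd, -rev.loc[fwd.index])

    def test_planted_cog_shifts_recovered(self, default_dataset,
                                          pipeline_result):
        _, truth = default_dataset
        table = pipeline_result.cog_differential
        hits = table[(table["group_a"] == "brewery")
                     & (table["group_b"] == "bran_grass")
                     & table["significant"]]
        called = set(hits["feature_id"])
        recall = len(called & truth.shifted_cog_ids) / len(truth.shifted_cog_ids)
        assert recall >= 0.9
        # planted shift raises brewery coverage -> positive fold change
        planted = table[(table["group_a"] == "brewery")
                        & (table["group_b"] == "bran_grass")
                        & table["feature_id"].isin(truth.shifted_cog_ids)]
        assert (planted["log2_fc"] > 0).all()


def dunn_oracle(groups):
    """Direct rank computation, written independently of the package."""
    names = list(groups)
    pooled = []
    for g in names:
        pooled.extend((v, g) for v in groups[g])
    pooled.sort(key=lambda t: t[0])
    # average ranks with ties
    ranks = {}
    i = 0
    assigned = []
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        assigned.extend([avg] * (j - i))
        i = j
    by_group = {g: [] for g in names}
    for (v, g), r in zip(pooled, assigned):
        by_group[g].append(r)
    N = len(pooled)
    from collections import Counter
    tie_counts = Counter(v for v, _ in pooled)
    tie_term = sum(t ** 3 - t for t in tie_counts.values()) / (12 * (N - 1))
    var = N * (N + 1) / 12 - tie_term
    out = {}
    for g_a, g_b in itertools.combinations(names, 2):
        se = np.sqrt(var * (1 / len(by_group[g_a]) + 1 / len(by_group[g_b])))
        diff = np.mean(by_group[g_a]) - np.mean(by_group[g_b])
        out[(g_a, g_b)] = diff / se if se > 0 else 0.0
    return out


class TestDunn:
    def test_identical_groups_are_null(self):
        res = dunn_test({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]})
        assert (res["z"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_ordered_groups_extreme_pair(self):
        res = dunn_test({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]})
        res = res.set_index(["group_a", "group_b"])
        assert abs(res.loc[("a", "c"), "z"]) == res["z"].abs().max()
        assert res.loc[("a", "c"), "z"] < 0

    def test_matches_rank_oracle_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            groups = {
                g: rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
                for g in ("a", "b", "c")
            }
            res = dunn_test(groups).set_index(["group_a", "group_b"])["z"]
            oracle = dunn_oracle(groups)
            for pair, z in oracle.items():
                assert res.loc[pair] == pytest.approx(z, abs=1e-9)

    def test_category_table_families(self, pipeline_result):
        table = pipeline_result.category_differential
        assert set(table.groupby("category").size().unique()) == {3}
        assert ((table["p_adj"] >= 0) & (table["p_adj"] <= 1)).all()


class TestAssumptions:
    def test_levene_zero_when_spreads_match(self):
        report = check_assumptions({"a": [1.0, 3.0], "b": [11.0, 13.0]})
        assert report["levene_statistic"] == pytest.approx(0.0)

    def test_constant_group_not_applicable(self):
        report = check_assumptions({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 4.0]})
        assert report["shapiro_p"]["a"] is None
        assert report["shapiro_p"]["b"] is not None

    def test_levene_matches_median_centered_formula(self):
        rng = np.random.default_rng(9)
        groups = {g: rng.normal(size=7) for g in "abc"}
        report = check_assumptions(groups)
        expected = stats.levene(*groups.values(), center="median")
        assert report["levene_statistic"] == pytest.approx(expected.statistic)
        assert report["levene_p"] == pytest.approx(expected.pvalue)
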