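"""Hill numbers, binary distance, and classical PCoA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import gutmags as gm
from gutmags.diversity import binary_distance, diversity_profile, hill_number, pcoa


class TestHillNumber:
    def test_uniform_community_any_order(self):
        p = np.full(4, 0.25)
        for q in (0, 0.5, 1, 2, 3):
            assert hill_number(p, q) == pytest.approx(4.0)

    def test_closed_form_q2(self):
        assert hill_number(np.array([0.8, 0.2]), 2) == pytest.approx(
            1 / 0.68, abs=1e-9
        )

    def test_closed_form_q1(self):
        expected = np.exp(-(0.8 * np.log(0.8) + 0.2 * np.log(0.2)))
        assert hill_number(np.array([0.8, 0.2]), 1) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(1.64936, abs=1e-4)

    def test_q0_counts_support(self):
        assert hill_number(np.array([0.5, 0.5, 0.0]), 0) == 2.0

    def test_monotone_nonincreasing_in_q(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = rng.dirichlet(np.full(rng.integers(2, 30), 0.5))
            values = [hill_number(p, q) for q in (0, 0.5, 1, 1.5, 2, 3)]
            assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_continuity_at_q1(self):
        rng = np.random.default_rng(7)
        p = rng.dirichlet(np.ones(10))
        at_1 = hill_number(p, 1.0)
        assert hill_number(p, 1 - 1e-6) == pytest.approx(at_1, rel=1e-4)
        assert hill_number(p, 1 + 1e-6) == pytest.approx(at_1, rel=1e-4)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError, match="empty community"):
            hill_number(np.zeros(3), 1)


class TestDiversityProfile:
    def test_equal_abundance_samples(self):
        cov = gm.CoverageMatrix(
            values=pd.DataFrame(
                {"s3": [1 / 3] * 3, "s1": [1.0, 0.0, 0.0]},
                index=["a", "b", "c"],
            ),
            state=gm.CoverageState.RELATIVE,
        )
        prof = diversity_profile(cov).table
        assert prof.loc["s3"].tolist() == pytest.approx([3.0, 3.0, 3.0])
        assert prof.loc["s1"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_d0_matches_presence_count_at_zero_threshold(self, default_dataset):
        ds, _ = default_dataset
        rel = gm.relative_abundance(ds.coverage)
        prof = diversity_profile(rel).table
        presence = gm.presence_matrix(rel, threshold=0.0)
        assert (prof["D0"] == presence.sum(axis=0)).all()

    def test_scale_invariance_of_hill_numbers(self, default_dataset):
        # sum-normalized vs relative abundances give identical profiles
        ds, _ = default_dataset
        lengths = pd.Series({m.mag_id: m.genome_length for m in ds.catalog})
        tpm = gm.tpm_normalize(ds.coverage, lengths)
        rel = gm.relative_abundance(tpm)
        tpm_as_rel = gm.relative_abundance(
            gm.CoverageMatrix(values=tpm.values, state=gm.CoverageState.RAW)
        )
        a = diversity_profile(rel).table
        b = diversity_profile(tpm_as_rel).table
        pd.testing.assert_frame_equal(a, b)


class TestBinaryDistance:
    def test_mismatch_counting(self):
        presence = pd.DataFrame(
            {"A": [True, True, False], "B": [True, False, True]},
            index=["m1", "m2", "m3"],
        )
        d = binary_distance(presence)
        assert d.loc["A", "B"] == pytest.approx(2 / 3)
        assert d.loc["A", "A"] == 0.0

    def test_identical_and_disjoint_profiles(self):
        presence = pd.DataFrame(
            {"A": [True, False], "B": [True, False], "C": [False, True]},
            index=["m1", "m2"],
        )
        d = binary_distance(presence)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == 1.0
        assert np.allclose(d, d.T)


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        res = pcoa(d)
        assert res.coordinates.shape[1] == 1
        sep = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert sep == pytest.approx(0.7)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_three_equidistant_samples(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("ABC"), columns=list("ABC"))
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.percent_variance[:2] == pytest.approx([50.0, 50.0])

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(8, 3))
        d = squareform(pdist(points))
        dist = pd.DataFrame(d, index=range(8), columns=range(8))
        res = pcoa(dist)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rebuilt, d, atol=1e-8)

    def test_percent_variance_sums_to_100(self, pipeline_result):
        assert pipeline_result.pcoa.percent_variance.sum() == pytest.approx(
            100.0, abs=0.01
        )
        eig = pipeline_result.pcoa.eigenvalues
        assert (np.diff(eig) <= 1e-12).all()

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(11)
        points = rng.normal(size=(6, 2))
        d = squareform(pdist(points))
        dist = pd.DataFrame(d, index=list("ABCDEF"), columns=list("ABCDEF"))
        res1 = pcoa(dist)
        order = list("FEDCBA")
        res2 = pcoa(dist.loc[order, order])
        back = res2.coordinates.loc[list("ABCDEF")]
        for col in res1.coordinates.columns:
            a = res1.coordinates[col].to_numpy()
            b = back[col].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_agrees_with_skbio_on_binary_distance(self, pipeline_result):
        skbio = pytest.importorskip("skbio")
        presence = gm.presence_matrix(pipeline_result.relative)
        d = binary_distance(presence)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        # compare percent variance over the axes we retain (positive eigenvalues)
        k = len(ours.eigenvalues)
        theirs_pct = (
            100.0
            * theirs.eigvals.to_numpy()[:k]
            / theirs.eigvals.to_numpy()[theirs.eigvals.to_numpy() > 0].sum()
        )
        assert np.allclose(ours.percent_variance, theirs_pct, atol=1e-6)
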