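"""Synthetic generator: design structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

import gutmags as gm
from gutmags.synth import (
    PhenotypeEffect,
    RecoveryReport,
    ReplicatePlan,
    SyntheticConfig,
    evaluate_recovery,
    generate_dataset,
)


class TestDesignStructure:
    def test_sample_plan_matches_config_and_bounds(self, default_dataset):
        ds, _ = default_dataset
        frame = ds.sample_frame()
        counts = frame.groupby(["substrate", "sample_type"]).size()
        for substrate in gm.datatypes.SUBSTRATES:
            assert counts[(substrate, "substrate_day0")] == 1
            assert 2 <= counts[(substrate, "substrate_day6")] <= 3
            assert 4 <= counts[(substrate, "gut_day6")] <= 5

    def test_gut_fraction_arithmetic(self, default_dataset):
        ds, truth = default_dataset
        assert len(truth.gut_related_mag_ids) == 60
        assert truth.gut_related_mag_ids <= set(ds.mag_ids)
        assert truth.enriched_module_ids <= set(ds.modules.module_ids)

    def test_gut_mags_absent_from_day0(self, default_dataset):
        ds, truth = default_dataset
        day0 = ds.samples_of("substrate_day0")
        sub = ds.coverage.values.loc[sorted(truth.gut_related_mag_ids), day0]
        assert (sub.to_numpy() == 0).all()

    def test_gut_mags_meet_configured_prevalence(self, default_dataset):
        ds, truth = default_dataset
        rel = gm.relative_abundance(ds.coverage)
        presence = gm.presence_matrix(rel)
        gut_ids = ds.samples_of("gut_day6")
        prev = presence.loc[sorted(truth.gut_related_mag_ids), gut_ids].mean(axis=1)
        assert (prev >= 0.75).all()

    def test_module_completeness_in_unit_interval(self, default_dataset):
        ds, _ = default_dataset
        vals = ds.modules.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_phenotypes_one_row_per_gut_sample(self, default_dataset):
        ds, _ = default_dataset
        assert sorted(ds.phenotypes.values["sample_id"]) == sorted(
            ds.samples_of("gut_day6")
        )
        surv = ds.phenotypes.values["survival"]
        assert ((surv >= 0) & (surv <= 1)).all()


class TestDeterminism:
    def test_same_seed_identical_datasets(self):
        cfg = SyntheticConfig(seed=7, n_mags=30, n_modules=20,
                              n_cog_functions=40)
        ds1, t1 = generate_dataset(cfg)
        ds2, t2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.coverage.values, ds2.coverage.values)
        pd.testing.assert_frame_equal(ds1.modules.values, ds2.modules.values)
        pd.testing.assert_frame_equal(ds1.genes.genes, ds2.genes.genes)
        pd.testing.assert_frame_equal(ds1.phenotypes.values,
                                      ds2.phenotypes.values)
        assert t1.gut_related_mag_ids == t2.gut_related_mag_ids
        assert t1.enriched_module_ids == t2.enriched_module_ids

    def test_different_seed_differs(self):
        cfg = SyntheticConfig(seed=7, n_mags=30, n_modules=20,
                              n_cog_functions=40)
        ds1, _ = generate_dataset(cfg)
        ds2, _ = generate_dataset(
            SyntheticConfig(seed=8, n_mags=30, n_modules=20, n_cog_functions=40)
        )
        assert not ds1.coverage.values.equals(ds2.coverage.values)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fraction_gut_related": 1.2},
            {"enriched_presence": (1.3, 0.1)},
            {"n_mags": 0},
            {"enriched_module_count": 500},
            {"gut_effect": -1.0},
            {"replicates": ReplicatePlan(day0=1, day6_substrate=5, gut=5)},
            {"replicates": ReplicatePlan(day0=1, day6_substrate=3, gut=2)},
        ],
    )
    def test_infeasible_config_rejected_before_sampling(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(SyntheticConfig(**kwargs))


class TestEvaluateRecovery:
    def test_perfect_results(self):
        truth = gm.SyntheticTruth(
            gut_related_mag_ids={"a", "b"}, enriched_module_ids=set(),
            phenotype_effects=(), shifted_cog_ids=set(), seed=0,
        )
        rep = evaluate_recovery(truth, {"a", "b"}, seed=0)
        assert rep.gut_precision == 1.0 and rep.gut_recall == 1.0

    def test_empty_prediction_has_zero_recall(self):
        truth = gm.SyntheticTruth(
            gut_related_mag_ids={"a"}, enriched_module_ids=set(),
            phenotype_effects=(), shifted_cog_ids=set(), seed=0,
        )
        rep = evaluate_recovery(truth, set(), seed=0)
        assert rep.gut_recall == 0.0

    def test_one_false_positive_counting(self):
        true_set = {f"m{i}" for i in range(60)}
        truth = gm.SyntheticTruth(
            gut_related_mag_ids=true_set, enriched_module_ids=set(),
            phenotype_effects=(), shifted_cog_ids=set(), seed=0,
        )
        rep = evaluate_recovery(truth, true_set | {"impostor"}, seed=0)
        assert rep.gut_precision == pytest.approx(60 / 61)
        assert rep.gut_recall == 1.0

    def test_seed_mismatch_rejected(self):
        truth = gm.SyntheticTruth(
            gut_related_mag_ids=set(), enriched_module_ids=set(),
            phenotype_effects=(), shifted_cog_ids=set(), seed=3,
        )
        with pytest.raises(ValueError, match="seed"):
            evaluate_recovery(truth, set(), seed=4)

    def test_noiseless_recovery_is_exact(self):
        cfg = SyntheticConfig(seed=5, noise_sd=0.0)
        ds, truth = generate_dataset(cfg)
        rel = gm.relative_abundance(ds.coverage)
        presence = gm.presence_matrix(rel)
        cls = gm.classify_gut_related(presence, ds.samples)
        rep = evaluate_recovery(truth, cls.gut_related_ids, seed=5)
        assert rep.gut_precision == 1.0
        assert rep.gut_recall == 1.0
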