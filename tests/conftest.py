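import pandas as pd
import pytest

import gutmags as gm


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions."""
    ds, truth = gm.generate_dataset(gm.SyntheticConfig(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    ds, _ = default_dataset
    return gm.run_pipeline(ds, gm.RunConfig(seed=1))


@pytest.fixture()
def mini_catalog():
    """Hand-built catalog: 2 archaea, 3 bacteria, 1 eukaryote."""
    def mag(i, domain, phylum="", genus="", **kw):
        defaults = dict(genome_length=2_000_000, completion=80.0, redundancy=3.0,
                        n_contigs=50, n50=40_000, n_trnas=15)
        defaults.update(kw)
        return gm.MagRecord(mag_id=f"MAG_{i}", domain=domain,
                            taxonomy={"phylum": phylum, "genus": genus}, **defaults)

    return [
        mag(1, "archaea"),
        mag(2, "archaea"),
        mag(3, "bacteria", phylum="Pseudomonadota", genus="Providencia"),
        mag(4, "bacteria", phylum="Pseudomonadota", genus="Alcaligenes"),
        mag(5, "bacteria", phylum="Bacillota", genus="Enterococcus"),
        mag(6, "eukaryote"),
    ]


@pytest.fixture()
def mini_dataset(mini_catalog):
    """2-MAG, 3-sample dataset exercising every table."""
    catalog = mini_catalog[:2]
    samples = [
        gm.SampleRecord("s_d0", "substrate_day0", "brewery", 1),
        gm.SampleRecord("s_d6", "substrate_day6", "brewery", 1),
        gm.SampleRecord("g_1", "gut_day6", "brewery", 1),
    ]
    coverage = gm.CoverageMatrix(
        values=pd.DataFrame(
            [[1.0, 2.0, 3.0], [0.0, 4.0, 5.0]],
            index=["MAG_1", "MAG_2"], columns=["s_d0", "s_d6", "g_1"],
        ),
        state=gm.CoverageState.RAW,
    )
    modules = gm.ModuleCompletenessMatrix(
        values=pd.DataFrame(
            [[1.0, 0.5], [0.0, 0.9]],
            index=["MAG_1", "MAG_2"], columns=["M0001", "M0002"],
        )
    )
    genes = gm.GeneFunctionTable(
        genes=pd.DataFrame(
            {
                "gene_id": ["gene_1", "gene_2"],
                "mag_id": ["MAG_1", "MAG_2"],
                "cog_function": ["COG0001", "COG0002"],
                "cog_category": ["C", "E"],
                "cog_pathway": ["PWY_C", "PWY_E"],
                "kegg_module": ["M0001", ""],
                "s_d0": [1.0, 0.0],
                "s_d6": [2.0, 1.0],
                "g_1": [3.0, 2.0],
            }
        ),
        total_reads=pd.Series({"s_d0": 1_000_000, "s_d6": 2_000_000,
                               "g_1": 500_000}),
    )
    phenotypes = gm.PhenotypeTable(
        values=pd.DataFrame(
            {"sample_id": ["g_1"], "survival": [0.8], "conversion": [1.2]}
        )
    )
    return gm.Dataset(catalog=catalog, samples=samples, coverage=coverage,
                      modules=modules, genes=genes, phenotypes=phenotypes)
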