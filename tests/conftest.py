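import numpy as np
import pandas as pd
import pytest

from pgsomics import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    SimulationConfig,
    VariantWeightSet,
    simulate_study,
)
from pgsomics.io import write_study_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_weights(snp_ids, effect, other, weights, chrom="1"):
    n = len(snp_ids)
    return VariantWeightSet(pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": [chrom] * n,
        "pos": np.arange(1, n + 1) * 100,
        "effect_allele": effect,
        "other_allele": other,
        "weight": weights,
    }))


def make_genotypes(sample_ids, snp_ids, a1, a2, dosages, chrom="1"):
    n = len(snp_ids)
    variants = pd.DataFrame({
        "snp_id": snp_ids, "chrom": [chrom] * n,
        "pos": np.arange(1, n + 1) * 100, "a1": a1, "a2": a2,
    })
    return GenotypeDosageMatrix(list(sample_ids), variants,
                                np.asarray(dosages, dtype=float))


def random_expression(rng, n=10, m=20, prefix="T"):
    ids = [f"S{i}" for i in range(n)]
    tids = [f"{prefix}{j}" for j in range(m)]
    return ExpressionMatrix(ids, tids, rng.standard_normal((n, m)))


def random_covariates(rng, sample_ids, sex=""):
    return CovariateTable(pd.DataFrame({
        "sample_id": list(sample_ids),
        "sex": sex,
        "age": rng.integers(20, 71, size=len(sample_ids)).astype(float),
        "bmi": rng.normal(27, 4, size=len(sample_ids)),
    }))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples_per_sex=100, n_snps=400, n_transcripts=150,
        n_causal_transcripts=15, n_tissues=3,
        r2_by_tissue=[0.5, 0.0, 0.0], r2_target=0.3,
        min_tissue_samples=60, seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_study_bundle(small_bundle, out)
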