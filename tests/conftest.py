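import numpy as np
import pytest

import rarecausal as rc


def make_genotypes(dosages, sample_prefix="s", variant_prefix="v"):
    """GenotypeMatrix from a plain array with auto-generated ids."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return rc.GenotypeMatrix(
        dosages=d,
        variant_ids=[f"{variant_prefix}{j}" for j in range(m)],
        positions=np.arange(1, m + 1),
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
    )


def balanced_phenotype(n, seed=None):
    """Binary phenotype with n/2 cases, optionally shuffled."""
    y = np.zeros(n)
    y[: n // 2] = 1
    if seed is not None:
        y = y[np.random.default_rng(seed).permutation(n)]
    return rc.PhenotypeTable(
        y=y, trait_type="dichotomous", sample_ids=[f"s{i}" for i in range(n)]
    )


@pytest.fixture(scope="session")
def small_pool():
    """Modest haplotype pool shared by simulation-driven tests."""
    return rc.simulate_haplotypes(
        n_hap=2000, n_sites=1500, region_length=150_000, seed=11
    )


@pytest.fixture(scope="session")
def m1_cohort(small_pool):
    """One M1 cohort with 20% causal variants (shared, read-only)."""
    region = rc.draw_region(small_pool, 10_000, seed=21)
    cohort = rc.simulate_cohort(
        region,
        rc.DiseaseModel.M1(causal_fraction=0.2),
        rc.AnnotationModel(ns_s_ratio=1.0),
        n_cases=500,
        n_controls=500,
        seed=22,
        calibration_mc_size=50_000,
    )
    return cohort
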