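import numpy as np
import pytest

from gstk.enviromics import build_env_matrix, env_kernel, load_daily_covariates
from gstk.kernels import genomic_kernel
from gstk.phenotypes import merge_geno_pheno
from gstk.simulate import (
    SimConfig,
    simulate_env_covariates,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """60 RIL lines x 100 markers, complete genotypes."""
    cfg = SimConfig(
        n_families=6, lines_per_family=10, n_chrom=2, markers_per_chrom=50, seed=11
    )
    geno, ped = simulate_genotypes(cfg)
    return geno, ped, cfg


@pytest.fixture(scope="session")
def me_dataset():
    """Multi-environment merged dataset: 50 lines x 5 envs with G x E."""
    cfg = SimConfig(
        n_families=5,
        lines_per_family=10,
        n_chrom=2,
        markers_per_chrom=60,
        n_envs=5,
        gxe_variance_ratio=0.5,
        seed=21,
    )
    geno, _ = simulate_genotypes(cfg)
    envs, cache = simulate_env_covariates(cfg)
    w = build_env_matrix(load_daily_covariates(cache, envs))
    omega = env_kernel(w, "gaussian")
    pheno, truth = simulate_phenotypes(geno, w, cfg)
    ds = merge_geno_pheno(geno, pheno, "trait1")
    return ds, omega, truth, cfg


@pytest.fixture(scope="session")
def linear_kernel(me_dataset):
    ds, _, _, _ = me_dataset
    return genomic_kernel(ds.geno, kind="linear")
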