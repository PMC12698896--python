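"""G-BLUP/REML, RR-BLUP duality, EM ridge, and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from gstk.kernels import GenomicKernel, genomic_kernel
from gstk.phenotypes import merge_geno_pheno
from gstk.simulate import SimConfig, simulate_genotypes, simulate_phenotypes
from gstk.single_trait import (
    MixedModelFit,
    fit_em_ridge,
    fit_gblup_reml,
    rrblup_marker_effects,
    select_candidates,
    solve_mme,
)


@pytest.fixture(scope="module")
def single_env():
    cfg = SimConfig(
        n_families=10, lines_per_family=20, n_chrom=5, markers_per_chrom=100, seed=2
    )
    g, _ = simulate_genotypes(cfg)
    ph, truth = simulate_phenotypes(g, ["E1"], cfg)
    ds = merge_geno_pheno(g, ph, "trait1")
    y = ds.records.set_index("strain").loc[ds.geno.taxa, "value"].to_numpy()
    m = ds.geno.dosage.astype(float)
    m = m - m.mean(axis=0)
    return ds, y, m, truth


def test_fixed_lambda_matches_dense_mme(single_env):
    """Spectral-path solution equals the Henderson-equation solve to 1e-8."""
    ds, y, _, _ = single_env
    k = genomic_kernel(ds.geno.take_taxa(range(20)), "gaussian")
    y20, x, z = y[:20], np.ones((20, 1)), np.eye(20)
    fit = fit_gblup_reml(y20, x, k, z, lambda_fixed=2.0)
    beta, u = solve_mme(y20, x, k.matrix, z, 2.0)
    np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
    np.testing.assert_allclose(fit.blup, u, atol=1e-8)


def test_rrblup_gblup_duality(single_env):
    """Marker-effect GEBVs equal kernel BLUPs under K = MM'/c, lam/c."""
    ds, y, m, _ = single_env
    n = 60
    m60, y60 = m[:n], y[:n]
    c = 2 * np.sum((ds.geno.dosage[:, :].mean(0) / 2) * (1 - ds.geno.dosage.mean(0) / 2))
    k = GenomicKernel(
        taxa=[f"s{i}" for i in range(n)], matrix=m60 @ m60.T / c, kind="linear"
    )
    lam_m = 75.0
    x = np.ones((n, 1))
    _, gebv = rrblup_marker_effects(y60, x, m60, lam_m)
    fit = fit_gblup_reml(y60, x, k, np.eye(n), lambda_fixed=lam_m / c)
    np.testing.assert_allclose(gebv, fit.blup, atol=1e-6)


def test_single_marker_closed_form():
    rng = np.random.default_rng(0)
    m = rng.normal(size=(30, 1))
    m -= m.mean()
    y = 0.5 * m[:, 0] + rng.normal(0, 0.1, 30)
    x = np.ones((30, 1))
    y_c = y - y.mean()
    lam = 3.0
    b, _ = rrblup_marker_effects(y, x, m, lam)
    expect = float(m[:, 0] @ y_c / (m[:, 0] @ m[:, 0] + lam))
    assert b[0] == pytest.approx(expect, abs=1e-10)


def test_infinite_shrinkage(single_env):
    _, y, m, _ = single_env
    b, _ = rrblup_marker_effects(y, np.ones((len(y), 1)), m, 1e12)
    assert np.max(np.abs(b)) < 1e-6


def test_constant_y_boundary(single_env):
    ds, _, _, _ = single_env
    k = genomic_kernel(ds.geno.take_taxa(range(30)), "gaussian")
    y = np.full(30, 3.14)
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_gblup_reml(y, np.ones((30, 1)), k, np.eye(30))
    assert fit.sigma2_u < 1e-4
    np.testing.assert_allclose(fit.blup, 0.0, atol=1e-4)


def test_reml_h2_recovery(single_env):
    ds, y, _, truth = single_env
    k = genomic_kernel(ds.geno, "linear")
    fit = fit_gblup_reml(y, np.ones((len(y), 1)), k, np.eye(len(y)))
    assert abs(fit.h2 - 0.5) < 0.1


def test_reml_local_optimality(single_env):
    """Restricted likelihood at lambda-hat beats 0.5x and 2x lambda."""
    ds, y, _, _ = single_env
    k = genomic_kernel(ds.geno, "linear")
    x = np.ones((len(y), 1))
    fit = fit_gblup_reml(y, x, k, np.eye(len(y)))
    for factor in (0.5, 2.0):
        alt = fit_gblup_reml(y, x, k, np.eye(len(y)), lambda_fixed=fit.lambda_ * factor)
        assert fit.loglik >= alt.loglik - 1e-9


def test_y_scaling_invariance(single_env):
    ds, y, _, _ = single_env
    k = genomic_kernel(ds.geno, "linear")
    x = np.ones((len(y), 1))
    f1 = fit_gblup_reml(y, x, k, np.eye(len(y)))
    c = 3.7
    f2 = fit_gblup_reml(c * y, x, k, np.eye(len(y)))
    assert f2.sigma2_u == pytest.approx(c**2 * f1.sigma2_u, rel=1e-5)
    assert f2.sigma2_e == pytest.approx(c**2 * f1.sigma2_e, rel=1e-5)
    assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)
    assert list(np.argsort(f2.blup)) == list(np.argsort(f1.blup))


def test_unphenotyped_strain_predicted_with_lower_reliability(single_env):
    ds, y, _, _ = single_env
    k = genomic_kernel(ds.geno, "linear")
    n = len(y)
    z = np.zeros((n - 10, n))
    z[np.arange(n - 10), np.arange(n - 10)] = 1.0  # last 10 strains unobserved
    fit = fit_gblup_reml(y[: n - 10], np.ones((n - 10, 1)), k, z)
    assert np.max(fit.reliability[n - 10 :]) <= np.max(fit.reliability[: n - 10]) + 1e-8
    # predictions for unobserved strains follow kinship regression
    vinv = np.linalg.inv(z @ k.matrix @ z.T + fit.lambda_ * np.eye(n - 10))
    resid = y[: n - 10] - fit.beta[0]
    expect_tail = (k.matrix @ z.T @ vinv @ resid)[n - 10 :]
    np.testing.assert_allclose(fit.blup[n - 10 :], expect_tail, atol=1e-6)


class TestEmRidge:
    def test_self_consistency(self, single_env):
        """Converged (s2_b, s2_e) reproduce their own ridge solution."""
        _, y, m, _ = single_env
        x = np.ones((len(y), 1))
        fit = fit_em_ridge(y, x, m)
        lam = fit.sigma2_e / fit.sigma2_u
        b, _ = rrblup_marker_effects(y, x, m, lam)
        np.testing.assert_allclose(b, fit.extra["marker_effects"], atol=1e-6)

    def test_zero_response(self, single_env):
        _, _, m, _ = single_env
        y = np.zeros(m.shape[0])
        fit = fit_em_ridge(y, np.ones((len(y), 1)), m)
        assert fit.sigma2_u < 1e-10

    def test_agrees_with_reml(self, single_env):
        ds, y, m, _ = single_env
        x = np.ones((len(y), 1))
        em = fit_em_ridge(y, x, m)
        k = genomic_kernel(ds.geno, "linear")
        reml = fit_gblup_reml(y, x, k, np.eye(len(y)))
        assert abs(em.h2 - reml.h2) < 0.05


class TestSelectCandidates:
    def _fit(self, values, strains):
        n = len(strains)
        return MixedModelFit(
            sigma2_u=1.0, sigma2_e=1.0, beta=np.zeros(1), strains=strains,
            blup=np.asarray(values, float), pev=np.zeros(n),
            reliability=np.ones(n), loglik=0.0,
        )

    def test_top_bottom(self):
        fit = self._fit([3.0, 1.0, 5.0, 2.0, 4.0], list("abcde"))
        res = select_candidates(fit, k_top=2, k_bottom=2)
        assert list(res["top"]["strain"]) == ["c", "e"]
        assert list(res["bottom"]["strain"]) == ["b", "d"]

    def test_ties_break_by_id(self):
        fit = self._fit([1.0] * 4, list("dcba"))
        res = select_candidates(fit, k_top=4)
        assert list(res["top"]["strain"]) == ["a", "b", "c", "d"]

    def test_k_too_large(self):
        fit = self._fit([1.0, 2.0], ["a", "b"])
        with pytest.raises(ValueError):
            select_candidates(fit, k_top=3)

    def test_covariate_adjustment_changes_ranking(self):
        strains = list("abcd")
        fit = self._fit([1.0, 2.0, 3.0, 4.0], strains)
        cov = pd.Series([0.0, 1.0, 2.0, 3.0], index=strains)  # fully explains ranking
        res = select_candidates(fit, k_top=4, adjust=cov)
        # adjusted predictions are residuals: ties broken by ID
        assert list(res["top"]["strain"]) == strains

    def test_paper_scale_selection(self):
        rng = np.random.default_rng(1)
        strains = [f"L{i:03d}" for i in range(200)]
        fit = self._fit(rng.normal(size=200), strains)
        res = select_candidates(fit, k_top=20, k_bottom=20)
        assert len(res["top"]) == 20 and len(res["bottom"]) == 20
        assert res["top"]["prediction"].min() >= res["ranked"]["prediction"].iloc[20]
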