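"""Gibbs samplers: bookkeeping, variance recovery, model collapse, multi-trait."""

import numpy as np
import pandas as pd
import pytest

from gstk.bayes_kernel import (
    GibbsConfig,
    fit_me_model,
    fit_multitrait,
    gibbs_kernel_regression,
)
from gstk.kernels import KernelTerm, MEModelSpec, build_model_kernels, genomic_kernel
from gstk.phenotypes import merge_geno_pheno
from gstk.simulate import SimConfig, simulate_genotypes, simulate_phenotypes
from gstk.single_trait import fit_gblup_reml

FAST = GibbsConfig(n_iter=1200, burn_in=200, thin=2, seed=5)


def test_retained_draw_count_follows_schedule():
    cfg = GibbsConfig(n_iter=10_000, burn_in=2_000, thin=5, seed=0)
    assert cfg.n_retained == 1600
    assert GibbsConfig(n_iter=1000, burn_in=100, thin=3).n_retained == 300
    with pytest.raises(ValueError):
        GibbsConfig(n_iter=100, burn_in=100)


def test_retained_draws_materialize(me_dataset, linear_kernel):
    ds, omega, _, _ = me_dataset
    cfg = GibbsConfig(n_iter=300, burn_in=100, thin=4, seed=1)
    post = fit_me_model(ds, MEModelSpec("G+E"), linear_kernel, omega, cfg)
    assert post.n_retained == cfg.n_retained == 50


def test_identity_kernel_variance_decomposition():
    """Single identity term: sigma2_r + sigma2_e recovers var(y)."""
    rng = np.random.default_rng(3)
    n = 400
    y = rng.normal(0, 2.0, n)
    term = KernelTerm("I", np.eye(n), "G-main")
    post = gibbs_kernel_regression(y, np.ones((n, 1)), [term], FAST)
    vc = post.varcomp.set_index("term")["mean"]
    total = vc["I"] + vc["residual"]
    assert abs(total - y.var()) / y.var() < 0.1


def test_h2_agrees_with_reml():
    """Posterior-mean h2 tracks the REML estimate on a single-env panel."""
    cfg = SimConfig(
        n_families=15, lines_per_family=20, n_chrom=3, markers_per_chrom=100, seed=13
    )
    g, _ = simulate_genotypes(cfg)
    ph, _ = simulate_phenotypes(g, ["E1"], cfg)
    ds = merge_geno_pheno(g, ph, "trait1")
    k = genomic_kernel(ds.geno, "linear")
    y = ds.records["value"].to_numpy()
    reml = fit_gblup_reml(y, np.ones((len(y), 1)), k, np.eye(len(y)))
    post = fit_me_model(ds, MEModelSpec("G+E"), k, None, FAST)
    assert abs(post.h2_genomic - reml.h2) < 0.1


def test_chain_determinism(me_dataset, linear_kernel):
    ds, omega, _, _ = me_dataset
    cfg = GibbsConfig(n_iter=400, burn_in=100, thin=2, seed=9)
    a = fit_me_model(ds, MEModelSpec("G+E+GxE"), linear_kernel, omega, cfg)
    b = fit_me_model(ds, MEModelSpec("G+E+GxE"), linear_kernel, omega, cfg)
    np.testing.assert_array_equal(a.predictions, b.predictions)
    pd.testing.assert_frame_equal(a.varcomp, b.varcomp)


def test_term_order_exchangeable(me_dataset, linear_kernel):
    """Swapping kernel-term order changes nothing beyond Monte-Carlo error."""
    ds, omega, _, _ = me_dataset
    terms, x, _ = build_model_kernels(MEModelSpec("G+E+GxE"), ds, linear_kernel, omega)
    y = ds.records["value"].to_numpy()
    cfg = GibbsConfig(n_iter=2000, burn_in=400, thin=2, seed=3)
    p1 = gibbs_kernel_regression(y, x, terms, cfg)
    p2 = gibbs_kernel_regression(y, x, terms[::-1], cfg)
    for label in ("G", "GxE"):
        m1 = p1.varcomp.set_index("term").loc[label]
        m2 = p2.varcomp.set_index("term").loc[label]
        mc_se = m1["sd"] / np.sqrt(max(m1["ess"], 1)) + m2["sd"] / np.sqrt(max(m2["ess"], 1))
        assert abs(m1["mean"] - m2["mean"]) < 3 * mc_se + 1e-12


def test_training_prediction_sanity_floor(me_dataset, linear_kernel):
    """Every formula correlates with training y at least as well as intercept."""
    ds, omega, _, _ = me_dataset
    y = ds.records["value"].to_numpy()
    for tag in ("G+E", "G+E+GxE", "G+E+W+GxW", "G+E+GxE_i"):
        post = fit_me_model(ds, MEModelSpec(tag), linear_kernel, omega, FAST)
        assert np.corrcoef(post.predictions, y)[0, 1] > 0.0


def test_single_env_collapses_to_gblup():
    """G+E on one environment reproduces single-trait G-BLUP predictions."""
    cfg = SimConfig(
        n_families=8, lines_per_family=12, n_chrom=2, markers_per_chrom=80, seed=6
    )
    g, _ = simulate_genotypes(cfg)
    ph, _ = simulate_phenotypes(g, ["E1"], cfg)
    ds = merge_geno_pheno(g, ph, "trait1")
    k = genomic_kernel(ds.geno, "linear")
    post = fit_me_model(
        ds, MEModelSpec("G+E"), k, None, GibbsConfig(n_iter=2500, burn_in=500, thin=2, seed=4)
    )
    y = ds.records["value"].to_numpy()
    reml = fit_gblup_reml(y, np.ones((len(y), 1)), k, np.eye(len(y)))
    order = ds.records["strain"].map({t: i for i, t in enumerate(k.taxa)}).to_numpy()
    assert np.corrcoef(post.predictions, reml.blup[order] + reml.beta[0])[0, 1] > 0.99


def test_unseen_env_refusal_and_fallback(me_dataset, linear_kernel):
    ds, omega, _, _ = me_dataset
    mask = (ds.records["env"] != ds.envs[0]).to_numpy()
    with pytest.raises(ValueError, match="no W term"):
        fit_me_model(ds, MEModelSpec("G+E"), linear_kernel, omega, FAST, train_mask=mask)
    post = fit_me_model(
        ds, MEModelSpec("G+E"), linear_kernel, omega, FAST,
        train_mask=mask, allow_unseen_env=True,
    )
    assert np.isfinite(post.predictions).all()
    # W-carrying formula predicts the unseen env without the fallback flag
    post_w = fit_me_model(
        ds, MEModelSpec("G+E+W"), linear_kernel, omega, FAST, train_mask=mask
    )
    held = ~mask
    y = ds.records["value"].to_numpy()
    assert np.corrcoef(post_w.predictions[held], y[held])[0, 1] > 0.0


class TestMultiTrait:
    @staticmethod
    def _panel(rg, h2, seed, n_fam=15, lpf=20):
        cfg = SimConfig(
            n_families=n_fam, lines_per_family=lpf, n_chrom=3, markers_per_chrom=100,
            n_envs=1, h2=h2, trait_corr=np.array([[1.0, rg], [rg, 1.0]]), seed=seed,
        )
        g, _ = simulate_genotypes(cfg)
        ph, _ = simulate_phenotypes(g, ["E1"], cfg)
        yw = ph.pivot(index="strain", columns="trait", values="value")
        return yw, genomic_kernel(g, "linear"), g

    def test_null_genetic_correlation(self):
        yw, k, _ = self._panel(0.0, (0.5, 0.5), seed=3)
        fit = fit_multitrait(yw, k, GibbsConfig(n_iter=2000, burn_in=400, thin=4, seed=2))
        assert abs(fit.genetic_correlation[0, 1]) < 0.2

    def test_strong_genetic_correlation(self):
        yw, k, _ = self._panel(0.8, (0.5, 0.5), seed=3)
        fit = fit_multitrait(yw, k, GibbsConfig(n_iter=2000, burn_in=400, thin=4, seed=2))
        assert 0.6 <= fit.genetic_correlation[0, 1] <= 0.95

    def test_sigma_g_psd_every_draw(self):
        yw, k, _ = self._panel(0.5, (0.5, 0.5), seed=4, n_fam=8, lpf=10)
        fit = fit_multitrait(yw, k, GibbsConfig(n_iter=600, burn_in=100, thin=2, seed=1))
        assert fit.draws["all_psd"]
        for draw in fit.draws["sigma_g"]:
            assert np.linalg.eigvalsh(draw).min() >= -1e-10

    def test_single_trait_redirected(self):
        yw, k, _ = self._panel(0.0, (0.5, 0.5), seed=5, n_fam=4, lpf=5)
        with pytest.raises(ValueError, match="single-trait"):
            fit_multitrait(yw[["trait1"]], k, FAST)

    def test_spike_slab_rejected(self):
        yw, k, _ = self._panel(0.0, (0.5, 0.5), seed=5, n_fam=4, lpf=5)
        with pytest.raises(ValueError, match="not available"):
            fit_multitrait(yw, k, FAST, method="spike-slab")

    def test_brr_marker_variant_runs(self):
        yw, k, g = self._panel(0.5, (0.5, 0.5), seed=6, n_fam=6, lpf=8)
        fit = fit_multitrait(
            yw, k, GibbsConfig(n_iter=600, burn_in=100, thin=2, seed=1),
            method="BRR-markers", geno=g,
        )
        assert fit.predictions.shape == yw.shape

    def test_masked_cells_sampled(self):
        yw, k, _ = self._panel(0.8, (0.3, 0.6), seed=7, n_fam=8, lpf=10)
        mask = pd.DataFrame({"strain": yw.index[:10], "trait": "trait1"})
        fit = fit_multitrait(
            yw, k, GibbsConfig(n_iter=800, burn_in=200, thin=2, seed=3), mask_cells=mask
        )
        assert np.isfinite(fit.predictions.to_numpy()).all()
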