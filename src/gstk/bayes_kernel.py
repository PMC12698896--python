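"""Gibbs samplers for kernel-based genomic prediction.

Single-trait, multi-environment reaction-norm models

    y = X beta + sum_r u_r + e,   u_r ~ N(0, sigma2_r K_r),
    e ~ N(0, sigma2_e I)

are sampled by diagonalizing each covariance term once (eigenvalues below
1e-10 of the largest are truncated) and updating the random effect in the
rotated basis, where its full conditional is diagonal.  Variance
components get scaled-inverse-chi-square full conditionals; fixed effects
a normal full conditional under a flat prior.  Held-out records (missing
or masked phenotypes) are handled by data augmentation: their y is
resampled from the model each sweep, so parameter draws marginally follow
the posterior given the observed records only while random effects stay
defined over the full kernel support.

The multi-trait sampler is a multivariate kernel G-BLUP:

    Y = 1 mu' + U + E,   U ~ MN(0, K, Sigma_g),   E ~ MN(0, I, Sigma_e)

with inverse-Wishart full conditionals on the trait covariance matrices
and within-sampler imputation of missing trait cells (which is what makes
CV2-style borrowing from observed secondary traits work).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .enviromics import EnvKernel
from .kernels import (
    GenomicKernel,
    KernelTerm,
    MEModelSpec,
    build_model_kernels,
    genomic_kernel,
    incidence,
)
from .phenotypes import MergedDataset

__all__ = [
    "GibbsConfig",
    "PosteriorSummary",
    "MultiTraitFit",
    "gibbs_kernel_regression",
    "fit_me_model",
    "fit_multitrait",
]

EIG_TRUNC = 1e-10


@dataclass
class GibbsConfig:
    """Sampler lengths and priors.

    Defaults follow common practice for kernel G-BLUP samplers: 10,000
    iterations, 2,000 burn-in, thinning 5 (1,600 retained draws);
    scaled-inverse-chi-square priors with df0 = 5 and prior modes
    allocating ``r2`` of var(y) equally among the random terms.
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    df0: float = 5.0
    r2: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.df0 <= 0 or not (0 < self.r2 < 1):
            raise ValueError("df0 must be > 0 and r2 in (0,1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def _ess(draws: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of one chain."""
    x = np.asarray(draws, float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] < 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


@dataclass
class PosteriorSummary:
    """Posterior means/sds of variance components plus record predictions."""

    varcomp: pd.DataFrame  # term, mean, sd, ess
    beta_mean: np.ndarray
    predictions: np.ndarray  # posterior mean of X beta + sum_r u_r per record
    n_retained: int
    draws: dict = field(default_factory=dict)  # label -> retained draws

    def varcomp_mean(self, label: str) -> float:
        return float(self.varcomp.set_index("term").loc[label, "mean"])

    @property
    def h2_genomic(self) -> float:
        """Genomic heritability on the phenotypic-variance scale.

        Each term's variance is weighted by its kernel's mean diagonal
        (the scale at which it contributes to phenotypic variance).
        """
        vc = self.varcomp.set_index("term")
        expressed = vc["mean"] * vc["mean_diag"]
        g = expressed.get("G", 0.0)
        return float(g / expressed.sum())


def gibbs_kernel_regression(
    y: np.ndarray,
    x_fixed: np.ndarray,
    terms: list[KernelTerm],
    cfg: GibbsConfig,
    train_mask: np.ndarray | None = None,
) -> PosteriorSummary:
    """Sample the kernel regression posterior.

    Parameters
    ----------
    y
        Record responses; NaN entries are treated as held out.
    x_fixed
        Fixed design including intercept; must be full column rank and
        identified from the training records alone.
    terms
        PSD covariance terms over all records (training and held-out).
    cfg
        Sampler configuration; ``cfg.seed`` fully determines the chain.
    train_mask
        Boolean mask of training records (default: all non-NaN y).
    """
    y = np.asarray(y, float).ravel()
    x = np.atleast_2d(np.asarray(x_fixed, float))
    n = len(y)
    if train_mask is None:
        train_mask = ~np.isnan(y)
    else:
        train_mask = np.asarray(train_mask, bool) & ~np.isnan(y)
    if cfg.n_retained < 50:
        warnings.warn(
            f"only {cfg.n_retained} retained draws; summaries will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    n_terms = len(terms)
    var_y = float(np.var(y[train_mask]))
    if var_y == 0:
        var_y = 1.0

    # one-time diagonalization of every term
    eigs = []
    for term in terms:
        w, v = np.linalg.eigh((term.matrix + term.matrix.T) / 2.0)
        keep = w > EIG_TRUNC * max(w.max(), 1.0)
        if not keep.any():
            raise ValueError(f"kernel term {term.label!r} has no positive eigenvalues")
        eigs.append((v[:, keep], w[keep]))

    mean_diag = [max(np.mean(np.diag(t.matrix)), 1e-12) for t in terms]
    s_r = [
        cfg.r2 * var_y / n_terms * (cfg.df0 + 2) / cfg.df0 / md for md in mean_diag
    ]
    s_e = (1 - cfg.r2) * var_y * (cfg.df0 + 2) / cfg.df0

    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx + 1e-12 * np.eye(x.shape[1]))
    chol_xtx_inv = np.linalg.cholesky(xtx_inv)

    sigma2 = np.full(n_terms, cfg.r2 * var_y / n_terms)
    sigma2_e = (1 - cfg.r2) * var_y
    beta = xtx_inv @ (x.T @ np.nan_to_num(y))
    u = np.zeros((n_terms, n))
    y_work = y.copy()
    y_work[~train_mask] = (x @ beta)[~train_mask]
    resid = y_work - x @ beta - u.sum(axis=0)

    n_ret = cfg.n_retained
    vc_draws = np.empty((n_ret, n_terms + 1))
    beta_acc = np.zeros_like(beta)
    pred_acc = np.zeros(n)
    ret = 0
    for it in range(cfg.n_iter):
        # random effects, one term at a time in the rotated basis
        for r, (v_r, d_r) in enumerate(eigs):
            e_r = resid + u[r]
            t = v_r.T @ e_r
            post_var = 1.0 / (1.0 / sigma2_e + 1.0 / (sigma2[r] * d_r))
            post_mean = post_var * t / sigma2_e
            alpha = post_mean + np.sqrt(post_var) * rng.standard_normal(len(d_r))
            u_new = v_r @ alpha
            resid = e_r - u_new
            u[r] = u_new
            ss = float(np.sum(alpha**2 / d_r))
            sigma2[r] = (cfg.df0 * s_r[r] + ss) / rng.chisquare(cfg.df0 + len(d_r))
        # fixed effects
        e_beta = resid + x @ beta
        beta_mean = xtx_inv @ (x.T @ e_beta)
        beta_new = beta_mean + np.sqrt(sigma2_e) * (
            chol_xtx_inv @ rng.standard_normal(len(beta))
        )
        resid = e_beta - x @ beta_new
        beta = beta_new
        # residual variance from training records only
        ee = float(resid[train_mask] @ resid[train_mask])
        sigma2_e = (cfg.df0 * s_e + ee) / rng.chisquare(cfg.df0 + train_mask.sum())
        if not np.isfinite(sigma2_e) or sigma2_e <= 0:
            raise RuntimeError("non-finite residual variance draw")
        # data augmentation for held-out records
        eta = x @ beta + u.sum(axis=0)
        miss = ~train_mask
        if miss.any():
            y_work[miss] = eta[miss] + np.sqrt(sigma2_e) * rng.standard_normal(
                miss.sum()
            )
            resid[miss] = y_work[miss] - eta[miss]
        # retain
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and ret < n_ret:
            vc_draws[ret] = np.concatenate([sigma2, [sigma2_e]])
            beta_acc += beta
            pred_acc += eta
            ret += 1

    labels = [t.label for t in terms] + ["residual"]
    varcomp = pd.DataFrame(
        {
            "term": labels,
            "mean": vc_draws[:ret].mean(axis=0),
            "sd": vc_draws[:ret].std(axis=0, ddof=1),
            "ess": [_ess(vc_draws[:ret, j]) for j in range(len(labels))],
            "mean_diag": mean_diag + [1.0],
        }
    )
    return PosteriorSummary(
        varcomp=varcomp,
        beta_mean=beta_acc / ret,
        predictions=pred_acc / ret,
        n_retained=ret,
        draws={"varcomp": vc_draws[:ret], "varcomp_labels": labels},
    )


def _env_fixed_design_with_fallback(
    env_labels: pd.Series, train_mask: np.ndarray
) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded env design identified from training envs only.

    Records in environments unseen during training get the average of the
    training env effects: a row of 1/L in every treatment column.
    """
    train_levels = list(pd.unique(env_labels[train_mask]))
    n = len(env_labels)
    cols = train_levels[1:]
    x = np.zeros((n, 1 + len(cols)))
    x[:, 0] = 1.0
    seen = set(train_levels)
    l = len(train_levels)
    for i, lab in enumerate(env_labels):
        if lab in seen:
            if lab in cols:
                x[i, 1 + cols.index(lab)] = 1.0
        else:
            x[i, 1:] = 1.0 / l
    names = ["intercept"] + [f"env[{c}]" for c in cols]
    unseen = sorted(set(env_labels) - seen)
    return x, names, unseen


def fit_me_model(
    dataset: MergedDataset,
    spec: MEModelSpec,
    k_g: GenomicKernel,
    omega: EnvKernel | None,
    cfg: GibbsConfig,
    train_mask: np.ndarray | None = None,
    allow_unseen_env: bool = False,
) -> PosteriorSummary:
    """Fit one multi-environment formula and predict every record.

    Kernels are assembled over all records (training and held-out) so the
    sampled random effects extend to held-out cells.  Records in
    environments absent from training are predictable only when the
    formula carries W terms (the env kernel row supplies borrowing) or
    when ``allow_unseen_env`` explicitly accepts genotype-main-effect
    predictions with the unseen env's fixed effect set to the mean of the
    training env effects.
    """
    rec = dataset.records
    y = rec["value"].to_numpy(float)
    n = len(y)
    if train_mask is None:
        train_mask = ~np.isnan(y)
    train_mask = np.asarray(train_mask, bool) & ~np.isnan(y)

    terms, _, _ = build_model_kernels(spec, dataset, k_g, omega)
    x, names, unseen = _env_fixed_design_with_fallback(rec["env"], train_mask)
    if unseen and not spec.wants_w and not allow_unseen_env:
        raise ValueError(
            f"environments {unseen} have no training records and model "
            f"{spec.tag} has no W term; pass allow_unseen_env=True to predict "
            "them from genotype main effects"
        )
    return gibbs_kernel_regression(y, x, terms, cfg, train_mask=train_mask)


# ----------------------------------------------------------------------
# multi-trait


@dataclass
class MultiTraitFit:
    """Posterior summaries of a multivariate kernel G-BLUP."""

    traits: list[str]
    strains: list[str]
    sigma_g: np.ndarray  # posterior mean genetic covariance (T x T)
    sigma_e: np.ndarray  # posterior mean residual covariance
    genetic_correlation: np.ndarray
    predictions: pd.DataFrame  # strain x trait posterior-mean mu + u
    n_retained: int
    draws: dict = field(default_factory=dict)


def _fill_missing_cells(rng, y_work, eta, obs, patterns, sigma):
    """Resample unobserved trait cells from their conditional normals.

    Rows are grouped by missingness pattern so each pattern needs one
    Schur complement and one Cholesky per sweep.
    """
    resid = y_work - eta
    for pat, rows in patterns:
        mis = ~pat
        if pat.any():
            s_oo = sigma[np.ix_(pat, pat)]
            s_mo = sigma[np.ix_(mis, pat)]
            mean = resid[np.ix_(rows, np.flatnonzero(pat))] @ np.linalg.solve(s_oo, s_mo.T).T
            cov = sigma[np.ix_(mis, mis)] - s_mo @ np.linalg.solve(s_oo, s_mo.T)
        else:
            mean = np.zeros((len(rows), int(mis.sum())))
            cov = sigma[np.ix_(mis, mis)]
        cov = (cov + cov.T) / 2 + 1e-12 * np.eye(int(mis.sum()))
        chol = np.linalg.cholesky(cov)
        draw = mean + rng.standard_normal(mean.shape) @ chol.T
        y_work[np.ix_(rows, np.flatnonzero(mis))] = (
            eta[np.ix_(rows, np.flatnonzero(mis))] + draw
        )


def fit_multitrait(
    y_wide: pd.DataFrame,
    k: GenomicKernel,
    cfg: GibbsConfig,
    method: str = "RKHS-kernel",
    geno=None,
    mask_cells: pd.DataFrame | None = None,
) -> MultiTraitFit:
    """Multivariate kernel G-BLUP by Gibbs sampling.

    Parameters
    ----------
    y_wide
        Strains x traits DataFrame (index = strain IDs); NaN cells are
        sampled within the chain.
    k
        Genomic kernel over (at least) the phenotyped strains; used
        directly for ``method="RKHS-kernel"``.
    method
        ``"RKHS-kernel"`` uses ``k`` as given; ``"BRR-markers"`` is the
        marker-effect Bayesian ridge variant, fit in its exact kernel
        dual form with the linear marker kernel built from ``geno``.
        Spike-slab multivariate regression is not provided.
    geno
        DosageMatrix, required for ``method="BRR-markers"``.
    mask_cells
        Optional DataFrame (strain, trait) of additional cells to treat
        as unobserved (CV masking).
    """
    if method == "BRR-markers":
        if geno is None:
            raise ValueError("BRR-markers requires the dosage matrix (geno=...)")
        k = genomic_kernel(geno, kind="linear")
    elif method != "RKHS-kernel":
        raise ValueError(
            f"method {method!r} not available; use 'RKHS-kernel' or 'BRR-markers' "
            "(multivariate spike-slab regression is not implemented)"
        )
    traits = list(y_wide.columns)
    t_dim = len(traits)
    if t_dim < 2:
        raise ValueError("multi-trait fit needs >= 2 traits; use the single-trait path")
    strains = list(y_wide.index.astype(str))
    kidx = k.taxon_index()
    missing = [s for s in strains if s not in kidx]
    if missing:
        raise ValueError(f"strains absent from kernel: {missing[:5]}")
    km = k.matrix[np.ix_([kidx[s] for s in strains], [kidx[s] for s in strains])]

    y = y_wide.to_numpy(float)
    obs = ~np.isnan(y)
    if mask_cells is not None:
        for _, row in mask_cells.iterrows():
            obs[strains.index(str(row["strain"])), traits.index(row["trait"])] = False
    n = len(strains)
    rng = np.random.default_rng(cfg.seed)

    w, v = np.linalg.eigh((km + km.T) / 2.0)
    keep = w > EIG_TRUNC * max(w.max(), 1.0)
    v, d = v[:, keep], w[keep]
    n_comp = keep.sum()

    var_t = np.array([np.nanvar(np.where(obs[:, j], y[:, j], np.nan)) for j in range(t_dim)])
    var_t[~np.isfinite(var_t) | (var_t == 0)] = 1.0
    nu0 = cfg.df0 + t_dim - 1
    s0_g = np.diag(cfg.r2 * var_t) * (nu0 - t_dim - 1)
    s0_e = np.diag((1 - cfg.r2) * var_t) * (nu0 - t_dim - 1)

    sigma_g = np.diag(cfg.r2 * var_t)
    sigma_e = np.diag((1 - cfg.r2) * var_t)
    col_means = np.array(
        [np.nanmean(np.where(obs[:, j], y[:, j], np.nan)) for j in range(t_dim)]
    )
    col_means[~np.isfinite(col_means)] = 0.0
    mu = col_means.copy()
    u = np.zeros((n, t_dim))
    y_work = np.where(obs, y, col_means[None, :])
    # group incomplete rows by missingness pattern for batched imputation
    patterns = []
    incomplete = np.flatnonzero(~obs.all(axis=1))
    if incomplete.size:
        pats = {}
        for i in incomplete:
            pats.setdefault(tuple(obs[i]), []).append(i)
        patterns = [(np.array(p, bool), np.array(rows)) for p, rows in pats.items()]

    n_ret = cfg.n_retained
    ret = 0
    sg_acc = np.zeros((t_dim, t_dim))
    se_acc = np.zeros((t_dim, t_dim))
    pred_acc = np.zeros((n, t_dim))
    sg_draws = np.empty((n_ret, t_dim, t_dim))
    psd_ok = True
    for it in range(cfg.n_iter):
        sigma_e_inv = np.linalg.inv(sigma_e)
        sigma_g_inv = np.linalg.inv(sigma_g)
        # rotated genetic effects, rows independent
        r = v.T @ (y_work - mu[None, :])
        prec = sigma_e_inv[None, :, :] + sigma_g_inv[None, :, :] / d[:, None, None]
        cov = np.linalg.inv(prec)
        mean = np.einsum("ijk,ik->ij", cov, r @ sigma_e_inv.T)
        chol = np.linalg.cholesky((cov + np.transpose(cov, (0, 2, 1))) / 2)
        ustar = mean + np.einsum(
            "ijk,ik->ij", chol, rng.standard_normal((n_comp, t_dim))
        )
        u = v @ ustar
        # trait covariances
        s_g = s0_g + np.einsum("ij,ik->jk", ustar / d[:, None], ustar)
        sigma_g = invwishart.rvs(df=nu0 + n_comp, scale=s_g, random_state=rng)
        e = y_work - mu[None, :] - u
        s_e = s0_e + e.T @ e
        sigma_e = invwishart.rvs(df=nu0 + n, scale=s_e, random_state=rng)
        sigma_g = np.atleast_2d(sigma_g)
        sigma_e = np.atleast_2d(sigma_e)
        # intercepts
        mu_mean = (y_work - u).mean(axis=0)
        mu = mu_mean + np.linalg.cholesky(sigma_e / n) @ rng.standard_normal(t_dim)
        # impute unobserved cells given observed traits of the same record
        eta = mu[None, :] + u
        if patterns:
            _fill_missing_cells(rng, y_work, eta, obs, patterns, sigma_e)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and ret < n_ret:
            sg_draws[ret] = sigma_g
            sg_acc += sigma_g
            se_acc += sigma_e
            pred_acc += eta
            if np.linalg.eigvalsh(sigma_g).min() < -1e-10:
                psd_ok = False
            ret += 1

    sigma_g_hat = sg_acc / ret
    sigma_e_hat = se_acc / ret
    dd = np.sqrt(np.diag(sigma_g_hat))
    rg = sigma_g_hat / np.outer(dd, dd)
    return MultiTraitFit(
        traits=traits,
        strains=strains,
        sigma_g=sigma_g_hat,
        sigma_e=sigma_e_hat,
        genetic_correlation=rg,
        predictions=pd.DataFrame(pred_acc / ret, index=strains, columns=traits),
        n_retained=ret,
        draws={"sigma_g": sg_draws[:ret], "all_psd": psd_ok},
    )
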