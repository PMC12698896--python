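"""Single-trait genomic prediction: G-BLUP by REML, RR-BLUP, EM ridge.

The core model is

    y = X b + Z u + e,   u ~ N(0, sigma2_u K),   e ~ N(0, sigma2_e I)

with K a genomic kernel over all candidate strains (phenotyped or not)
and Z the record->strain incidence restricted to phenotyped strains.
REML profiles the restricted likelihood over the variance ratio
lambda = sigma2_e / sigma2_u via a single spectral decomposition of the
phenotypic covariance structure projected off the fixed effects, then
recovers BLUPs, prediction error variances (PEV), and reliabilities from
the solution at the optimum.  Strains without records are predicted by
kinship regression on the estimated effects of phenotyped strains
(K_21 K_11^{-1} u_hat), which is exactly what the full-kernel BLUP
equations deliver.

RR-BLUP estimates marker effects at a fixed ridge parameter and is the
exact dual of G-BLUP under the linear kernel; the EM ridge variant
("emRR") iterates expectation-maximization updates on
(sigma2_b, sigma2_e) instead of profiling a likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kernels import GenomicKernel

__all__ = [
    "MixedModelFit",
    "fit_gblup_reml",
    "solve_mme",
    "rrblup_marker_effects",
    "fit_em_ridge",
    "select_candidates",
]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class MixedModelFit:
    """Variance components, fixed effects, BLUPs, PEV and reliability."""

    sigma2_u: float
    sigma2_e: float
    beta: np.ndarray
    strains: list[str]
    blup: np.ndarray  # u_hat per strain (all strains in K)
    pev: np.ndarray  # prediction error variance per strain
    reliability: np.ndarray  # 1 - PEV_i / (sigma2_u K_ii)
    loglik: float  # restricted log-likelihood at the optimum
    lambda_: float = np.nan
    converged: bool = True
    k_diag_mean: float = 1.0  # mean kernel diagonal (inbred panels: ~2)
    extra: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        """Genomic heritability as a phenotypic-variance fraction.

        The genetic variance expressed in the phenotype is
        sigma2_u * mean(K_ii), so the kernel's diagonal scale (about 2
        for a VanRaden kernel over inbred lines) is folded in.
        """
        vg = self.sigma2_u * self.k_diag_mean
        tot = vg + self.sigma2_e
        return vg / tot if tot > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strains,
                "prediction": self.blup,
                "pev": self.pev,
                "reliability": self.reliability,
            }
        )


def _restricted_loglik(lam: float, theta: np.ndarray, omega2: np.ndarray) -> float:
    """Profiled restricted log-likelihood (up to a constant) at ratio lam."""
    n = len(theta)
    denom = theta + lam
    s2 = np.sum(omega2 / denom) / n
    return -0.5 * (n * np.log(s2) + np.sum(np.log(denom)))


def fit_gblup_reml(
    y: np.ndarray,
    x: np.ndarray,
    k: GenomicKernel,
    z: np.ndarray,
    lambda_fixed: float | None = None,
) -> MixedModelFit:
    """G-BLUP with REML variance estimation.

    Parameters
    ----------
    y : (n,) record response vector.
    x : (n, p) fixed-effects design (include the intercept column).
    k : genomic kernel over all candidate strains.
    z : (n, q) record->strain incidence (q = len(k.taxa)).
    lambda_fixed
        Skip the REML search and solve at this variance ratio (used for
        oracle checks and fast refits).

    Notes
    -----
    The restricted likelihood is profiled over lambda on the spectrum of
    the projected covariance S (Z K Z') S, computed once; the search
    brackets lambda in [1e-6, 1e6] on the log scale.  A boundary optimum
    is reported with ``converged=False`` and a warning.
    """
    y = np.asarray(y, float).ravel()
    x = np.atleast_2d(np.asarray(x, float))
    n, p = x.shape
    if n != len(y) or z.shape[0] != n:
        raise ValueError("dimension mismatch between y, X, Z")
    if n < np.linalg.matrix_rank(x) + 2:
        raise ValueError("too few records for the fixed design")
    lam_min = min_eig = float(np.linalg.eigvalsh((k.matrix + k.matrix.T) / 2).min())
    if min_eig < -1e-8:
        raise ValueError(f"kernel is not PSD (min eigenvalue {min_eig:.3g})")

    h = z @ k.matrix @ z.T
    # orthonormal basis of the complement of col(X)
    q_full, _ = np.linalg.qr(x, mode="complete")
    q2 = q_full[:, np.linalg.matrix_rank(x) :]  # n x (n - rank)
    hp = q2.T @ h @ q2
    theta, vec = np.linalg.eigh((hp + hp.T) / 2)
    theta = np.maximum(theta, 0.0)
    omega = vec.T @ (q2.T @ y)
    omega2 = omega**2

    converged = True
    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    else:
        res = minimize_scalar(
            lambda ll: -_restricted_loglik(np.exp(ll), theta, omega2),
            bounds=np.log(LAMBDA_BOUNDS),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        if lam <= LAMBDA_BOUNDS[0] * 1.01 or lam >= LAMBDA_BOUNDS[1] * 0.99:
            warnings.warn(
                f"REML ratio at search boundary (lambda={lam:.3g}); "
                "likelihood may be flat",
                stacklevel=2,
            )
            converged = False
    m = len(theta)
    sigma2_u = float(np.sum(omega2 / (theta + lam)) / m)
    sigma2_e = lam * sigma2_u
    loglik = _restricted_loglik(lam, theta, omega2)

    # GLS fixed effects and full-kernel BLUPs at the optimum
    v = h + lam * np.eye(n)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ beta
    kz = k.matrix @ z.T  # q x n
    u_hat = kz @ (vinv @ r)

    # PEV over all strains: sigma2_u * (K - K Z' P Z K), P the REML projector
    pmat = vinv - vinv @ x @ np.linalg.solve(xtvx, x.T @ vinv)
    cov_shrink = kz @ pmat @ kz.T
    pev = sigma2_u * np.maximum(np.diag(k.matrix) - np.diag(cov_shrink), 0.0)
    kdiag = np.diag(k.matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(
            (sigma2_u > 0) & (kdiag > 0), 1.0 - pev / (sigma2_u * kdiag), 0.0
        )
    rel = np.clip(rel, 0.0, 1.0)
    return MixedModelFit(
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        beta=beta,
        strains=list(k.taxa),
        blup=u_hat,
        pev=pev,
        reliability=rel,
        loglik=float(loglik),
        lambda_=lam,
        converged=converged,
        k_diag_mean=float(np.mean(np.diag(k.matrix))),
    )


def solve_mme(
    y: np.ndarray, x: np.ndarray, k: np.ndarray, z: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dense mixed-model-equation solve at a fixed variance ratio.

    Independent route to the BLUP solution: builds and inverts the full
    Henderson coefficient matrix with K^{-1} (jittered only when K is
    near-singular, as the VanRaden kernel always is).  Returns (beta, u).
    Intended for small instances and cross-checks.
    """
    ev = np.linalg.eigvalsh((k + k.T) / 2)
    jitter = 0.0 if ev.min() > 1e-10 * max(ev.max(), 1.0) else 1e-10
    kinv = np.linalg.inv(k + jitter * np.eye(len(k)))
    top = np.hstack([x.T @ x, x.T @ z])
    bottom = np.hstack([z.T @ x, z.T @ z + lam * kinv])
    coeff = np.vstack([top, bottom])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    sol = np.linalg.solve(coeff, rhs)
    p = x.shape[1]
    return sol[:p], sol[p:]


def rrblup_marker_effects(
    y: np.ndarray, x: np.ndarray, m: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-regression BLUP of marker effects at a fixed ridge parameter.

    ``b_hat = (M' S M + lam I)^{-1} M' S y`` with S the residual-forming
    projection off the fixed design; GEBV = M b_hat.  Exact dual of
    G-BLUP under K = M M' / c with lam scaled by c.
    """
    y = np.asarray(y, float).ravel()
    m = np.asarray(m, float)
    x = np.atleast_2d(np.asarray(x, float))
    s = np.eye(len(y)) - x @ np.linalg.pinv(x)
    a = m.T @ s @ m + lam * np.eye(m.shape[1])
    b = np.linalg.solve(a, m.T @ s @ y)
    return b, m @ b


def fit_em_ridge(
    y: np.ndarray,
    x: np.ndarray,
    m: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MixedModelFit:
    """Expectation-maximization ridge regression on marker effects.

    Model: y = X beta + M b + e with b ~ N(0, sigma2_b I).  E-step
    computes the posterior mean/covariance of b at the current variance
    components; M-step updates sigma2_b from E[b'b]/m and sigma2_e from
    the expected residual sum of squares.  Returns GEBVs (M b_hat) in the
    ``blup`` slot with one pseudo-strain per record.
    """
    y = np.asarray(y, float).ravel()
    m_mat = np.asarray(m, float)
    x = np.atleast_2d(np.asarray(x, float))
    n, p = x.shape
    n_markers = m_mat.shape[1]
    sigma2_e = float(np.var(y)) / 2 + 1e-12
    sigma2_b = sigma2_e / n_markers + 1e-12
    beta = np.linalg.pinv(x) @ y
    # dual (n x n) form so m >> n stays well-posed even as lambda -> 0:
    # (M'M + lam I)^{-1} M' = M' Q diag(1/(gamma_i + lam)) Q', M M' = Q G Q'
    gram = m_mat @ m_mat.T
    gamma, q_vec = np.linalg.eigh((gram + gram.T) / 2)
    gamma = np.maximum(gamma, 0.0)
    converged = False
    for it in range(max_iter):
        lam = sigma2_e / sigma2_b
        qty = q_vec.T @ (y - x @ beta)
        b_hat = m_mat.T @ (q_vec @ (qty / (gamma + lam)))
        beta = np.linalg.pinv(x) @ (y - m_mat @ b_hat)
        resid = y - x @ beta - m_mat @ b_hat
        # tr(C) and tr(M'M C) from the spectrum of M M'
        tr_fit = float(np.sum(gamma / (gamma + lam)))
        tr_c = (n_markers - tr_fit) / lam
        # E[b'b] = b_hat'b_hat + sigma2_e tr(C); E[e'e] adds the fit-term trace
        new_b = float(b_hat @ b_hat + sigma2_e * tr_c) / n_markers
        new_e = float(resid @ resid + sigma2_e * tr_fit) / n
        delta = abs(new_b - sigma2_b) / max(sigma2_b, 1e-300) + abs(
            new_e - sigma2_e
        ) / max(sigma2_e, 1e-300)
        sigma2_b, sigma2_e = max(new_b, 1e-300), max(new_e, 1e-300)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM ridge hit max_iter={max_iter}", stacklevel=2)
    gebv = m_mat @ b_hat
    return MixedModelFit(
        sigma2_u=sigma2_b,
        sigma2_e=sigma2_e,
        beta=beta,
        strains=[f"rec{i}" for i in range(n)],
        blup=gebv,
        pev=np.full(n, np.nan),
        reliability=np.full(n, np.nan),
        loglik=np.nan,
        lambda_=sigma2_e / sigma2_b,
        converged=converged,
        k_diag_mean=float(np.trace(gram) / n),  # genic variance scale
        extra={"marker_effects": b_hat, "n_iter": it + 1},
    )


def select_candidates(
    fit: MixedModelFit,
    k_top: int,
    k_bottom: int = 0,
    adjust: pd.Series | None = None,
) -> dict:
    """Rank strains by (optionally covariate-adjusted) prediction.

    When ``adjust`` (a per-strain covariate such as maturity date) is
    given, predictions are replaced by residuals of their OLS regression
    on the covariate before ranking.  Ties break by strain ID.  Returns
    {"top": DataFrame, "bottom": DataFrame, "ranked": DataFrame}.
    """
    n = len(fit.strains)
    if k_top > n or k_bottom > n:
        raise ValueError(f"k exceeds the {n} available strains")
    pred = pd.Series(fit.blup, index=fit.strains, name="prediction")
    if adjust is not None:
        cov = adjust.reindex(pred.index)
        if cov.isna().any():
            raise ValueError("adjust covariate missing for some strains")
        a = np.vstack([np.ones(n), cov.to_numpy(float)]).T
        coef, *_ = np.linalg.lstsq(a, pred.to_numpy(), rcond=None)
        pred = pred - a @ coef + coef[0]
    ranked = (
        pred.rename_axis("strain")
        .reset_index()
        .sort_values(["prediction", "strain"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranked["rank"] = np.arange(1, n + 1)
    return {
        "top": ranked.head(k_top).reset_index(drop=True),
        "bottom": ranked.tail(k_bottom).iloc[::-1].reset_index(drop=True),
        "ranked": ranked,
    }
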