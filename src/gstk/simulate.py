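"""Synthetic data generators: biparental families, environments, phenotypes.

Every downstream stage of the pipeline is exercised against data produced
here, so the generators return full simulation truth (QTL effects, true
breeding values, variance components) alongside the observable data.  The
population emulated is a public soybean-style breeding panel: near-inbred
lines derived from biparental crosses of a modest founder set, genotyped
on a SNP panel, phenotyped as per-environment BLUEs in a handful of
multi-environment trial locations with weather covariates.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .core import MISSING, DosageMatrix
from .enviromics import POWER_COVARIATES, EnvCovariateMatrix, EnvSpec

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_env_covariates",
    "simulate_phenotypes",
    "simulate_plot_data",
    "mask_genotypes",
]


@dataclass
class SimConfig:
    """Configuration for the synthetic breeding program.

    Genotype defaults give a panel of 10 biparental families x 20 lines
    (200 near-inbred lines) on 5 chromosomes x 200 markers.  Trait
    defaults: one trait with narrow-sense heritability 0.5 on the
    per-record (BLUE) basis.  Environment defaults: 7 locations with the
    standard weather-covariate set over a May 1 - Nov 30 season,
    matching a northern-latitude soybean trial network.
    """

    n_founders: int = 20
    n_families: int = 10
    lines_per_family: int = 20
    n_chrom: int = 5
    markers_per_chrom: int = 200
    map_length_morgans: float = 1.0
    chrom_length_bp: int = 100_000_000
    residual_het_rate: float = 0.02
    # traits
    n_qtl: int = 100
    h2: tuple[float, ...] = (0.5,)
    trait_corr: np.ndarray | None = None
    # environments
    n_envs: int = 7
    covariates: tuple[str, ...] = tuple(dict.fromkeys(POWER_COVARIATES))
    window_start: date = date(2023, 5, 1)
    window_end: date = date(2023, 11, 30)
    gxe_variance_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.window_start, str):
            self.window_start = date.fromisoformat(self.window_start)
        if isinstance(self.window_end, str):
            self.window_end = date.fromisoformat(self.window_end)
        for h in self.h2:
            if not (0.0 < h < 1.0):
                raise ValueError("h2 must be in (0,1)")
        if self.trait_corr is not None:
            c = np.asarray(self.trait_corr, float)
            if c.shape != (len(self.h2), len(self.h2)):
                raise ValueError("trait_corr shape must match number of traits")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("trait_corr must be PSD")
            self.trait_corr = c

    @property
    def n_traits(self) -> int:
        return len(self.h2)


@dataclass
class SimTruth:
    """Everything needed to score a downstream method without real data."""

    qtl_sites: np.ndarray  # site indices into the genotype matrix
    qtl_effects: np.ndarray  # (n_qtl, n_traits) additive effects
    tbv: pd.DataFrame  # columns strain, env, trait, tbv (g + gxe)
    g_main: pd.DataFrame  # columns strain, trait, g (env-independent part)
    var_components: dict  # per-trait dict: sigma2_g, sigma2_gxe, sigma2_e
    realized_h2: dict  # per-trait realized var(tbv)/var(y - env mean)


# ----------------------------------------------------------------------
# genotypes


def _founder_haplotypes(rng, cfg: SimConfig) -> np.ndarray:
    """Inbred founder haplotypes with block-copy LD along each chromosome.

    Alleles follow a Markov chain along sites: with probability 0.9 the
    allele state at site j copies an ancestral block continuation; a
    switch redraws from the site's population frequency.
    """
    m = cfg.n_chrom * cfg.markers_per_chrom
    freq = rng.uniform(0.1, 0.9, size=m)
    hap = np.empty((cfg.n_founders, m), dtype=np.int8)
    for c in range(cfg.n_chrom):
        lo = c * cfg.markers_per_chrom
        hap[:, lo] = rng.random(cfg.n_founders) < freq[lo]
        for j in range(lo + 1, lo + cfg.markers_per_chrom):
            switch = rng.random(cfg.n_founders) < 0.1
            redraw = (rng.random(cfg.n_founders) < freq[j]).astype(np.int8)
            hap[:, j] = np.where(switch, redraw, hap[:, j - 1])
    return hap


def simulate_genotypes(cfg: SimConfig) -> tuple[DosageMatrix, pd.DataFrame]:
    """Simulate near-inbred biparental-family genotypes.

    Families are random founder pairs.  Each line's genome is a mosaic of
    the two parental haplotypes with Poisson crossovers (map expansion x2
    for repeated selfing); residual heterozygosity is injected at
    ``residual_het_rate`` per marker.

    Returns the dosage matrix and a pedigree table
    (line, family, parent1, parent2).
    """
    rng = np.random.default_rng(cfg.seed)
    founders = _founder_haplotypes(rng, cfg)
    m_per = cfg.markers_per_chrom
    pos_on_chrom = np.linspace(1, cfg.chrom_length_bp, m_per).round().astype(np.int64)

    taxa: list[str] = []
    ped_rows = []
    dosage_rows = []
    for fam in range(cfg.n_families):
        p1, p2 = rng.choice(cfg.n_founders, size=2, replace=False)
        for k in range(cfg.lines_per_family):
            line = f"F{fam:03d}_L{k:02d}"
            genome = np.empty(cfg.n_chrom * m_per, dtype=np.int8)
            for c in range(cfg.n_chrom):
                lo = c * m_per
                # crossover positions in Morgans; RIL map expansion ~2x
                n_co = rng.poisson(2.0 * cfg.map_length_morgans)
                co = np.sort(rng.uniform(0, cfg.map_length_morgans, size=n_co))
                marker_cm = np.linspace(0, cfg.map_length_morgans, m_per)
                seg = np.searchsorted(co, marker_cm)  # segment index per marker
                start = rng.integers(2)
                use_p1 = (seg + start) % 2 == 0
                allele = np.where(use_p1, founders[p1, lo : lo + m_per], founders[p2, lo : lo + m_per])
                genome[lo : lo + m_per] = 2 * allele
            if cfg.residual_het_rate > 0:
                het = rng.random(genome.size) < cfg.residual_het_rate
                genome[het] = 1
            taxa.append(line)
            ped_rows.append(
                {"line": line, "family": fam, "parent1": f"P{p1:03d}", "parent2": f"P{p2:03d}"}
            )
            dosage_rows.append(genome)

    sites = pd.DataFrame(
        {
            "chrom": np.repeat([f"chr{c + 1}" for c in range(cfg.n_chrom)], m_per),
            "pos": np.tile(pos_on_chrom, cfg.n_chrom),
            "id": [
                f"chr{c + 1}_{p}"
                for c in range(cfg.n_chrom)
                for p in pos_on_chrom
            ],
            "ref": "A",
            "alt": "B",
        }
    )
    g = DosageMatrix(
        taxa=taxa, sites=sites, dosage=np.vstack(dosage_rows), source_tag="synthetic-RIL"
    )
    return g, pd.DataFrame(ped_rows)


# ----------------------------------------------------------------------
# environments

# base seasonal level and amplitude per covariate family (arbitrary but
# plausible units; temperature in degC, radiation in MJ/m2/day, etc.)
_COV_BASE = {
    "T2M": (18.0, 8.0),
    "T2M_MAX": (24.0, 9.0),
    "T2M_MIN": (12.0, 8.0),
    "T2MDEW": (10.0, 7.0),
    "ALLSKY_SFC_LW_DWN": (330.0, 40.0),
    "ALLSKY_SFC_SW_DWN": (20.0, 8.0),
    "ALLSKY_SFC_SW_DNI": (22.0, 7.0),
    "ALLSKY_SFC_PAR_TOT": (9.0, 4.0),
    "ALLSKY_SFC_PAR_UVA": (1.1, 0.5),
    "ALLSKY_SFC_PAR_UVB": (0.03, 0.015),
    "PRECTOT": (3.0, 1.5),
    "WS2M": (3.5, 1.0),
    "RH2M": (70.0, 10.0),
    "EVPTRNS": (2.5, 1.5),
}


def simulate_env_covariates(cfg: SimConfig) -> tuple[list[EnvSpec], pd.DataFrame]:
    """Simulate trial locations and their daily weather cache.

    Each environment gets coordinates on a latitude gradient and a daily
    series per covariate: a shared seasonal sinusoid plus an env-specific
    offset (the signal the env kernel picks up) plus day-to-day noise.
    Returns the EnvSpec list and a long-format cache
    (env_id, date, covariate, value).
    """
    rng = np.random.default_rng(cfg.seed + 101)
    n_days = (cfg.window_end - cfg.window_start).days + 1
    days = [cfg.window_start + timedelta(days=i) for i in range(n_days)]
    doy = np.array([d.timetuple().tm_yday for d in days], dtype=float)
    season = np.sin((doy - 120) / 365.0 * 2 * np.pi)

    envs = []
    rows = []
    covs = list(dict.fromkeys(cfg.covariates))
    for i in range(cfg.n_envs):
        env_id = f"ENV{i + 1:02d}"
        lat = 44.0 + 4.0 * i / max(cfg.n_envs - 1, 1) + rng.normal(0, 0.1)
        lon = -96.0 + rng.normal(0, 1.0)
        envs.append(
            EnvSpec(
                env_id=env_id,
                latitude=lat,
                longitude=lon,
                window_start=cfg.window_start,
                window_end=cfg.window_end,
            )
        )
        for cov in covs:
            base, amp = _COV_BASE.get(cov, (1.0, 0.5))
            offset = rng.normal(0, 0.25 * abs(amp))
            daily = base + amp * season + offset + rng.normal(0, 0.1 * abs(amp), size=n_days)
            rows.append(
                pd.DataFrame(
                    {"env_id": env_id, "date": days, "covariate": cov, "value": daily}
                )
            )
    cache = pd.concat(rows, ignore_index=True)
    return envs, cache


# ----------------------------------------------------------------------
# phenotypes


def _effect_draws(rng, n_qtl: int, h2: tuple[float, ...], corr) -> np.ndarray:
    t = len(h2)
    if t == 1:
        return rng.standard_normal((n_qtl, 1))
    c = np.asarray(corr, float) if corr is not None else np.eye(t)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(t))
    return rng.standard_normal((n_qtl, t)) @ chol.T


def simulate_phenotypes(
    geno: DosageMatrix,
    envs,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-environment BLUE-like phenotype records with truth.

    The genetic architecture is additive: ``n_qtl`` markers carry effects
    drawn (multi-trait) with the target genetic correlation; the main
    genetic value is scaled to variance 1 per trait.  G x E enters as
    env-specific rescaling of the QTL effects, driven by the environment
    covariate profile when an :class:`EnvCovariateMatrix` is passed (iid
    per env otherwise), scaled so var(gxe)/var(g) equals
    ``cfg.gxe_variance_ratio``.  Environment main effects have unit
    variance; residual variance is solved per trait so that
    var(g + gxe) / var(y - env mean) hits the target h2.

    Parameters
    ----------
    geno
        Complete (no-missing) dosage matrix.
    envs
        EnvCovariateMatrix, list of EnvSpec, or list of env-id strings.
    cfg
        Simulation configuration (uses n_qtl, h2, trait_corr,
        gxe_variance_ratio, seed).

    Returns
    -------
    (records, truth) where records is a long DataFrame
    (strain, env, trait, value).
    """
    if geno.is_missing().any():
        raise ValueError("genotypes must be complete; impute first")
    if cfg.n_qtl > geno.n_sites:
        raise ValueError("n_qtl exceeds number of markers")
    rng = np.random.default_rng(cfg.seed + 202)

    if isinstance(envs, EnvCovariateMatrix):
        env_ids = list(envs.env_ids)
        env_profile = envs.values  # standardized env x covariate
    else:
        env_ids = [e.env_id if isinstance(e, EnvSpec) else str(e) for e in envs]
        env_profile = None
    n_env = len(env_ids)
    n_strain = geno.n_taxa
    traits = [f"trait{t + 1}" for t in range(cfg.n_traits)]

    qtl = rng.choice(geno.n_sites, size=cfg.n_qtl, replace=False)
    beta = _effect_draws(rng, cfg.n_qtl, cfg.h2, cfg.trait_corr)
    zq = geno.to_float()[:, qtl]
    zq = zq - zq.mean(axis=0)

    g_main = zq @ beta  # (n_strain, n_traits)
    g_sd = g_main.std(axis=0, ddof=0)
    g_sd[g_sd == 0] = 1.0
    g_main = g_main / g_sd  # var 1 per trait
    beta = beta / g_sd  # keep truth consistent
    if cfg.n_traits > 1 and cfg.trait_corr is not None:
        # re-impose the target correlation exactly on the realized TBVs
        # (finite QTL counts otherwise let the sample correlation drift)
        emp = np.corrcoef(g_main, rowvar=False)
        adj = np.linalg.cholesky(
            np.asarray(cfg.trait_corr) + 1e-10 * np.eye(cfg.n_traits)
        ) @ np.linalg.inv(np.linalg.cholesky(emp + 1e-10 * np.eye(cfg.n_traits)))
        g_main = g_main @ adj.T
        sd = g_main.std(axis=0, ddof=0)
        g_main = g_main / sd
        beta = beta @ adj.T / sd

    # env-specific QTL perturbations for GxE
    gxe = np.zeros((n_strain, n_env, cfg.n_traits))
    if cfg.gxe_variance_ratio > 0:
        if env_profile is not None:
            load = rng.standard_normal((cfg.n_qtl, env_profile.shape[1]))
            pert = load @ env_profile.T  # (n_qtl, n_env)
        else:
            pert = rng.standard_normal((cfg.n_qtl, n_env))
        for t in range(cfg.n_traits):
            dev = zq @ (pert * rng.standard_normal((cfg.n_qtl, 1)))  # (n_strain, n_env)
            dev = dev - dev.mean(axis=0)
            sd = dev.std(ddof=0)
            if sd > 0:
                dev = dev / sd * np.sqrt(cfg.gxe_variance_ratio)
            gxe[:, :, t] = dev

    env_eff = rng.standard_normal((n_env, cfg.n_traits))  # sigma2_E = 1

    records = []
    var_components = {}
    realized_h2 = {}
    tbv_rows = []
    y_all = np.empty((n_strain, n_env, cfg.n_traits))
    for t, trait in enumerate(traits):
        tbv = g_main[:, [t]] + gxe[:, :, t]  # (n_strain, n_env)
        var_tbv = float(tbv.var(ddof=0))
        h2 = cfg.h2[t]
        sigma2_e = var_tbv * (1 - h2) / h2
        eps = rng.normal(0, np.sqrt(sigma2_e), size=(n_strain, n_env))
        y_all[:, :, t] = 10.0 + env_eff[None, :, t] + tbv + eps
        var_components[trait] = {
            "sigma2_g": 1.0,
            "sigma2_gxe": float(gxe[:, :, t].var(ddof=0)),
            "sigma2_e": sigma2_e,
        }
        within = y_all[:, :, t] - y_all[:, :, t].mean(axis=0, keepdims=True)
        realized_h2[trait] = float(tbv.var(ddof=0) / within.var(ddof=0))
        for e, env in enumerate(env_ids):
            for s, strain in enumerate(geno.taxa):
                tbv_rows.append(
                    {"strain": strain, "env": env, "trait": trait, "tbv": tbv[s, e]}
                )

    for e, env in enumerate(env_ids):
        for s, strain in enumerate(geno.taxa):
            for t, trait in enumerate(traits):
                records.append(
                    {
                        "strain": strain,
                        "env": env,
                        "trait": trait,
                        "value": y_all[s, e, t],
                    }
                )
    pheno = pd.DataFrame(records)
    g_main_df = pd.DataFrame(
        [
            {"strain": strain, "trait": trait, "g": g_main[s, t]}
            for t, trait in enumerate(traits)
            for s, strain in enumerate(geno.taxa)
        ]
    )
    truth = SimTruth(
        qtl_sites=qtl,
        qtl_effects=beta,
        tbv=pd.DataFrame(tbv_rows),
        g_main=g_main_df,
        var_components=var_components,
        realized_h2=realized_h2,
    )
    return pheno, truth


def simulate_plot_data(
    strains: list[str],
    g_effects: np.ndarray,
    n_trials: int = 2,
    n_blocks: int = 2,
    sigma_trial: float = 1.0,
    sigma_block: float = 0.5,
    sigma_e: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot-level records from the fixed-effects trial model.

    ``y = mu + g_i + t_j + b_k(j) + eps`` with every strain appearing in
    every block of every trial (a balanced RCBD within each trial).  Used
    to exercise the BLUE-estimation stage against known line effects.
    """
    rng = np.random.default_rng(seed)
    t_eff = rng.normal(0, sigma_trial, n_trials)
    b_eff = rng.normal(0, sigma_block, (n_trials, n_blocks))
    rows = []
    for j in range(n_trials):
        for k in range(n_blocks):
            for i, s in enumerate(strains):
                rows.append(
                    {
                        "strain": s,
                        "trial": f"T{j + 1}",
                        "block": f"B{k + 1}",
                        "value": 10.0
                        + g_effects[i]
                        + t_eff[j]
                        + b_eff[j, k]
                        + rng.normal(0, sigma_e),
                    }
                )
    return pd.DataFrame(rows)


def mask_genotypes(
    g: DosageMatrix, fraction: float, seed: int
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Mask a random fraction of the called cells for imputation scoring.

    Exactly ``round(fraction * n_called_cells)`` cells are set MISSING,
    drawn uniformly among currently non-missing cells.  Returns the masked
    matrix and a truth table (taxon, site, row, col, true_dosage).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    called = np.flatnonzero(~g.is_missing().ravel())
    n_mask = int(round(fraction * called.size))
    chosen = rng.choice(called, size=n_mask, replace=False)
    rows, cols = np.unravel_index(chosen, g.shape)
    masked = g.copy()
    truth = pd.DataFrame(
        {
            "taxon": [g.taxa[r] for r in rows],
            "site": g.sites["id"].to_numpy()[cols],
            "row": rows,
            "col": cols,
            "true_dosage": masked.dosage[rows, cols],
        }
    )
    masked.dosage[rows, cols] = MISSING
    return masked, truth
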