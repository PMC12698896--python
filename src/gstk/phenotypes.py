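"""Phenotype tables: loading BLUEs, estimating them, merging with genotypes.

The pipeline is two-stage: genomic prediction consumes best linear
unbiased estimates (BLUEs) of strain effects, normally computed per
environment by the trial-analysis software of the breeding program
(avoiding double shrinkage downstream).  :func:`estimate_blues` is an
in-repo convenience implementing the standard per-location fixed-effects
model

    y_ijk = mu + g_i + t_j + b_k(j) (+ covariate) + eps_ijk

by ordinary least squares with treatment coding, where g is the breeding
line, t the trial, and b the block nested in trial.  Only line contrasts
matter downstream, so the intercept convention (reference = first line
level) is immaterial.

Phenotype records are held long-format: one row per
(strain, env, trait) with a real value or NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .core import DosageMatrix

__all__ = [
    "load_pheno",
    "pheno_summary",
    "estimate_blues",
    "merge_geno_pheno",
    "MergedDataset",
]

PHENO_COLUMNS = ["strain", "env", "trait", "value"]


def load_pheno(path_or_df, column_map: dict | None = None) -> pd.DataFrame:
    """Load a phenotype table into canonical long format.

    Accepts either long format (strain/env/trait/value columns, possibly
    under other names supplied in ``column_map``) or wide format, where
    ``column_map`` gives ``{"strain": ..., "env": ..., "traits": [...]}``
    and the trait columns are melted.

    Blank values are kept as NA records.  Duplicated (strain, env, trait)
    rows raise with the offending keys named.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    column_map = dict(column_map or {})
    rename = {
        column_map.get("strain", "strain"): "strain",
        column_map.get("env", "env"): "env",
    }
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise ValueError(
            f"columns {missing} not found; available columns: {list(df.columns)}"
        )
    df = df.rename(columns=rename)
    if "traits" in column_map:
        absent = [t for t in column_map["traits"] if t not in df.columns]
        if absent:
            raise ValueError(f"trait columns {absent} not found in {list(df.columns)}")
        df = df.melt(
            id_vars=[c for c in df.columns if c not in column_map["traits"]],
            value_vars=column_map["traits"],
            var_name="trait",
            value_name="value",
        )
    else:
        need = [c for c in ("trait", "value") if c not in df.columns]
        if need:
            raise ValueError(
                f"long-format table needs columns {need}; "
                "or pass column_map={'traits': [...]} for wide input"
            )
    df["strain"] = df["strain"].astype(str)
    df["env"] = df["env"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    dup = df.duplicated(subset=["strain", "env", "trait"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["strain", "env", "trait"]].drop_duplicates()
        raise ValueError(
            f"duplicated (strain, env, trait) records: {keys.to_dict('records')[:10]}"
        )
    return df.reset_index(drop=True)


def pheno_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-environment trait summaries (n, mean, sd, min, max)."""
    return (
        pheno.dropna(subset=["value"])
        .groupby(["trait", "env"])["value"]
        .agg(n="count", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )


def estimate_blues(
    plot_data: pd.DataFrame,
    covariate: str | None = None,
    env_label: str = "env",
    trait_name: str = "trait1",
) -> pd.DataFrame:
    """Per-strain BLUEs from plot-level data of a single location.

    Fits ``value ~ C(strain) + C(trial) + C(trial):C(block)`` (+ optional
    numeric covariate such as maturity date) by OLS with treatment
    coding; the returned BLUE of strain i is intercept + its treatment
    coefficient, i.e. anchored so the first strain level is the
    reference.  Only differences between strains are meaningful.

    Returns a long-format table (strain, env, trait, value).
    """
    need = {"strain", "trial", "block", "value"}
    if not need.issubset(plot_data.columns):
        raise ValueError(f"plot data needs columns {sorted(need)}")
    formula = "value ~ C(strain) + C(trial) + C(trial):C(block)"
    if covariate:
        formula += f" + {covariate}"
    model = smf.ols(formula, data=plot_data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient beyond the nesting constraints; "
            "strain, trial, and block-in-trial are confounded in this layout"
        )
    fit = model.fit()
    strains = sorted(plot_data["strain"].astype(str).unique())
    intercept = fit.params["Intercept"]
    blues = []
    for s in strains:
        key = f"C(strain)[T.{s}]"
        blues.append(intercept + (fit.params[key] if key in fit.params else 0.0))
    out = pd.DataFrame(
        {"strain": strains, "env": env_label, "trait": trait_name, "value": blues}
    )
    out.attrs["fit"] = fit
    return out


@dataclass
class MergedDataset:
    """Genotypes and phenotype records restricted to their intersection.

    Invariants: every strain in ``records`` has a row in ``geno``; no
    record has a missing focal-trait value.
    """

    geno: DosageMatrix
    records: pd.DataFrame  # strain, env, trait, value for focal trait(s)
    focal_traits: list[str]
    report: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def strains(self) -> list[str]:
        return list(self.geno.taxa)

    @property
    def envs(self) -> list[str]:
        return list(pd.unique(self.records["env"]))


def _normalize_ids(ids, enabled: bool):
    if not enabled:
        return list(ids)
    return [str(i).strip().casefold() for i in ids]


def merge_geno_pheno(
    g: DosageMatrix,
    pheno: pd.DataFrame,
    focal_trait: str | list[str],
    normalize_ids: bool = False,
) -> MergedDataset:
    """Intersect genotypes and phenotypes on strain ID.

    Records lacking a focal-trait value are dropped; strains present in
    only one of the two inputs are dropped; the report counts everything
    removed.  With ``normalize_ids`` strain identifiers are matched after
    trimming and case-folding (the normalization applied is recorded).
    """
    focal = [focal_trait] if isinstance(focal_trait, str) else list(focal_trait)
    ph = pheno[pheno["trait"].isin(focal)].copy()
    n_records_in = len(ph)
    ph = ph.dropna(subset=["value"])

    geno_keys = _normalize_ids(g.taxa, normalize_ids)
    pheno_raw = list(pd.unique(ph["strain"]))
    pheno_keys = _normalize_ids(pheno_raw, normalize_ids)
    key_to_geno_idx = {k: i for i, k in enumerate(geno_keys)}
    shared_keys = [k for k in dict.fromkeys(pheno_keys) if k in key_to_geno_idx]
    if not shared_keys:
        raise ValueError(
            "no shared strain identifiers between genotypes and phenotypes; "
            "check naming conventions (try normalize_ids=True)"
        )
    pheno_key_of = dict(zip(pheno_raw, pheno_keys))
    ph["_key"] = ph["strain"].map(pheno_key_of)
    ph = ph[ph["_key"].isin(set(shared_keys))].copy()
    # map phenotype strain names onto genotype taxa names
    canonical = {k: g.taxa[key_to_geno_idx[k]] for k in shared_keys}
    ph["strain"] = ph["_key"].map(canonical)
    ph = ph.drop(columns="_key").reset_index(drop=True)

    keep_idx = sorted(key_to_geno_idx[k] for k in shared_keys)
    geno_sub = g.take_taxa(keep_idx)
    report = {
        "n_geno_strains_in": g.n_taxa,
        "n_pheno_strains_in": len(pheno_raw),
        "n_shared_strains": len(shared_keys),
        "n_records_in": n_records_in,
        "n_records_kept": len(ph),
        "n_records_dropped": n_records_in - len(ph),
        "normalize_ids": normalize_ids,
    }
    return MergedDataset(geno=geno_sub, records=ph, focal_traits=focal, report=report)
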