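"""Cross-validation schemes for multi-environment genomic prediction.

The schemes cross tested/untested strains with tested/untested
environments:

=======  ==============================================================
kfold    random partition of records
CV2      random partition of records, stratified by environment
         (tested strains in tested environments)
CV1      random partition of strains; a fold masks every record of its
         strains (untested strains, tested environments)
CV0      one fold per environment (tested strains, untested envs)
CV00     environment folds crossed with strain folds; evaluation is
         restricted to masked-strain x masked-env cells
LOFO     one fold per level of a user-chosen factor column (leave-one-
         trial-out when the factor is the trial)
=======  ==============================================================

Predictive ability (PA) is the Pearson correlation of observed vs
predicted values on the masked records, computed within each left-out
unit: the fold for kfold/CV1, the environment within fold for CV2, the
left-out level for CV0/LOFO, and the masked cell-set for CV00.  Folds
with fewer than 3 evaluable records are flagged and excluded from the
mean/SE summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_kernel import GibbsConfig, fit_me_model
from .enviromics import EnvKernel
from .kernels import GenomicKernel, MEModelSpec, genomic_kernel
from .phenotypes import MergedDataset
from .single_trait import fit_gblup_reml

__all__ = [
    "CVPlan",
    "CVResult",
    "make_partitions",
    "run_cv",
    "compare_models",
    "gblup_fitter",
    "me_model_fitter",
]

SCHEMES = ("kfold", "CV1", "CV2", "CV0", "CV00", "LOFO")


@dataclass
class Fold:
    """One CV fold: training records, evaluation records, PA unit labels."""

    test: np.ndarray  # record indices to predict and score
    train: np.ndarray  # record indices available for fitting
    label: str = ""
    flagged: bool = False  # fewer than 3 evaluable records


@dataclass
class CVPlan:
    scheme: str
    k: int | None
    factor: str | None
    seed: int
    folds: list[Fold]

    def masked_sets(self) -> list[frozenset]:
        return [frozenset(f.test.tolist()) for f in self.folds]


@dataclass
class CVResult:
    """Per-unit predictive abilities and their summary."""

    unit_pa: pd.DataFrame  # columns: fold, unit, n, pa
    failures: list = field(default_factory=list)

    @property
    def pa_values(self) -> np.ndarray:
        return self.unit_pa["pa"].dropna().to_numpy()

    @property
    def mean_pa(self) -> float:
        v = self.pa_values
        return float(np.mean(v)) if v.size else np.nan

    @property
    def se_pa(self) -> float:
        v = self.pa_values
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if v.size > 1 else 0.0

    @property
    def min_pa(self) -> float:
        v = self.pa_values
        return float(np.min(v)) if v.size else np.nan

    @property
    def max_pa(self) -> float:
        v = self.pa_values
        return float(np.max(v)) if v.size else np.nan

    def summary(self) -> dict:
        return {
            "mean_pa": self.mean_pa,
            "se_pa": self.se_pa,
            "min_pa": self.min_pa,
            "max_pa": self.max_pa,
            "n_units": int(self.unit_pa["pa"].notna().sum()),
        }


def _chunk(idx: np.ndarray, k: int) -> list[np.ndarray]:
    return [np.array(c, dtype=int) for c in np.array_split(idx, k)]


def make_partitions(
    dataset: MergedDataset,
    scheme: str,
    k: int = 5,
    factor: str | None = None,
    seed: int = 0,
) -> CVPlan:
    """Build a masking plan for the requested scheme (seeded, disjoint folds)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rec = dataset.records.reset_index(drop=True)
    n = len(rec)
    all_idx = np.arange(n)
    rng = np.random.default_rng(seed)
    folds: list[Fold] = []

    if scheme in ("kfold", "CV2"):
        if k < 2:
            raise ValueError("k must be >= 2")
        if scheme == "kfold":
            parts = _chunk(rng.permutation(n), k)
        else:  # stratified by environment
            parts = [[] for _ in range(k)]
            for env in pd.unique(rec["env"]):
                env_idx = rng.permutation(np.flatnonzero(rec["env"] == env))
                for j, c in enumerate(_chunk(env_idx, k)):
                    parts[j].extend(c.tolist())
            parts = [np.array(sorted(p), dtype=int) for p in parts]
        for j, test in enumerate(parts):
            folds.append(
                Fold(
                    test=np.asarray(test, int),
                    train=np.setdiff1d(all_idx, test),
                    label=f"fold{j + 1}",
                )
            )
    elif scheme == "CV1":
        if k < 2:
            raise ValueError("k must be >= 2")
        strains = np.array(sorted(set(rec["strain"])))
        parts = _chunk(rng.permutation(len(strains)), k)
        for j, sp in enumerate(parts):
            masked = set(strains[sp])
            test = np.flatnonzero(rec["strain"].isin(masked))
            folds.append(
                Fold(test=test, train=np.setdiff1d(all_idx, test), label=f"fold{j + 1}")
            )
    elif scheme == "CV0":
        for env in pd.unique(rec["env"]):
            test = np.flatnonzero(rec["env"] == env)
            folds.append(
                Fold(test=test, train=np.setdiff1d(all_idx, test), label=str(env))
            )
    elif scheme == "CV00":
        if k < 2:
            raise ValueError("k must be >= 2")
        strains = np.array(sorted(set(rec["strain"])))
        sparts = _chunk(rng.permutation(len(strains)), k)
        for env in pd.unique(rec["env"]):
            env_mask = (rec["env"] == env).to_numpy()
            for j, sp in enumerate(sparts):
                masked = set(strains[sp])
                strain_mask = rec["strain"].isin(masked).to_numpy()
                test = np.flatnonzero(env_mask & strain_mask)
                train = np.flatnonzero(~env_mask & ~strain_mask)
                folds.append(Fold(test=test, train=train, label=f"{env}xS{j + 1}"))
    elif scheme == "LOFO":
        if factor is None or factor not in rec.columns:
            raise ValueError(
                f"LOFO needs an existing factor column; got {factor!r} "
                f"(columns: {list(rec.columns)})"
            )
        for lev in pd.unique(rec[factor]):
            test = np.flatnonzero(rec[factor] == lev)
            folds.append(
                Fold(test=test, train=np.setdiff1d(all_idx, test), label=str(lev))
            )
    for f in folds:
        f.flagged = len(f.test) < 3
    return CVPlan(scheme=scheme, k=k, factor=factor, seed=seed, folds=folds)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(dataset: MergedDataset, fitter, plan: CVPlan) -> CVResult:
    """Refit per fold, predict masked records, summarize PA per unit.

    ``fitter(dataset, train_idx, test_idx) -> predictions`` must return
    predictions aligned with ``test_idx``.  Model refusals (e.g. an
    unseen environment without an enviromic term) are recorded per fold
    and do not abort the run.
    """
    rec = dataset.records.reset_index(drop=True)
    y = rec["value"].to_numpy(float)
    rows = []
    failures = []
    for f in plan.folds:
        if f.flagged:
            rows.append({"fold": f.label, "unit": f.label, "n": len(f.test), "pa": np.nan})
            continue
        try:
            pred = np.asarray(fitter(dataset, f.train, f.test), float)
        except ValueError as exc:
            failures.append({"fold": f.label, "error": str(exc)})
            rows.append({"fold": f.label, "unit": f.label, "n": len(f.test), "pa": np.nan})
            continue
        if plan.scheme == "CV2":
            envs = rec["env"].to_numpy()[f.test]
            for env in pd.unique(envs):
                sel = envs == env
                rows.append(
                    {
                        "fold": f.label,
                        "unit": f"{f.label}:{env}",
                        "n": int(sel.sum()),
                        "pa": _pearson(y[f.test][sel], pred[sel]),
                    }
                )
        else:
            rows.append(
                {
                    "fold": f.label,
                    "unit": f.label,
                    "n": len(f.test),
                    "pa": _pearson(y[f.test], pred),
                }
            )
    return CVResult(unit_pa=pd.DataFrame(rows), failures=failures)


# ----------------------------------------------------------------------
# fitter factories


def gblup_fitter(k: GenomicKernel, lambda_fixed: float | None = None):
    """Single-trait G-BLUP fit-predict adapter (REML per fold).

    The fixed design is intercept + environment (treatment coding over
    training envs; unseen envs fall back to the mean env effect).
    """

    def fit_predict(dataset: MergedDataset, train_idx, test_idx):
        from .bayes_kernel import _env_fixed_design_with_fallback

        rec = dataset.records.reset_index(drop=True)
        y = rec["value"].to_numpy(float)
        mask = np.zeros(len(rec), bool)
        mask[train_idx] = True
        x_all, _, _ = _env_fixed_design_with_fallback(rec["env"], mask)
        tidx = {t: i for i, t in enumerate(k.taxa)}
        z = np.zeros((len(train_idx), len(k.taxa)))
        for row, i in enumerate(train_idx):
            z[row, tidx[rec["strain"].iloc[i]]] = 1.0
        fit = fit_gblup_reml(
            y[train_idx], x_all[train_idx], k, z, lambda_fixed=lambda_fixed
        )
        u = pd.Series(fit.blup, index=fit.strains)
        preds = x_all[test_idx] @ fit.beta + u.loc[
            rec["strain"].iloc[test_idx]
        ].to_numpy()
        return preds

    return fit_predict


def me_model_fitter(
    spec: MEModelSpec,
    k_g: GenomicKernel,
    omega: EnvKernel | None,
    cfg: GibbsConfig,
    allow_unseen_env: bool = True,
):
    """Bayesian multi-environment model fit-predict adapter."""

    def fit_predict(dataset: MergedDataset, train_idx, test_idx):
        mask = np.zeros(len(dataset.records), bool)
        mask[train_idx] = True
        post = fit_me_model(
            dataset,
            spec,
            k_g,
            omega,
            cfg,
            train_mask=mask,
            allow_unseen_env=allow_unseen_env,
        )
        return post.predictions[test_idx]

    return fit_predict


def compare_models(
    dataset: MergedDataset,
    model_grid: list[tuple[str, str]],
    omega: EnvKernel | None,
    plan: CVPlan,
    cfg: GibbsConfig,
    allow_unseen_env: bool = True,
) -> pd.DataFrame:
    """Run the same CV plan over a grid of (model tag, genomic kernel kind).

    All models share the identical plan, so partition noise cancels in
    paired comparisons.  Returns one row per grid entry with mean PA, SE
    of the mean, and the min/max across units.
    """
    kernels = {}
    rows = []
    for tag, kind in model_grid:
        if kind not in kernels:
            kernels[kind] = genomic_kernel(dataset.geno, kind=kind)
        spec = MEModelSpec(tag, genomic_kind=kind)
        fitter = me_model_fitter(
            spec, kernels[kind], omega, cfg, allow_unseen_env=allow_unseen_env
        )
        res = run_cv(dataset, fitter, plan)
        rows.append(
            {
                "model": spec.tag,
                "genomic_kernel": kind,
                **res.summary(),
            }
        )
    return pd.DataFrame(rows)
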