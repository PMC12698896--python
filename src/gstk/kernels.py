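"""Genomic kinship and multi-environment covariance structure assembly.

The genomic kernel is either the VanRaden linear kinship
``K = Z Z' / (2 sum p_j (1-p_j))`` (Z = dosages centered by twice the
allele frequency) or a Gaussian kernel on marker-scaled Euclidean
distances with median-heuristic bandwidth.

Reaction-norm multi-environment models are assembled as lists of
record-level covariance terms over the n phenotype records (strain-env
cells).  With Z_g, Z_e the record->strain and record->env incidence
matrices, the available random terms are:

========  ==========================================================
G-main    Z_g K_G Z_g'
GxE       (Z_g K_G Z_g') o (Z_e Z_e')           common-variance G x E
GxE_i     G-main masked to records of env i      one term per env
W         Z_e Omega Z_e'                         enviromic main effect
GxW       (Z_g K_G Z_g') o (Z_e Omega Z_e')
GxW_i     GxW masked to records of env i
========  ==========================================================

(o = Hadamard product.)  The environment grouping E always enters as a
fixed factor (intercept + treatment coding), never as a random term.
The nine supported model formulae combine these as in the tags listed in
:data:`MODEL_TAGS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DosageMatrix
from .enviromics import EnvKernel
from .phenotypes import MergedDataset

__all__ = [
    "GenomicKernel",
    "KernelTerm",
    "MEModelSpec",
    "MODEL_TAGS",
    "genomic_kernel",
    "build_model_kernels",
    "min_eigenvalue",
]

#: The nine supported multi-environment model formulae.
MODEL_TAGS = (
    "G+E",
    "G+E+GxE",
    "G+E+GxE_i",
    "G+E+W",
    "G+E+GxE+W",
    "G+E+GxE_i+W",
    "G+E+W+GxW",
    "G+E+GxE+W+GxW",
    "G+E+GxE_i+W+GxW_i",
)


@dataclass
class GenomicKernel:
    """Symmetric PSD genomic relationship matrix over taxa."""

    taxa: list[str]
    matrix: np.ndarray
    kind: str
    scaling: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}


@dataclass
class KernelTerm:
    """A labeled record-level covariance matrix with its model role."""

    label: str
    matrix: np.ndarray
    role: str  # G-main | GxE-common | GxE-env_i | W-env | GxW-common | GxW-env_i


def normalize_tag(tag: str) -> str:
    """Canonicalize a model formula tag (unicode x, spacing, case of 'x')."""
    t = tag.replace(" ", "").replace("×", "x").replace("X", "x")
    t = t.replace("xE", "xE").replace("xW", "xW")
    for known in MODEL_TAGS:
        if t.lower() == known.lower():
            return known
    raise ValueError(f"unknown model tag {tag!r}; legal tags: {', '.join(MODEL_TAGS)}")


@dataclass
class MEModelSpec:
    """A multi-environment model formula plus kernel choices."""

    tag: str
    genomic_kind: str = "linear"

    def __post_init__(self) -> None:
        self.tag = normalize_tag(self.tag)

    @property
    def wants_w(self) -> bool:
        return "W" in self.tag.split("+")or "GxW" in self.tag or "GxW_i" in self.tag

    @property
    def parts(self) -> list[str]:
        return self.tag.split("+")


def min_eigenvalue(m: np.ndarray) -> float:
    return float(np.linalg.eigvalsh((m + m.T) / 2.0).min())


def genomic_kernel(
    g: DosageMatrix, kind: str = "linear", theta: float = 1.0
) -> GenomicKernel:
    """Genomic relationship matrix from a complete dosage matrix.

    linear
        VanRaden kinship: columns centered by 2 p_hat_j, then
        ``K = Z Z' / (2 sum p_hat_j (1 - p_hat_j))``.
    gaussian
        ``K_ij = exp(-theta d2_ij / q)`` with ``d2`` the squared
        Euclidean distance over dosages divided by the marker count and
        ``q`` the median off-diagonal ``d2``.
    """
    if g.is_missing().any():
        raise ValueError("kernel requires a complete matrix; impute first")
    if theta <= 0:
        raise ValueError("theta must be positive")
    x = g.dosage.astype(float)
    p = x.mean(axis=0) / 2.0
    if kind == "linear":
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise ValueError("all markers monomorphic: VanRaden denominator is zero")
        z = x - 2.0 * p
        k = z @ z.T / denom
        scaling = {"denominator": denom}
    elif kind == "gaussian":
        sq = np.sum(x**2, axis=1)
        d2 = (sq[:, None] + sq[None, :] - 2.0 * x @ x.T) / g.n_sites
        d2 = np.maximum(d2, 0.0)
        off = d2[~np.eye(len(x), dtype=bool)]
        q = float(np.median(off)) if off.size and off.max() > 0 else 1.0
        k = np.exp(-theta * d2 / q)
        scaling = {"theta": theta, "median_d2": q}
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    k = (k + k.T) / 2.0
    return GenomicKernel(taxa=list(g.taxa), matrix=k, kind=kind, scaling=scaling)


def incidence(labels: pd.Series, levels: list[str]) -> np.ndarray:
    """Record x level 0/1 incidence matrix."""
    idx = {l: j for j, l in enumerate(levels)}
    z = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        z[i, idx[lab]] = 1.0
    return z


def env_fixed_design(
    env_labels: pd.Series, env_levels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded (drop-first) environment design."""
    levels = env_levels if env_levels is not None else list(pd.unique(env_labels))
    x = np.ones((len(env_labels), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = (env_labels == lev).astype(float)
    names = ["intercept"] + [f"env[{lev}]" for lev in levels[1:]]
    return x, names


def build_model_kernels(
    spec: MEModelSpec,
    dataset: MergedDataset,
    k_g: GenomicKernel,
    omega: EnvKernel | None = None,
) -> tuple[list[KernelTerm], np.ndarray, list[str]]:
    """Assemble the random covariance terms and fixed design for a formula.

    Returns ``(terms, X_fixed, fixed_names)`` over the dataset's records.
    Environment-specific deviation terms are implemented by masking
    (zeroing rows/columns outside env i) so every term shares the record
    dimension; masking a PSD matrix to a principal block keeps it PSD.
    """
    rec = dataset.records
    strains = [t for t in k_g.taxa]
    missing = set(rec["strain"]) - set(strains)
    if missing:
        raise ValueError(f"records reference strains absent from the kernel: {sorted(missing)[:5]}")
    envs = list(pd.unique(rec["env"]))
    if spec.wants_w:
        if omega is None:
            raise ValueError(f"model {spec.tag} includes W terms but no env kernel was given")
        missing_env = set(envs) - set(omega.env_ids)
        if missing_env:
            raise ValueError(f"envs absent from env kernel: {sorted(missing_env)}")

    z_g = incidence(rec["strain"], strains)
    z_e = incidence(rec["env"], envs)
    g_rec = z_g @ k_g.matrix @ z_g.T

    terms: list[KernelTerm] = [KernelTerm("G", g_rec, "G-main")]
    parts = spec.parts
    env_blocks = z_e @ z_e.T

    if "GxE" in parts:
        terms.append(KernelTerm("GxE", g_rec * env_blocks, "GxE-common"))
    if "GxE_i" in parts:
        for env in envs:
            mask = (rec["env"] == env).to_numpy(float)
            terms.append(
                KernelTerm(f"GxE[{env}]", g_rec * np.outer(mask, mask), "GxE-env_i")
            )
    if "W" in parts:
        w_rec = z_e @ omega.to_frame().loc[envs, envs].to_numpy() @ z_e.T
        terms.append(KernelTerm("W", w_rec, "W-env"))
    if "GxW" in parts or "GxW_i" in parts:
        w_rec = z_e @ omega.to_frame().loc[envs, envs].to_numpy() @ z_e.T
        gxw = g_rec * w_rec
        if "GxW" in parts:
            terms.append(KernelTerm("GxW", gxw, "GxW-common"))
        if "GxW_i" in parts:
            for env in envs:
                mask = (rec["env"] == env).to_numpy(float)
                terms.append(
                    KernelTerm(f"GxW[{env}]", gxw * np.outer(mask, mask), "GxW-env_i")
                )

    x_fixed, names = env_fixed_design(rec["env"], envs)
    return terms, x_fixed, names
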