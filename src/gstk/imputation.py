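"""Population-based nearest-neighbor genotype imputation.

Two imputers operate on scattered missing scores:

* **LD-KNNi** — for each missing cell, sites in highest linkage
  disequilibrium (r^2 on dosages, optionally restricted to a genomic
  window) with the target site define a local fingerprint; the k taxa
  nearest in IBS distance over that fingerprint vote with
  inverse-distance weights.
* **numeric KNN** — taxa distances are Euclidean over mutually called
  sites (scaled by the number of compared sites); the missing cell takes
  the mean of the k nearest called neighbors.

A third route lifts a low-density (LD) target panel onto a high-density
(HD) reference panel by merging the two matrices on shared marker IDs and
running LD-KNNi over the merged matrix, so HD-only sites of the target
taxa are filled from their nearest reference relatives.  This preserves
the LD-to-HD pipeline stage functionally without haplotype phasing.

All imputers are total (a site-mean fallback guarantees zero missing
cells in the output), never alter an observed cell, and are deterministic
for a given input (neighbor ties break toward the lowest taxon index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, DosageMatrix

__all__ = [
    "LDKnniParams",
    "NumericKnnParams",
    "impute_ldknni",
    "impute_numeric_knn",
    "impute_ld_to_hd",
]

EPS = 1e-9  # added to distances before inverse weighting


@dataclass
class LDKnniParams:
    l_sites: int = 30
    k_neighbors: int = 5
    max_dist_bp: int = 10_000_000  # 0 = unbounded

    def __post_init__(self) -> None:
        if self.l_sites < 1 or self.k_neighbors < 1:
            raise ValueError("l_sites and k_neighbors must be >= 1")


@dataclass
class NumericKnnParams:
    k_neighbors: int = 5
    distance: str = "euclidean"
    use_mean: bool = True  # False: inverse-distance-weighted mean

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.distance != "euclidean":
            raise ValueError("only 'euclidean' distance is supported")


def _round_dosage(v: float) -> int:
    return int(min(2, max(0, np.floor(v + 0.5))))


def _site_mean_fill(x: np.ndarray, col: int) -> float:
    m = np.nanmean(x[:, col])
    if np.isnan(m):
        m = np.nanmean(x)
    return 0.0 if np.isnan(m) else float(m)


def _pairwise_r2_with_site(x: np.ndarray, s: int, cand: np.ndarray) -> np.ndarray:
    """r^2 between column s and candidate columns, pairwise-complete."""
    a = x[:, s]
    A = x[:, cand]
    m_a = ~np.isnan(a)
    M = ~np.isnan(A) & m_a[:, None]
    a0 = np.nan_to_num(a)
    A0 = np.nan_to_num(A)
    n = M.sum(axis=0).astype(float)
    sa = (a0[:, None] * M).sum(axis=0)
    sA = (A0 * M).sum(axis=0)
    saa = ((a0**2)[:, None] * M).sum(axis=0)
    sAA = (A0**2 * M).sum(axis=0)
    saA = (a0[:, None] * A0 * M).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * saA - sa * sA
        den = (n * saa - sa**2) * (n * sAA - sA**2)
        r2 = np.where((n >= 2) & (den > 0), num**2 / np.maximum(den, 1e-300), 0.0)
    return r2


def impute_ldknni(
    g: DosageMatrix, p: LDKnniParams = LDKnniParams(), seed: int = 0
) -> DosageMatrix:
    """LD k-nearest-neighbor imputation of scattered missing dosages.

    For each site with missing calls: rank other sites by squared Pearson
    correlation with the target site (within ``max_dist_bp`` on the same
    chromosome when bounded), take the top ``l_sites``, and for every
    missing taxon compute its IBS distance (het-vs-hom counts as half a
    match) to every called taxon over that site set.  The imputed dosage
    is the 1/(d+eps)-weighted mean of the ``k_neighbors`` nearest donors,
    rounded to {0,1,2}.  Cells with no usable donor fall back to the
    rounded site mean; the fallback count is recorded in
    ``out.imputation_report``.

    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity only.
    """
    if g.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if g.n_sites < p.l_sites + 1:
        raise ValueError("need at least l_sites+1 sites")
    x = g.to_float()
    out = g.copy()
    chrom = g.sites["chrom"].to_numpy()
    pos = g.sites["pos"].to_numpy()
    n_imputed = 0
    n_fallback = 0
    miss_mask = g.is_missing()
    for s in np.flatnonzero(miss_mask.any(axis=0)):
        if p.max_dist_bp > 0:
            cand = np.flatnonzero(
                (chrom == chrom[s]) & (np.abs(pos - pos[s]) <= p.max_dist_bp)
            )
            cand = cand[cand != s]
        else:
            cand = np.delete(np.arange(g.n_sites), s)
        if cand.size == 0:
            cand = np.delete(np.arange(g.n_sites), s)
        r2 = _pairwise_r2_with_site(x, s, cand)
        order = np.lexsort((cand, -r2))  # best r2 first, lowest index on ties
        ranked = cand[order]
        called = ~np.isnan(x[:, s])
        for t in np.flatnonzero(miss_mask[:, s]):
            # fingerprint: top-LD sites at which the target taxon is called
            t_called = ~np.isnan(x[t, ranked])
            sel = ranked[t_called][: p.l_sites]
            n_imputed += 1
            if sel.size == 0:
                out.dosage[t, s] = _round_dosage(_site_mean_fill(x, s))
                n_fallback += 1
                continue
            # IBS distance to every donor over the fingerprint
            diff = np.abs(x[t, sel][None, :] - x[:, sel]) / 2.0
            shared = (~np.isnan(diff)).sum(axis=1)
            with np.errstate(invalid="ignore"):
                d = np.where(
                    shared > 0,
                    np.nansum(np.nan_to_num(diff), axis=1) / np.maximum(shared, 1),
                    np.inf,
                )
            d[~called] = np.inf
            d[t] = np.inf
            donors = np.flatnonzero(np.isfinite(d))
            if donors.size == 0:
                out.dosage[t, s] = _round_dosage(_site_mean_fill(x, s))
                n_fallback += 1
                continue
            order_d = np.lexsort((donors, d[donors]))
            near = donors[order_d[: p.k_neighbors]]
            w = 1.0 / (d[near] + EPS)
            val = float(np.sum(w * x[near, s]) / np.sum(w))
            out.dosage[t, s] = _round_dosage(val)
    out.imputation_report = {
        "method": "ldknni",
        "cells_imputed": n_imputed,
        "fallback_count": n_fallback,
        "l_sites": p.l_sites,
        "k_neighbors": p.k_neighbors,
        "max_dist_bp": p.max_dist_bp,
    }
    return out


def impute_numeric_knn(
    g: DosageMatrix, p: NumericKnnParams = NumericKnnParams()
) -> DosageMatrix:
    """Numeric KNN imputation with taxa-wise Euclidean distances.

    Distances are computed over mutually called sites and scaled by the
    count of compared sites, so taxa pairs with different amounts of
    overlap are comparable.  The imputed value is the mean dosage of the
    ``k_neighbors`` nearest called donors (inverse-distance weighted when
    ``use_mean`` is False), rounded into {0,1,2} for storage; the
    real-valued imputations are kept in ``out.imputation_report["values"]``.
    """
    if g.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    x = g.to_float()
    M = (~np.isnan(x)).astype(float)
    X0 = np.nan_to_num(x)
    S = X0 @ X0.T
    Q = (X0**2) @ M.T
    n_shared = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (Q + Q.T - 2 * S) / np.maximum(n_shared, 1)
    d = np.sqrt(np.maximum(d2, 0.0))
    d[n_shared == 0] = np.inf
    np.fill_diagonal(d, np.inf)

    out = g.copy()
    n_imputed = 0
    n_fallback = 0
    real_values = []
    miss_mask = g.is_missing()
    for s in np.flatnonzero(miss_mask.any(axis=0)):
        called = ~np.isnan(x[:, s])
        for t in np.flatnonzero(miss_mask[:, s]):
            dt = d[t].copy()
            dt[~called] = np.inf
            donors = np.flatnonzero(np.isfinite(dt))
            n_imputed += 1
            if donors.size == 0:
                val = _site_mean_fill(x, s)
                n_fallback += 1
            else:
                order = np.lexsort((donors, dt[donors]))
                near = donors[order[: p.k_neighbors]]
                if p.use_mean:
                    val = float(np.mean(x[near, s]))
                else:
                    w = 1.0 / (dt[near] + EPS)
                    val = float(np.sum(w * x[near, s]) / np.sum(w))
            real_values.append((t, s, val))
            out.dosage[t, s] = _round_dosage(val)
    out.imputation_report = {
        "method": "numeric_knn",
        "cells_imputed": n_imputed,
        "fallback_count": n_fallback,
        "k_neighbors": p.k_neighbors,
        "values": real_values,
    }
    return out


def impute_ld_to_hd(
    hd_ref: DosageMatrix,
    ld_target: DosageMatrix,
    p: LDKnniParams = LDKnniParams(),
    seed: int = 0,
    min_intersection: float = 0.5,
) -> DosageMatrix:
    """Lift an LD target panel onto the HD reference marker set.

    The target matrix is merged with the reference over the HD site set
    (matching by marker ID; sites whose ref/alt alleles are swapped
    between panels have their target dosages flipped 2<->0), target taxa
    get MISSING at HD-only sites, and LD-KNNi runs over the merged
    matrix.  Reference taxa are returned unchanged.

    Raises
    ------
    ValueError
        If fewer than ``min_intersection`` of the LD sites match an HD
        marker ID (likely a marker-naming mismatch between platforms).
    """
    hd_ids = {sid: j for j, sid in enumerate(hd_ref.sites["id"])}
    shared = [
        (i, hd_ids[sid]) for i, sid in enumerate(ld_target.sites["id"]) if sid in hd_ids
    ]
    if len(shared) == 0:
        raise ValueError("no shared marker IDs between HD reference and LD target")
    if len(shared) < min_intersection * ld_target.n_sites:
        raise ValueError(
            f"only {len(shared)}/{ld_target.n_sites} LD sites match HD marker IDs; "
            "reconcile marker names between panels before imputing"
        )
    overlap = set(hd_ref.taxa) & set(ld_target.taxa)
    if overlap:
        raise ValueError(f"taxa present in both panels: {sorted(overlap)[:5]} ...")

    n_hd = hd_ref.n_sites
    merged_dosage = np.full(
        (hd_ref.n_taxa + ld_target.n_taxa, n_hd), MISSING, dtype=np.int8
    )
    merged_dosage[: hd_ref.n_taxa, :] = hd_ref.dosage
    for ld_j, hd_j in shared:
        col = ld_target.dosage[:, ld_j].copy()
        ld_site = ld_target.sites.iloc[ld_j]
        hd_site = hd_ref.sites.iloc[hd_j]
        if (ld_site["ref"], ld_site["alt"]) == (hd_site["alt"], hd_site["ref"]):
            flip = col != MISSING
            col[flip] = 2 - col[flip]
        elif (ld_site["ref"], ld_site["alt"]) != (hd_site["ref"], hd_site["alt"]):
            # allele mismatch that is not a clean swap: treat as missing
            col[:] = MISSING
        merged_dosage[hd_ref.n_taxa :, hd_j] = col

    merged = DosageMatrix(
        taxa=list(hd_ref.taxa) + list(ld_target.taxa),
        sites=hd_ref.sites.copy(),
        dosage=merged_dosage,
        source_tag=f"merged:{hd_ref.source_tag}+{ld_target.source_tag}",
    )
    imputed = impute_ldknni(merged, p, seed=seed)
    # reference taxa pass through untouched
    imputed.dosage[: hd_ref.n_taxa, :] = hd_ref.dosage
    imputed.imputation_report["n_shared_sites"] = len(shared)
    return imputed
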