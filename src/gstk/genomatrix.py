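"""VCF loading, site/taxa quality filters, and a PC-based integrity check.

Genotypes are read from VCF into a :class:`~gstk.core.DosageMatrix`
(ALT-allele counts 0/1/2, missing or half-missing calls mapped to the
``MISSING`` sentinel).  Filtering follows the usual QC order for breeding
panels: sites on missingness + minor-allele frequency, then taxa on
missingness.  The PC check compares taxa scores between two genotype
matrices of the same material (e.g. an assay panel before and after
imputation) to confirm that processing preserved relative genetic
distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, DosageMatrix, minor_allele_frequencies

__all__ = [
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "filter_taxa",
    "pc_integrity_check",
]


@dataclass
class FilterReport:
    """Before/after counts plus the thresholds that produced them."""

    n_sites_in: int
    n_sites_out: int
    n_taxa_in: int
    n_taxa_out: int
    maf_min: float | None = None
    site_missing_max: float | None = None
    taxon_missing_max: float | None = None

    def __post_init__(self) -> None:
        assert self.n_sites_out <= self.n_sites_in
        assert self.n_taxa_out <= self.n_taxa_in

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class VcfParseError(ValueError):
    pass


class EmptyDataError(ValueError):
    pass


def read_vcf(path, biallelic_only: bool = True, source_tag: str = "") -> DosageMatrix:
    """Load a VCF with GT fields into a dosage matrix.

    Dosage is the count of ALT alleles per call; a call with any missing
    allele ("./.", "./1") becomes ``MISSING``.  Phased and unphased
    genotypes are treated identically.  Multiallelic records are skipped
    when ``biallelic_only`` (the default) and rejected otherwise.

    Raises
    ------
    VcfParseError
        On malformed records (message names the offending site).
    EmptyDataError
        If no site survives the biallelic filter.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    taxa = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        if len(var.ALT) != 1 or var.is_indel:
            if biallelic_only:
                continue
            raise VcfParseError(
                f"non-biallelic-SNP record at {var.CHROM}:{var.POS} "
                "(rerun with biallelic_only=True to skip)"
            )
        # genotypes: list of [a0, a1, phased]; -1 encodes a missing allele
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int16)
        dose = gt.sum(axis=1).astype(np.int8)
        dose[(gt < 0).any(axis=1)] = MISSING
        cols.append(dose)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if not rows:
        raise EmptyDataError(f"no biallelic SNP records in {path}")
    sites = pd.DataFrame(rows)
    dosage = np.column_stack(cols)
    return DosageMatrix(taxa=taxa, sites=sites, dosage=dosage, source_tag=source_tag)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: DosageMatrix, path) -> None:
    """Write a dosage matrix as an unphased biallelic-SNP VCF.

    Heterozygous dosages are written as ``0/1``; phase information is not
    represented (the pipeline is dosage-based).
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.taxa)
            + "\n"
        )
        for j, site in g.sites.iterrows():
            calls = "\t".join(_GT_CODE[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{site['id']}\t"
                f"{site['ref']}\t{site['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def filter_sites(
    g: DosageMatrix, maf_min: float = 0.05, site_missing_max: float = 0.2
) -> tuple[DosageMatrix, FilterReport]:
    """Retain sites with missing fraction <= ``site_missing_max`` and
    minor-allele frequency >= ``maf_min`` (MAF over non-missing calls only).
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= site_missing_max <= 1.0):
        raise ValueError("site_missing_max must be in [0, 1]")
    miss = g.is_missing().mean(axis=0) if g.n_taxa else np.zeros(g.n_sites)
    maf = minor_allele_frequencies(g)
    keep = (miss <= site_missing_max) & ~np.isnan(maf) & (maf >= maf_min)
    out = g.take_sites(np.flatnonzero(keep))
    report = FilterReport(
        n_sites_in=g.n_sites,
        n_sites_out=out.n_sites,
        n_taxa_in=g.n_taxa,
        n_taxa_out=out.n_taxa,
        maf_min=maf_min,
        site_missing_max=site_missing_max,
    )
    if out.n_sites == 0:
        import warnings

        warnings.warn("all sites removed by filter_sites", stacklevel=2)
    return out, report


def filter_taxa(
    g: DosageMatrix, taxon_missing_max: float = 0.2
) -> tuple[DosageMatrix, FilterReport]:
    """Retain taxa with missing fraction <= ``taxon_missing_max``."""
    if not (0.0 <= taxon_missing_max <= 1.0):
        raise ValueError("taxon_missing_max must be in [0, 1]")
    miss = g.is_missing().mean(axis=1) if g.n_sites else np.zeros(g.n_taxa)
    keep = miss <= taxon_missing_max
    out = g.take_taxa(np.flatnonzero(keep))
    report = FilterReport(
        n_sites_in=g.n_sites,
        n_sites_out=out.n_sites,
        n_taxa_in=g.n_taxa,
        n_taxa_out=out.n_taxa,
        taxon_missing_max=taxon_missing_max,
    )
    if out.n_taxa == 0:
        import warnings

        warnings.warn("all taxa removed by filter_taxa", stacklevel=2)
    return out, report


def _pc_scores(x: np.ndarray, n_pc: int) -> np.ndarray:
    """Taxa scores of the leading PCs of a mean-imputed, centered matrix."""
    col_mean = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), col_mean, x)
    centered = filled - filled.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :n_pc] * s[:n_pc]


def pc_integrity_check(g1: DosageMatrix, g2: DosageMatrix, n_pc: int = 2) -> np.ndarray:
    """Correlate taxa PC scores between two genotype matrices.

    Both matrices are restricted to their shared taxa, mean-imputed and
    column-centered, and decomposed by SVD.  Returns the absolute Pearson
    correlation between matched leading PC scores (sign-aligned), one value
    per PC.  Values near 1 indicate that relative genetic distances were
    preserved (e.g. across an imputation or marker-set change).
    """
    shared = [t for t in g1.taxa if t in set(g2.taxa)]
    if len(shared) < 3:
        raise ValueError("g1 and g2 must share at least 3 taxa")
    if len(shared) < n_pc + 1:
        raise ValueError(f"{len(shared)} shared taxa cannot support {n_pc} PCs")
    i1 = [g1.taxon_index()[t] for t in shared]
    i2 = [g2.taxon_index()[t] for t in shared]
    s1 = _pc_scores(g1.to_float()[i1, :], n_pc)
    s2 = _pc_scores(g2.to_float()[i2, :], n_pc)
    out = np.empty(n_pc)
    for k in range(n_pc):
        a, b = s1[:, k], s2[:, k]
        denom = a.std() * b.std()
        out[k] = 0.0 if denom == 0 else abs(np.corrcoef(a, b)[0, 1])
    return out
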