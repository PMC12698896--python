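"""Core containers shared across the pipeline.

The genotypic backbone of every stage is the :class:`DosageMatrix`: a
taxa x sites matrix of ALT-allele counts (0/1/2) with a dedicated
``MISSING`` sentinel.  The sentinel is an out-of-band integer (-1) and is
never allowed to leak into arithmetic: every numeric consumer goes through
:meth:`DosageMatrix.to_float`, which converts missing cells to NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Kept negative so that any
#: accidental arithmetic on raw dosages produces obviously wrong values.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class DosageMatrix:
    """Taxa x sites allele-dosage matrix with site and taxa metadata.

    Parameters
    ----------
    taxa
        Ordered strain identifiers (unique).
    sites
        DataFrame with columns ``chrom, pos, id, ref, alt`` (one row per
        site, order matches the dosage columns).
    dosage
        ``(len(taxa), len(sites))`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    source_tag
        Free-text provenance label (e.g. ``"HD-parents"``).
    """

    taxa: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.taxa), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.sites)} sites"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa identifiers must be unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        self.sites = self.sites.reset_index(drop=True)
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def is_missing(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        return self.dosage == MISSING

    def missing_fraction(self) -> float:
        """Overall fraction of missing cells (0 for an empty matrix)."""
        if self.dosage.size == 0:
            return 0.0
        return float(self.is_missing().mean())

    def to_float(self) -> np.ndarray:
        """Dosages as float64 with missing cells mapped to NaN."""
        out = self.dosage.astype(np.float64)
        out[self.dosage == MISSING] = np.nan
        return out

    # ------------------------------------------------------------------
    def take_taxa(self, index: np.ndarray | list[int]) -> "DosageMatrix":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            taxa=[self.taxa[i] for i in index],
            dosage=self.dosage[index, :],
            sites=self.sites.copy(),
        )

    def take_sites(self, index: np.ndarray | list[int]) -> "DosageMatrix":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            taxa=list(self.taxa),
            dosage=self.dosage[:, index],
            sites=self.sites.iloc[index].reset_index(drop=True),
        )

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}

    def summary(self) -> dict:
        """Counts shown after loading: taxa, markers, % missing."""
        return {
            "n_taxa": self.n_taxa,
            "n_sites": self.n_sites,
            "pct_missing": 100.0 * self.missing_fraction(),
        }

    def copy(self) -> "DosageMatrix":
        return replace(
            self, taxa=list(self.taxa), sites=self.sites.copy(), dosage=self.dosage.copy()
        )

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as comma-separated text: taxa rows, marker-id columns.

        Missing cells are written as ``NA``.
        """
        df = pd.DataFrame(
            self.dosage.astype(object), index=self.taxa, columns=self.sites["id"]
        )
        df = df.mask(self.dosage == MISSING, "NA")
        df.index.name = "taxon"
        df.to_csv(path)


def allele_frequencies(g: DosageMatrix) -> np.ndarray:
    """Per-site ALT allele frequency computed over non-missing calls.

    Sites with no calls get NaN.
    """
    x = g.to_float()
    with np.errstate(invalid="ignore"):
        return np.nanmean(x, axis=0) / 2.0


def minor_allele_frequencies(g: DosageMatrix) -> np.ndarray:
    """Per-site minor-allele frequency in [0, 0.5]."""
    p = allele_frequencies(g)
    return np.minimum(p, 1.0 - p)
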