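"""Nearest-neighbor imputation: exactness, totality, accuracy, determinism."""

import numpy as np
import pandas as pd
import pytest

from gstk.core import MISSING, DosageMatrix
from gstk.imputation import (
    LDKnniParams,
    NumericKnnParams,
    impute_ld_to_hd,
    impute_ldknni,
    impute_numeric_knn,
)
from gstk.simulate import SimConfig, mask_genotypes, simulate_genotypes


def _modal_accuracy(masked, truth):
    """Per-site modal-genotype baseline accuracy on the masked cells."""
    x = masked.to_float()
    correct = 0
    for col, grp in truth.groupby("col"):
        vals = x[:, col]
        vals = vals[~np.isnan(vals)]
        mode = int(np.argmax([np.sum(vals == v) for v in (0, 1, 2)])) if len(vals) else 0
        correct += int((grp["true_dosage"] == mode).sum())
    return correct / len(truth)


@pytest.fixture(scope="module")
def masked_panel():
    cfg = SimConfig(
        n_families=8, lines_per_family=12, n_chrom=2, markers_per_chrom=150, seed=4
    )
    g, _ = simulate_genotypes(cfg)  # 96 x 300
    masked, truth = mask_genotypes(g, 0.2, seed=11)
    return g, masked, truth


def test_duplicate_taxon_recovered_exactly(small_panel):
    g, _, _ = small_panel
    dup = g.copy()
    dup.dosage[1] = dup.dosage[0]
    dup.dosage[1, 7] = MISSING
    imp = impute_ldknni(dup, LDKnniParams(l_sites=10, k_neighbors=1))
    assert imp.dosage[1, 7] == dup.dosage[0, 7]
    imp2 = impute_numeric_knn(dup, NumericKnnParams(k_neighbors=1))
    assert imp2.dosage[1, 7] == dup.dosage[0, 7]


def test_no_missing_is_noop(small_panel):
    g, _, _ = small_panel
    for out in (impute_ldknni(g), impute_numeric_knn(g)):
        np.testing.assert_array_equal(out.dosage, g.dosage)
        assert out.imputation_report["cells_imputed"] == 0


@pytest.mark.parametrize("method", ["ldknni", "numeric"])
def test_observed_cells_never_altered_and_total(masked_panel, method):
    _, masked, _ = masked_panel
    out = (
        impute_ldknni(masked, LDKnniParams(l_sites=20))
        if method == "ldknni"
        else impute_numeric_knn(masked)
    )
    obs = ~masked.is_missing()
    np.testing.assert_array_equal(out.dosage[obs], masked.dosage[obs])
    assert not out.is_missing().any()


def test_accuracy_beats_modal_baseline(masked_panel):
    g, masked, truth = masked_panel
    baseline = _modal_accuracy(masked, truth)
    for out in (impute_ldknni(masked, LDKnniParams(l_sites=20)), impute_numeric_knn(masked)):
        acc = (out.dosage[truth["row"], truth["col"]] == truth["true_dosage"]).mean()
        assert acc > baseline


def test_determinism(masked_panel):
    _, masked, _ = masked_panel
    a = impute_ldknni(masked, LDKnniParams(l_sites=15), seed=0)
    b = impute_ldknni(masked, LDKnniParams(l_sites=15), seed=0)
    np.testing.assert_array_equal(a.dosage, b.dosage)


def test_numeric_knn_all_taxa_equals_site_mean():
    """k = all taxa on a site with one missing cell -> rounded site mean."""
    sites = pd.DataFrame(
        {"chrom": ["1"] * 2, "pos": [1, 2], "id": ["a", "b"], "ref": "A", "alt": "C"}
    )
    dosage = np.array([[0, 2], [1, 2], [2, 1], [1, MISSING]], dtype=np.int8)
    g = DosageMatrix(taxa=list("wxyz"), sites=sites, dosage=dosage)
    out = impute_numeric_knn(g, NumericKnnParams(k_neighbors=3))
    (t, s, val) = out.imputation_report["values"][0]
    assert val == pytest.approx(np.mean([2, 2, 1]))
    assert out.dosage[3, 1] == 2


def test_masking_monotonicity():
    """Average accuracy at 10% masking >= at 40% (5 seeds)."""
    cfg = SimConfig(
        n_families=6, lines_per_family=10, n_chrom=2, markers_per_chrom=100, seed=15
    )
    g, _ = simulate_genotypes(cfg)

    def acc(frac, seed):
        masked, truth = mask_genotypes(g, frac, seed=seed)
        out = impute_ldknni(masked, LDKnniParams(l_sites=15))
        return (out.dosage[truth["row"], truth["col"]] == truth["true_dosage"]).mean()

    lo = np.mean([acc(0.1, s) for s in range(5)])
    hi = np.mean([acc(0.4, s) for s in range(5)])
    assert lo >= hi


@pytest.fixture(scope="module")
def panels():
    cfg = SimConfig(
        n_founders=8, n_families=5, lines_per_family=10, n_chrom=2,
        markers_per_chrom=300, seed=12,
    )
    full, _ = simulate_genotypes(cfg)
    hd = full.take_taxa(range(15))
    hd.source_tag = "HD-parents"
    prog = full.take_taxa(range(15, 50))
    keep = np.sort(np.random.default_rng(1).choice(600, 90, replace=False))
    ld = prog.take_sites(keep)
    ld.source_tag = "LD-progeny"
    return hd, ld, prog, keep


class TestLdToHd:

    def test_duplicate_parent_recovered(self, panels):
        hd, ld, _, keep = panels
        clone = hd.take_taxa([0]).take_sites(keep)
        clone.taxa = ["clone"]
        out = impute_ld_to_hd(hd, clone, LDKnniParams(l_sites=15, k_neighbors=1))
        row = out.taxon_index()["clone"]
        np.testing.assert_array_equal(out.dosage[row], hd.dosage[0])

    def test_concordance_beats_modal(self, panels):
        hd, ld, prog, keep = panels
        out = impute_ld_to_hd(hd, ld, LDKnniParams(l_sites=15, k_neighbors=3))
        hd_only = np.setdiff1d(np.arange(600), keep)
        idx = out.taxon_index()
        rows = [idx[t] for t in prog.taxa]
        conc = (out.dosage[np.ix_(rows, hd_only)] == prog.dosage[:, hd_only]).mean()
        x = hd.to_float()[:, hd_only]
        modes = np.array(
            [np.argmax([np.sum(x[:, j] == v) for v in (0, 1, 2)]) for j in range(len(hd_only))]
        )
        modal = (prog.dosage[:, hd_only] == modes[None, :]).mean()
        assert conc > modal

    def test_reference_taxa_unchanged(self, panels):
        hd, ld, _, _ = panels
        out = impute_ld_to_hd(hd, ld, LDKnniParams(l_sites=15))
        np.testing.assert_array_equal(out.dosage[: hd.n_taxa], hd.dosage)

    def test_empty_intersection_errors(self, panels):
        hd, ld, _, _ = panels
        renamed = ld.copy()
        renamed.sites = renamed.sites.assign(id=[f"other{i}" for i in range(ld.n_sites)])
        with pytest.raises(ValueError, match="shared marker"):
            impute_ld_to_hd(hd, renamed)

    def test_allele_swap_flipped(self, panels):
        hd, ld, prog, keep = panels
        swapped = ld.copy()
        # swap ref/alt of the first LD site and flip its dosages
        s = swapped.sites.iloc[0]
        swapped.sites.loc[0, ["ref", "alt"]] = [s["alt"], s["ref"]]
        col = swapped.dosage[:, 0]
        flip = col != MISSING
        col[flip] = 2 - col[flip]
        out_sw = impute_ld_to_hd(hd, swapped, LDKnniParams(l_sites=15))
        out = impute_ld_to_hd(hd, ld, LDKnniParams(l_sites=15))
        np.testing.assert_array_equal(out_sw.dosage, out.dosage)
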