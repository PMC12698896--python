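"""CV plan construction, leakage guards, PA summaries, model comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gstk.bayes_kernel import GibbsConfig
from gstk.cross_validation import (
    CVResult,
    compare_models,
    gblup_fitter,
    make_partitions,
    me_model_fitter,
    run_cv,
)
from gstk.kernels import MODEL_TAGS, MEModelSpec


class TestMakePartitions:
    def test_cv0_one_fold_per_env(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV0")
        assert len(plan.folds) == len(ds.envs)
        for f in plan.folds:
            assert set(ds.records["env"].iloc[f.test]) == {f.label}

    def test_cv1_masks_whole_strains(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV1", k=5, seed=3)
        strains = sorted(set(ds.records["strain"]))
        seen = []
        for f in plan.folds:
            masked = set(ds.records["strain"].iloc[f.test])
            train_strains = set(ds.records["strain"].iloc[f.train])
            assert not masked & train_strains  # leakage guard
            seen.extend(masked)
        assert sorted(seen) == strains  # each strain masked exactly once

    def test_cv00_cell_restriction(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV00", k=3, seed=1)
        rec = ds.records
        for f in plan.folds:
            test_strains = set(rec["strain"].iloc[f.test])
            test_envs = set(rec["env"].iloc[f.test])
            assert not test_strains & set(rec["strain"].iloc[f.train])
            assert not test_envs & set(rec["env"].iloc[f.train])

    def test_lofo_by_factor(self, me_dataset):
        ds, _, _, _ = me_dataset
        from dataclasses import replace

        rec = ds.records.copy()
        rec["trial"] = np.where(rec["env"].isin(ds.envs[:2]), "T1", "T2")
        ds2 = replace(ds, records=rec)
        plan = make_partitions(ds2, "LOFO", factor="trial")
        assert {f.label for f in plan.folds} == {"T1", "T2"}
        with pytest.raises(ValueError, match="factor column"):
            make_partitions(ds, "LOFO", factor="nope")

    def test_kfold_covers_each_record_once(self, me_dataset):
        ds, _, _, _ = me_dataset
        for scheme in ("kfold", "CV2"):
            plan = make_partitions(ds, scheme, k=4, seed=7)
            allm = sorted(itertools.chain(*[f.test.tolist() for f in plan.folds]))
            assert allm == list(range(ds.n_records))

    def test_cv2_stratified_by_env(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV2", k=5, seed=2)
        per_env = ds.records["env"].value_counts()
        for f in plan.folds:
            counts = ds.records["env"].iloc[f.test].value_counts()
            for env, n_env in per_env.items():
                assert abs(counts.get(env, 0) - n_env / 5) <= 1

    def test_seed_determinism(self, me_dataset):
        ds, _, _, _ = me_dataset
        a = make_partitions(ds, "CV1", k=5, seed=4)
        b = make_partitions(ds, "CV1", k=5, seed=4)
        c = make_partitions(ds, "CV1", k=5, seed=5)
        assert a.masked_sets() == b.masked_sets()
        assert a.masked_sets() != c.masked_sets()


class TestRunCV:
    def test_perfect_predictions(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "kfold", k=4, seed=1)
        y = ds.records["value"].to_numpy()
        res = run_cv(ds, lambda d, tr, te: y[te], plan)
        np.testing.assert_allclose(res.unit_pa["pa"], 1.0, atol=1e-12)
        assert res.se_pa == pytest.approx(0.0, abs=1e-12)

    def test_noise_predictions_near_zero(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "kfold", k=2, seed=1)
        rng = np.random.default_rng(8)
        res = run_cv(ds, lambda d, tr, te: rng.normal(size=len(te)), plan)
        assert abs(res.mean_pa) < 0.15  # ~125 records per fold

    def test_summary_matches_independent_recount(self, me_dataset, linear_kernel):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV1", k=4, seed=2)
        res = run_cv(ds, gblup_fitter(linear_kernel), plan)
        pa = res.unit_pa["pa"].dropna().to_numpy()
        assert res.mean_pa == pytest.approx(pa.mean())
        assert res.se_pa == pytest.approx(pa.std(ddof=1) / np.sqrt(len(pa)))
        assert res.min_pa == pytest.approx(pa.min())
        assert res.max_pa == pytest.approx(pa.max())

    def test_refusal_recorded_not_fatal(self, me_dataset, linear_kernel):
        ds, omega, _, _ = me_dataset
        plan = make_partitions(ds, "CV0")
        fitter = me_model_fitter(
            MEModelSpec("G+E"), linear_kernel, omega,
            GibbsConfig(n_iter=200, burn_in=50, thin=2, seed=1),
            allow_unseen_env=False,
        )
        res = run_cv(ds, fitter, plan)
        assert len(res.failures) == len(plan.folds)
        assert res.unit_pa["pa"].isna().all()

    def test_small_fold_flagged(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "kfold", k=4, seed=1)
        plan.folds[0].test = plan.folds[0].test[:2]
        plan.folds[0].flagged = True
        y = ds.records["value"].to_numpy()
        res = run_cv(ds, lambda d, tr, te: y[te], plan)
        assert np.isnan(res.unit_pa["pa"].iloc[0])


class TestCompareModels:
    def test_full_grid_shape(self, me_dataset):
        """9 formulae x 2 genomic kernels -> 18 result rows."""
        ds, omega, _, _ = me_dataset
        plan = make_partitions(ds, "CV2", k=2, seed=3)
        grid = [(tag, kind) for tag in MODEL_TAGS for kind in ("gaussian", "linear")]
        cfg = GibbsConfig(n_iter=150, burn_in=50, thin=2, seed=1)
        table = compare_models(ds, grid, omega, plan, cfg)
        assert len(table) == 18
        assert set(table["model"]) == set(MODEL_TAGS)
        assert table["mean_pa"].notna().all()

    def test_identical_model_identical_rows(self, me_dataset):
        ds, omega, _, _ = me_dataset
        plan = make_partitions(ds, "CV2", k=2, seed=3)
        cfg = GibbsConfig(n_iter=200, burn_in=50, thin=2, seed=1)
        table = compare_models(ds, [("G+E", "linear"), ("G+E", "linear")], omega, plan, cfg)
        pd.testing.assert_series_equal(
            table.iloc[0].drop("model"), table.iloc[1].drop("model"), check_names=False
        )

    def test_paired_plan_shared_masks(self, me_dataset):
        ds, _, _, _ = me_dataset
        plan = make_partitions(ds, "CV1", k=3, seed=9)
        again = make_partitions(ds, "CV1", k=3, seed=9)
        assert plan.masked_sets() == again.masked_sets()
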