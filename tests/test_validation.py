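"""Optimism bootstrap: bookkeeping identities, approach semantics, shrinkage."""

import logging

import numpy as np
import pandas as pd
import pytest

import lassoval as lv
from lassoval.lasso import PooledLassoModel
from lassoval.validation import ValidationReport


def fixed_builder(coefs, intercept=1.0):
    model = PooledLassoModel(intercept, np.asarray(coefs, float),
                             (np.asarray(coefs) != 0).astype(int))

    def fit(sets, seed):
        return model

    return fit


@pytest.fixture(scope="module")
def small_sets(cohort):
    idx = np.arange(120)
    sub = lv.Dataset(cohort.values[idx], cohort.mask[idx], cohort.columns, cohort.var_types)
    return lv.ImputedSets([sub], sub.mask.copy())


class TestBookkeeping:
    def test_tabled_arithmetic(self):
        assert lv.corrected_performance(0.9047, [-0.1162]) == pytest.approx(1.0209)

    def test_hand_arithmetic(self):
        assert lv.corrected_performance(2.0, [-0.5, -1.5]) == pytest.approx(3.0)

    def test_zero_optimism_returns_apparent(self):
        assert lv.corrected_performance(1.23, [0.0, 0.0]) == 1.23

    def test_empty_optimisms_rejected(self):
        with pytest.raises(ValueError):
            lv.corrected_performance(1.0, [])

    def test_per_boot_identities_hold_exactly(self, small_sets):
        rep = lv.bootstrap_optimism(small_sets, 1, B=6, mode="best",
                                    n_lambda=8, n_boot_tune=8, seed=0)
        r = rep.records
        assert np.array_equal(r["optimism"], r["apparent"] - r["test"])
        assert rep.corrected_performance == pytest.approx(rep.apparent - r["optimism"].mean())
        assert rep.shrinkage_s == pytest.approx(r["lp_slope"].mean())


class TestShrinkageFactor:
    def _report(self, slopes):
        rec = pd.DataFrame({"apparent": 0.0, "test": 0.0, "optimism": 0.0,
                            "lp_slope": slopes})
        return ValidationReport(1, "best", len(slopes), 0.0, rec)

    def test_constant_slopes(self):
        assert lv.shrinkage_factor(self._report([0.9, 0.9, 0.9])) == pytest.approx(0.9)

    def test_non_finite_excluded_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="lassoval.validation"):
            s = lv.shrinkage_factor(self._report([1.0, np.inf, 3.0]))
        assert s == pytest.approx(2.0)
        assert "non-finite" in caplog.text

    def test_all_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lv.shrinkage_factor(self._report([np.nan]))


class TestDegenerateBuilder:
    def test_data_independent_model_has_zero_optimism(self):
        # builder ignores the data and its residuals are the same constant on
        # every row, so apparent* and test* agree exactly on any resample
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 3))
        beta = np.array([0.5, -1.0, 2.0])
        from conftest import toy_dataset

        ds = toy_dataset(X, 1.0 + X @ beta + 2.0)
        sets = lv.ImputedSets([ds], ds.mask.copy())
        rep = lv.bootstrap_optimism(sets, 1, B=5, mode="best", seed=1,
                                    fit_fn=fixed_builder(beta, intercept=1.0))
        assert np.allclose(rep.records["apparent"], 4.0)
        assert np.allclose(rep.records["optimism"], 0.0, atol=1e-12)
        assert rep.corrected_performance == pytest.approx(rep.apparent)

    def test_halved_coefficients_give_slope_two(self):
        # noiseless outcome, builder returns the truth halved => regressing
        # y on LP* recovers slope 2 exactly
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 3))
        beta = np.array([1.0, -2.0, 0.5])
        from conftest import toy_dataset

        ds = toy_dataset(X, X @ beta)
        sets = lv.ImputedSets([ds], ds.mask.copy())
        rep = lv.bootstrap_optimism(sets, 1, B=4, mode="best", seed=2,
                                    fit_fn=fixed_builder(beta / 2, intercept=0.0))
        assert rep.shrinkage_s == pytest.approx(2.0)


def standalone_harrell(ds, B, modes, n_lambda, n_boot_tune, seed):
    """Independent no-missing-data Harrell procedure (plain numpy loop over
    the documented seed layout), used as the equivalence oracle."""
    root = np.random.SeedSequence(seed)
    s_orig, s_boot = root.spawn(2)
    n = ds.n

    def build(dataset, seed_seq):
        tr = lv.tune_penalty(dataset, n_boot=n_boot_tune, seed=seed_seq, n_lambda=n_lambda)
        return {md: lv.fit_lasso(dataset, tr.lambda_for(md)) for md in modes}

    orig = build(ds, s_orig)
    apparent = {md: lv.mse(orig[md], ds) for md in modes}
    out = {md: [] for md in modes}
    for stream in s_boot.spawn(B):
        s_idx, s_fit, _ = stream.spawn(3)
        idx = np.random.default_rng(s_idx).integers(0, n, size=n)
        ds_boot = lv.Dataset(ds.values[idx], ds.mask[idx], ds.columns, ds.var_types)
        models = build(ds_boot, s_fit)
        for md in modes:
            app = lv.mse(models[md], ds_boot)
            test = lv.mse(models[md], ds)
            lp = models[md].predict(ds)
            slope = np.cov(lp, ds.outcome, ddof=0)[0, 1] / lp.var()
            out[md].append((app, test, app - test, slope))
    return apparent, out


class TestApproachSemantics:
    def test_approach3_equals_standalone_no_mi_procedure(self, imputed_small):
        modes = ("best", "tolerance")
        reports = lv.bootstrap_optimism(imputed_small, 3, B=5, mode=modes,
                                        n_lambda=10, n_boot_tune=10,
                                        set_index=1, seed=7)
        apparent, records = standalone_harrell(imputed_small.sets[1], 5, modes,
                                               n_lambda=10, n_boot_tune=10, seed=7)
        for md in modes:
            rep = reports[md]
            assert rep.apparent == pytest.approx(apparent[md], abs=1e-12)
            got = rep.records[["apparent", "test", "optimism", "lp_slope"]].to_numpy()
            assert np.allclose(got, np.asarray(records[md]), atol=1e-10)

    def test_identical_copies_make_approaches_1_and_3_coincide(self, small_sets):
        ds = small_sets.sets[0]
        copies = lv.ImputedSets([ds.copy() for _ in range(4)], ds.mask.copy())
        kw = dict(B=4, mode="best", n_lambda=8, n_boot_tune=8, seed=5)
        r1 = lv.bootstrap_optimism(copies, 1, **kw)
        r3 = lv.bootstrap_optimism(copies, 3, **kw)
        assert np.allclose(r1.records.to_numpy(), r3.records.to_numpy(), atol=1e-12)
        assert r1.apparent == pytest.approx(r3.apparent)

    def test_approach2_on_identical_copies_reports_little_optimism(self, cohort):
        # ten copies of one complete dataset mimic an MI setup without
        # missingness; per-set resampling averages away the overfit, so the
        # optimism estimate wrongly collapses toward zero
        copies = lv.ImputedSets([cohort.copy() for _ in range(10)], cohort.mask.copy())
        kw = dict(B=8, mode="best", n_lambda=12, n_boot_tune=12, seed=9)
        r1 = lv.bootstrap_optimism(copies, 1, **kw)
        r2 = lv.bootstrap_optimism(copies, 2, **kw)
        assert abs(r2.mean_optimism) < 0.1
        assert abs(r2.mean_optimism) < 0.4 * abs(r1.mean_optimism)

    def test_approach4_runs_and_respects_identities(self, incomplete_cohort):
        rep = lv.bootstrap_optimism(incomplete_cohort, 4, B=3, mode="best",
                                    n_lambda=8, n_boot_tune=8, m=2,
                                    impute_kwargs=dict(n_cycles=2), seed=11)
        r = rep.records
        assert len(r) == 3
        assert np.array_equal(r["optimism"], r["apparent"] - r["test"])
        assert np.isfinite(r.to_numpy()).all()

    def test_approach4_rejects_imputed_sets_source(self, imputed_small):
        with pytest.raises(TypeError):
            lv.bootstrap_optimism(imputed_small, 4, B=2, seed=0)

    def test_invalid_arguments(self, small_sets):
        with pytest.raises(ValueError):
            lv.bootstrap_optimism(small_sets, 5, B=2, seed=0)
        with pytest.raises(ValueError):
            lv.bootstrap_optimism(small_sets, 1, B=0, seed=0)

    def test_seed_reproducibility(self, imputed_small):
        kw = dict(B=3, mode="best", n_lambda=8, n_boot_tune=8, seed=13)
        a = lv.bootstrap_optimism(imputed_small, 2, **kw)
        b = lv.bootstrap_optimism(imputed_small, 2, **kw)
        assert np.array_equal(a.records.to_numpy(), b.records.to_numpy())
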