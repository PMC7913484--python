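import math

import numpy as np
import pytest

from honeynir import (CalibrationError, SpectraSet, apply_treatment,
                      calibration_stats, cross_validate,
                      eliminate_t_outliers, external_validate, fit_mpls,
                      fit_pca, screen_h, select_best_model)
from conftest import SMALL_GRID
from oracles import nipals_pls1, paired_t_pvalue, svd_pca


class TestPCA:
    def test_rank_one_data_first_component_explains_all(self, rng):
        direction = rng.normal(size=12)
        coef = rng.normal(size=(20, 1))
        x = coef * direction + rng.normal(size=12)  # one line through centroid
        pca = fit_pca(x, 1)
        assert pca.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        x = rng.normal(size=(25, 10))
        pca = fit_pca(x, 4)
        loadings, scores, explained = svd_pca(x, 4)
        for j in range(4):
            sign = np.sign(loadings[:, j] @ pca.loadings[:, j])
            np.testing.assert_allclose(pca.loadings[:, j],
                                       sign * loadings[:, j], atol=1e-8)
            np.testing.assert_allclose(pca.scores[:, j],
                                       sign * scores[:, j], atol=1e-8)
        np.testing.assert_allclose(pca.explained_variance_pct, explained,
                                   atol=1e-8)

    def test_all_components_explain_everything(self, rng):
        x = rng.normal(size=(8, 5))
        pca = fit_pca(x, 5)
        assert pca.explained_variance_pct[-1] == pytest.approx(100.0)

    def test_components_beyond_rank_rejected(self, rng):
        x = np.tile(rng.normal(size=6), (9, 1)) + rng.normal(size=(9, 1))
        with pytest.raises(CalibrationError, match="rank"):
            fit_pca(x, 5)

    def test_loadings_orthonormal(self, rng):
        pca = fit_pca(rng.normal(size=(30, 12)), 6)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)


class TestHScreen:
    def test_sample_at_centroid_has_zero_h(self, rng):
        center = rng.normal(size=6)
        deltas = rng.normal(size=(4, 6))
        x = np.vstack([center + deltas, center - deltas, center])
        pca = fit_pca(x, 3)
        result = screen_h(pca)
        assert result.h_values[-1] == pytest.approx(0.0, abs=1e-16)

    def test_mean_h_trace_identity(self, rng):
        n = 50
        pca = fit_pca(rng.normal(size=(n, 20)), 5)
        result = screen_h(pca)
        assert result.h_values.mean() == pytest.approx((n - 1) / n, rel=1e-10)

    def test_injected_outlier_flagged(self, rng):
        x = rng.normal(size=(60, 15))
        x[0] += 10.0 * x.std(axis=0)
        pca = fit_pca(x, 5)
        result = screen_h(pca, threshold=3.0)
        assert 0 in result.outlier_idx

    def test_threshold_monotonicity(self, rng):
        pca = fit_pca(rng.normal(size=(40, 10)), 4)
        flagged = [set(screen_h(pca, thr).outlier_idx.tolist())
                   for thr in (0.5, 1.0, 2.0, 3.0)]
        for smaller, larger in zip(flagged[1:], flagged[:-1]):
            assert smaller <= larger


class TestMPLS:
    def test_plain_mode_matches_nipals_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(20, 8))
            y = x @ rng.normal(size=8) + rng.normal(size=20) * 0.1
            for nf in (1, 3, 5):
                model = fit_mpls(x, y, nf, modified=False)
                coef, intercept, fitted = nipals_pls1(x, y, nf)
                np.testing.assert_allclose(model.coefficients, coef, atol=1e-8)
                np.testing.assert_allclose(model.predict(x), fitted, atol=1e-8)

    def test_noiseless_linear_perfect_fit(self, rng):
        x = rng.normal(size=(30, 6))
        y = x @ rng.normal(size=6) + 2.0
        model = fit_mpls(x, y, 6, modified=True)
        resid = y - model.predict(x)
        sstot = np.sum((y - y.mean()) ** 2)
        assert 1 - resid @ resid / sstot == pytest.approx(1.0, abs=1e-12)

    def test_single_channel_equals_univariate_least_squares(self, rng):
        x = rng.normal(size=(15, 1))
        y = 3.0 * x[:, 0] + 1.0 + rng.normal(size=15) * 0.2
        model = fit_mpls(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        np.testing.assert_allclose(model.predict(x),
                                   slope * x[:, 0] + intercept, atol=1e-10)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(CalibrationError, match="zero-variance"):
            fit_mpls(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_predictions_reproduce_fitted_values(self, rng):
        # the stored linear coefficients must replay the fit exactly
        x = rng.normal(size=(40, 12))
        y = x @ rng.normal(size=12) + rng.normal(size=40)
        model = fit_mpls(x, y, 6, modified=True)
        np.testing.assert_allclose(model.predict(x),
                                   model.predict(x.copy()), atol=1e-12)
        np.testing.assert_allclose(
            model.predict(x, n_factors=model.n_factors),
            model.predict(x), atol=1e-10)

    def test_factor_cap(self, rng):
        with pytest.raises(CalibrationError, match="exceeds"):
            fit_mpls(rng.normal(size=(5, 10)), rng.normal(size=5), 5)

    def test_modified_differs_from_plain_on_noisy_data(self, rng):
        x = rng.normal(size=(25, 10)) * rng.uniform(0.1, 10, size=10)
        y = x @ rng.normal(size=10) + rng.normal(size=25)
        plain = fit_mpls(x, y, 3, modified=False)
        modified = fit_mpls(x, y, 3, modified=True)
        assert not np.allclose(plain.coefficients, modified.coefficients)


class TestCrossValidation:
    def test_each_sample_in_exactly_one_fold(self, rng):
        x = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        cv = cross_validate(x, y, 3, n_groups=8, seed=1)
        all_idx = np.concatenate(cv.folds)
        assert sorted(all_idx.tolist()) == list(range(30))

    def test_noiseless_linear_secv_tiny(self, rng):
        x = rng.normal(size=(40, 5))
        y = x @ rng.normal(size=5)
        cv = cross_validate(x, y, 5, n_groups=8, seed=1)
        assert cv.secv[-1] < 1e-6 * y.std()

    def test_pure_noise_null(self, rng):
        y = rng.normal(size=200)
        x = rng.normal(size=(200, 10))
        cv = cross_validate(x, y, 8, n_groups=8, seed=1)
        assert cv.best_factors() <= 2
        assert cv.secv.min() == pytest.approx(y.std(), rel=0.2)

    def test_fold_count_bounds(self, rng):
        with pytest.raises(CalibrationError, match="n_groups"):
            cross_validate(rng.normal(size=(10, 3)), rng.normal(size=10), 2,
                           n_groups=1)

    def test_secv_at_least_sec_on_noisy_data(self, rng):
        # regularity check, not a theorem: CV error should rarely beat SEC
        wins = 0
        trials = 20
        for _ in range(trials):
            x = rng.normal(size=(40, 8))
            y = x @ rng.normal(size=8) + rng.normal(size=40)
            nf = 4
            model = fit_mpls(x, y, nf)
            e = y - model.predict(x)
            sec = math.sqrt(e @ e / (40 - nf - 1))
            cv = cross_validate(x, y, nf, n_groups=8, seed=0)
            if cv.secv[nf - 1] >= sec:
                wins += 1
        assert wins >= 0.9 * trials


class TestTElimination:
    def test_perfect_fit_no_removals(self, rng):
        x = rng.normal(size=(20, 4))
        y = x @ rng.normal(size=4)
        result = eliminate_t_outliers(x, y, 4)
        assert result.removed_idx.size == 0

    def test_corrupted_sample_removed_first_pass(self, rng):
        x = rng.normal(size=(40, 5))
        y = x @ rng.normal(size=5) + rng.normal(size=40) * 0.05
        y[7] += 10.0 * y.std()
        result = eliminate_t_outliers(x, y, 5)
        assert 7 in result.removed_idx

    def test_removal_bookkeeping(self, rng):
        x = rng.normal(size=(40, 5))
        y = x @ rng.normal(size=5) + rng.normal(size=40) * 0.3
        y[::9] += 5 * y.std()
        result = eliminate_t_outliers(x, y, 5)
        assert result.removed_idx.size == 40 - result.retained_idx.size
        assert np.intersect1d(result.removed_idx, result.retained_idx).size == 0


def engineered_fit(sd, sec, n=3):
    """y_ref/y_fit pair with exact SD and SEC (1 factor)."""
    y_ref = np.array([-sd, 0.0, sd])
    e = np.array([sec * math.sqrt(n - 2), 0.0, 0.0])
    return y_ref, y_ref - e


class TestCalibrationStats:
    @pytest.mark.parametrize("sd,sec,expected", [
        (31.6, 11.3, 2.8),   # Pfund-style arithmetic
        (1.0, 0.5, 2.0),     # moisture-style arithmetic
    ])
    def test_rpd_is_sd_over_sec(self, sd, sec, expected):
        y_ref, y_fit = engineered_fit(sd, sec)
        stats = calibration_stats(y_ref, y_fit, None, 1)
        assert stats.SD == pytest.approx(sd)
        assert stats.SEC == pytest.approx(sec)
        assert round(stats.RPD, 1) == expected

    def test_rpd_on_secv_flag(self):
        y_ref, y_fit = engineered_fit(2.0, 1.0)
        y_cv = y_ref - 0.5
        stats = calibration_stats(y_ref, y_fit, y_cv, 1, rpd_on="secv")
        assert stats.RPD == pytest.approx(stats.SD / stats.SECV)

    def test_perfect_fit_sentinels(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        stats = calibration_stats(y, y, y, 1)
        assert stats.RSQ == pytest.approx(1.0)
        assert stats.SEC == 0.0
        assert math.isinf(stats.RPD)

    def test_est_range_clamped_for_nonnegative(self):
        y_ref, y_fit = engineered_fit(5.0, 1.0)
        stats = calibration_stats(y_ref, y_fit, None, 1, nonnegative=True)
        assert stats.est_min == 0.0
        assert stats.est_max == pytest.approx(stats.mean + 3 * stats.SD)

    def test_secv_uses_n_denominator(self, rng):
        y_ref = rng.normal(size=10)
        y_cv = y_ref + 1.0
        stats = calibration_stats(y_ref, y_ref, y_cv, 1)
        assert stats.SECV == pytest.approx(1.0)

    def test_too_few_samples(self):
        with pytest.raises(CalibrationError, match="N"):
            calibration_stats([1.0, 2.0], [1.0, 2.0], None, 1)


class TestExternalValidation:
    def test_identical_predictions_all_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        stats = external_validate(y, y)
        assert stats.RMSE == 0.0 and stats.SEP == 0.0 and stats.bias == 0.0
        assert stats.t_p_value == 1.0 and stats.comparable

    def test_pure_bias(self):
        y = np.array([1.0, 2.0, 3.0])
        stats = external_validate(y, y + 0.7)
        assert stats.bias == pytest.approx(0.7)
        assert stats.SEP_C == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_textbook_oracle(self, rng):
        for _ in range(5):
            y_ref = rng.normal(size=16)
            y_pred = y_ref + rng.normal(size=16) * 0.5 + 0.1
            stats = external_validate(y_ref, y_pred)
            assert stats.t_p_value == pytest.approx(
                paired_t_pvalue(y_pred, y_ref), abs=1e-10)

    def test_consistency_identity(self, rng):
        # RMSE^2 = bias^2 + SEP_C^2 (n-1)/n
        y_ref = rng.normal(size=20)
        y_pred = y_ref + rng.normal(size=20)
        s = external_validate(y_ref, y_pred)
        assert s.RMSE ** 2 == pytest.approx(
            s.bias ** 2 + s.SEP_C ** 2 * 19 / 20, rel=1e-10)

    def test_minimum_pairs(self):
        with pytest.raises(CalibrationError, match="at least 3"):
            external_validate([1.0, 2.0], [1.0, 2.0])


class TestModelSelection:
    @pytest.fixture(scope="class")
    def cal_data(self, default_dataset):
        ids = default_dataset.ids_in("calibration")
        return (default_dataset.spectra.subset(ids),
                default_dataset.reference.loc[ids, "moisture"].to_numpy())

    def test_single_treatment_grid_returns_it(self, cal_data):
        spectra, y = cal_data
        sel = select_best_model(spectra, y, "moisture",
                                treatment_grid=("SNV 1,4,4,1",), seed=0)
        assert str(sel.best.treatment) == "SNV 1,4,4,1"

    def test_report_covers_grid(self, cal_data):
        spectra, y = cal_data
        sel = select_best_model(spectra, y, "moisture",
                                treatment_grid=SMALL_GRID, seed=0)
        assert len(sel.grid) == len(SMALL_GRID)

    def test_scatter_correction_wins_under_strong_scatter(self, rng):
        from honeynir import SyntheticConfig, generate_dataset
        cfg = SyntheticConfig(seed=11, scatter_model=(0.3, 0.1, 0.05))
        ds = generate_dataset(cfg)
        ids = ds.ids_in("calibration")
        spectra = ds.spectra.subset(ids)
        y = ds.reference.loc[ids, "moisture"].to_numpy()
        sel = select_best_model(
            spectra, y, "moisture", seed=0,
            treatment_grid=("None 0,0,1,1", "SNV 1,4,4,1", "MSC 1,4,4,1",
                            "SNV-DT 1,4,4,1"))
        by_treatment = {str(e.treatment): e.stats for e in sel.grid
                        if e.stats is not None}
        none_secv = by_treatment["None 0,0,1,1"].SECV
        corrected = [s.SECV for t, s in by_treatment.items()
                     if t != "None 0,0,1,1"]
        assert min(corrected) < none_secv

    def test_recovery_harness(self, cal_data):
        # low-noise synthetic data must be recoverable end to end
        spectra, y = cal_data
        sel = select_best_model(spectra, y, "moisture",
                                treatment_grid=SMALL_GRID, seed=0)
        assert sel.best.stats.RSQ > 0.95


def test_mpls_identity_with_rescaling_disabled(rng):
    # MPLS -> PLS1 limit across all factor counts
    x = rng.normal(size=(30, 10))
    y = x @ rng.normal(size=10) + rng.normal(size=30) * 0.2
    for nf in range(1, 8):
        model = fit_mpls(x, y, nf, modified=False)
        coef, _, _ = nipals_pls1(x, y, nf)
        np.testing.assert_allclose(model.coefficients, coef, atol=1e-8)
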