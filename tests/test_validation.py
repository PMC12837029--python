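import numpy as np
import pytest
from scipy import stats

from mixcal import calibration, designs, spectra_sim, validation
from mixcal.validation import (
    applicability_domain,
    error_metrics,
    friedman_test,
    nested_cv,
    pooled_t_test,
    rmse_reduction,
    variance_ratio_f,
    y_randomization,
)


class TestErrorMetrics:
    def test_perfect_prediction(self):
        y = np.array([10.0, 15.0, 20.0, 25.0])
        rep = error_metrics(y, y)
        assert rep.rmse == 0.0
        assert rep.mean_recovery == pytest.approx(100.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0)
        assert rep.r == pytest.approx(1.0)

    def test_constant_offset(self):
        y = np.array([10.0, 20.0, 30.0])
        rep = error_metrics(y, y + 1.0)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(1.0)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 30, size=20)
        y_hat = y + rng.normal(0, 0.5, size=20)
        rep = error_metrics(y, y_hat)
        brute_rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(y_hat, y)) / 20)
        assert rep.rmse == pytest.approx(brute_rmse, abs=1e-12)
        # r from the explicit covariance formula
        r = np.sum((y - y.mean()) * (y_hat - y_hat.mean())) / np.sqrt(
            np.sum((y - y.mean()) ** 2) * np.sum((y_hat - y_hat.mean()) ** 2))
        assert rep.r == pytest.approx(r, abs=1e-12)
        assert rep.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_rsd_definition(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(10, 30, size=15)
        y_hat = y * rng.normal(1.0, 0.02, size=15)
        rep = error_metrics(y, y_hat)
        rec = 100 * y_hat / y
        assert rep.rsd_percent == pytest.approx(100 * rec.std(ddof=1) / rec.mean())

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            error_metrics(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestRMSEReduction:
    def test_identity(self):
        assert rmse_reduction(0.5, 0.5) == 0.0

    def test_paper_style_arithmetic(self):
        assert round(rmse_reduction(0.3913, 0.0317), 1) == 91.9
        assert round(rmse_reduction(0.4068, 0.1996), 1) == 50.9

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            rmse_reduction(0.0, 0.1)


class _PLSFactory:
    def __init__(self, max_lv=5):
        self.max_lv = max_lv

    def __call__(self, x, y):
        cap = min(self.max_lv, x.shape[0] - 2, x.shape[1])
        lv, _ = calibration.select_lv_loocv(x, y, cap)
        return calibration.fit_pls(x, y, lv)


class TestNestedCV:
    def test_zero_noise_linear(self, clean_calibration):
        res = nested_cv(clean_calibration.absorbance, clean_calibration.concentrations,
                        _PLSFactory(), outer_folds=5, n_bootstrap=200, seed=0)
        assert res.pooled_rmsecv <= 1e-6
        assert res.ci_high - res.ci_low <= 1e-6

    def test_no_leakage_row_indices(self, noisy_calibration):
        res = nested_cv(noisy_calibration.absorbance, noisy_calibration.concentrations,
                        _PLSFactory(), outer_folds=5, n_bootstrap=50, seed=1)
        for tr, te in zip(res.train_indices, res.test_indices):
            assert set(tr).isdisjoint(te)
        all_test = np.concatenate(res.test_indices)
        assert sorted(all_test) == list(range(noisy_calibration.n_samples))

    def test_bootstrap_constant_residuals_zero_width(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        y = (x @ np.ones(3))[:, None]

        class Exact:
            def predict(self, xn):
                return (xn @ np.ones(3))[:, None] + 0.5  # constant residual 0.5

        res = nested_cv(x, y, lambda a, b: Exact(), outer_folds=4, n_bootstrap=100, seed=3)
        assert res.ci_high - res.ci_low < 1e-12
        assert res.pooled_rmsecv == pytest.approx(0.5)

    def test_fold_count_bound(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError):
            nested_cv(x, np.zeros(3), _PLSFactory(), outer_folds=5)

    def test_leakage_sentinel(self, noisy_calibration):
        """A column equal to the outer-fold test labels must not help an
        honest protocol (tuning confined to the training rows), while a
        deliberately leaky protocol collapses toward zero error."""
        x = noisy_calibration.absorbance
        y = noisy_calibration.concentrations[:, :1]
        n = x.shape[0]
        rng = np.random.default_rng(4)

        clean = nested_cv(x, y, _TopKFactory(k=20), outer_folds=5, n_bootstrap=50, seed=5)

        # replay the same outer folds, injecting a per-fold sentinel column
        # that equals y on that fold's test rows and is noise on its training
        # rows
        honest_sq, leaky_sq = [], []
        for tr, te in zip(clean.train_indices, clean.test_indices):
            z = rng.normal(20, 6, size=n)
            z[te] = y[te, 0]
            x_aug = np.column_stack([x, z])
            model = _TopKFactory(k=20)(x_aug[tr], y[tr])  # honest: sees train only
            honest_sq.extend(((model.predict(x_aug[te]) - y[te]) ** 2).ravel())
            # leaky: the "selected feature" was picked by looking at the test
            # labels, so prediction is the sentinel itself
            leaky_sq.extend(((z[te, None] - y[te]) ** 2).ravel())
        honest_rmse = np.sqrt(np.mean(honest_sq))
        leaky_rmse = np.sqrt(np.mean(leaky_sq))

        assert honest_rmse <= 2.0 * clean.pooled_rmsecv
        assert leaky_rmse < 1e-12


def _top_k_columns(x, y, k):
    corr = np.abs(np.corrcoef(x.T, y[:, 0])[-1, :-1])
    return np.argsort(corr)[-k:]


class _TopKFactory:
    """Selects its top-correlated columns on the data it is given only."""

    def __init__(self, k):
        self.k = k

    def __call__(self, x, y):
        cols = _top_k_columns(x, y, self.k)
        cap = min(3, x.shape[0] - 2)
        model = calibration.fit_pls(x[:, cols], y, cap)

        class _Wrapped:
            def predict(self, xn):
                return model.predict(xn[:, cols])

        return _Wrapped()


class TestBootstrapCoverage:
    def test_95_ci_covers_true_rmse(self):
        # 200 seeded replicates of n=30 Gaussian residuals; the percentile CI
        # for RMSE should contain sigma in >= 90% of them
        rng = np.random.default_rng(6)
        sigma, n, covered = 1.0, 80, 0
        for _ in range(200):
            resid = rng.normal(0, sigma, size=n)
            sq = resid**2
            boot = np.array([
                np.sqrt(sq[rng.integers(0, n, size=n)].mean()) for _ in range(400)])
            lo, hi = np.percentile(boot, [2.5, 97.5])
            covered += lo <= sigma <= hi
        assert covered >= 180


class TestYRandomization:
    def test_synthetic_calibration_passes(self, noisy_calibration):
        res = y_randomization(
            noisy_calibration.absorbance, noisy_calibration.concentrations,
            _PLSFactory(max_lv=3), n_permutations=20, seed=7)
        assert res["r_original"] > 0.99
        assert res["mean_permuted_r"] < 0.5
        assert res["passed"]

    def test_constant_y_rejected(self):
        x = np.random.default_rng(8).normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            y_randomization(x, np.full(10, 3.0), _PLSFactory(), n_permutations=10)

    def test_minimum_permutations(self, noisy_calibration):
        with pytest.raises(ValueError):
            y_randomization(noisy_calibration.absorbance,
                            noisy_calibration.concentrations, _PLSFactory(),
                            n_permutations=5)


class TestApplicabilityDomain:
    def test_leverage_sum_is_p_plus_1(self, noisy_pls, noisy_calibration):
        resid = (noisy_pls.predict(noisy_calibration.absorbance)
                 - noisy_calibration.concentrations)[:, 0]
        rep = applicability_domain(noisy_pls.scores, resid)
        assert rep.leverage.sum() == pytest.approx(noisy_pls.n_lv + 1, abs=1e-8)

    def test_h_star_formula(self, noisy_pls, noisy_calibration):
        resid = np.zeros(noisy_calibration.n_samples) + np.random.default_rng(0).normal(
            0, 0.1, noisy_calibration.n_samples)
        rep = applicability_domain(noisy_pls.scores, resid)
        n, p = noisy_pls.scores.shape
        assert rep.h_star == pytest.approx(3 * (p + 1) / n)

    def test_constructed_outlier_flagged(self, noisy_pls, noisy_calibration, space,
                                         library, grid):
        # a mixture far outside the calibration cloud: high leverage
        far = designs.DesignMatrix(space, np.array([[1.0, 1.0]]))
        sset = spectra_sim.trim_wavelengths(
            spectra_sim.simulate_mixtures(far, library, grid), 200, 335)
        out_scores = noisy_pls.transform(sset.absorbance * 5.0)  # 5x beyond range
        resid = np.zeros(1)
        rep = applicability_domain(noisy_pls.scores, np.random.default_rng(1).normal(
            0, 0.1, noisy_calibration.n_samples), out_scores, resid)
        assert rep.leverage[0] > rep.h_star
        assert not rep.in_domain[0]

    def test_calibration_points_in_domain(self, noisy_pls, noisy_calibration):
        resid = (noisy_pls.predict(noisy_calibration.absorbance)
                 - noisy_calibration.concentrations)[:, 0]
        rep = applicability_domain(noisy_pls.scores, resid)
        assert rep.in_domain.all()

    def test_equal_magnitude_residuals(self):
        # residuals of one magnitude, alternating sign: all standardized to +-1
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(24, 3)) * 0.1
        resid = np.resize([0.2, -0.2], 24)
        rep = applicability_domain(scores, resid)
        np.testing.assert_allclose(np.abs(rep.std_residual), 1.0, atol=1e-10)
        assert rep.in_domain.all()


class TestMethodComparison:
    # printed summary statistics: mean %R, SD, n=5 per group
    T_CASES = [
        ((95.99, 1.913, 5), (98.34, 1.354, 5), 2.242),
        ((97.87, 1.946, 5), (98.02, 1.520, 5), 0.136),
        ((99.46, 1.085, 5), (98.34, 1.354, 5), 1.443),
        ((99.87, 1.409, 5), (98.02, 1.520, 5), 1.996),
        ((97.46, 1.535, 5), (98.34, 1.354, 5), 0.961),
        ((99.42, 1.410, 5), (98.02, 1.520, 5), 1.510),
    ]

    @pytest.mark.parametrize("g1,g2,expected", T_CASES)
    def test_pooled_t_published_values(self, g1, g2, expected):
        rep = pooled_t_test(*g1, *g2)
        assert round(rep.statistic, 3) == pytest.approx(expected, abs=5e-4)
        assert rep.df == (8,)
        assert rep.critical_value == pytest.approx(2.306, abs=5e-4)
        assert rep.passed

    def test_t_symmetry(self):
        a = pooled_t_test(95.0, 2.0, 5, 98.0, 1.5, 5)
        b = pooled_t_test(98.0, 1.5, 5, 95.0, 2.0, 5)
        assert a.statistic == pytest.approx(b.statistic)

    def test_equal_means_t_zero(self):
        assert pooled_t_test(50.0, 1.0, 5, 50.0, 2.0, 5).statistic == 0.0

    def test_both_zero_sds_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 0.0, 5, 2.0, 0.0, 5)

    F_CASES = [
        ((1.913, 5), (1.354, 5), 1.996),
        ((1.946, 5), (1.520, 5), 1.639),
        ((1.354, 5), (1.085, 5), 1.557),   # reference/model orientation
        ((1.409, 5), (1.520, 5), 0.859),
        ((1.535, 5), (1.354, 5), 1.285),
        ((1.410, 5), (1.520, 5), 0.861),
    ]

    @pytest.mark.parametrize("num,den,expected", F_CASES)
    def test_variance_ratio_published_values(self, num, den, expected):
        rep = variance_ratio_f(*num, *den)
        assert round(rep.statistic, 3) == pytest.approx(expected, abs=5e-4)
        assert rep.df == (4, 4)
        assert rep.critical_value == pytest.approx(6.39, abs=5e-3)
        assert rep.passed

    def test_f_reciprocal_symmetry(self):
        a = variance_ratio_f(2.0, 6, 1.5, 8)
        b = variance_ratio_f(1.5, 8, 2.0, 6)
        assert a.statistic == pytest.approx(1 / b.statistic)
        assert a.df == (5, 7) and b.df == (7, 5)

    def test_equal_sds_f_one(self):
        assert variance_ratio_f(1.3, 5, 1.3, 5).statistic == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_f(1.0, 5, 0.0, 5)


class TestFriedman:
    def test_identical_orderings_hand_value(self):
        # 2 blocks x 3 treatments, same ranking: sum R_j^2 = 56 -> chi2 = 4
        scores = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        res = friedman_test(scores)
        assert res["chi2"] == pytest.approx(4.0)
        assert res["df"] == 2

    def test_all_equal_chi2_zero(self):
        with pytest.warns(UserWarning, match="tied"):
            res = friedman_test(np.ones((3, 3)))
        assert res["chi2"] == pytest.approx(0.0)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(10, 3))
        res = friedman_test(scores)
        ref = stats.friedmanchisquare(*[scores[:, j] for j in range(3)])
        assert res["chi2"] == pytest.approx(ref.statistic, abs=1e-10)
        assert res["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_brute_force_rank_sum_formula(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=(10, 3))
        b, k = scores.shape
        rj = np.array([stats.rankdata(row) for row in scores]).sum(axis=0)
        brute = 12.0 / (b * k * (k + 1)) * (rj**2).sum() - 3 * b * (k + 1)
        assert friedman_test(scores)["chi2"] == pytest.approx(brute, abs=1e-10)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.ones((3, 1)))


class TestSamplerRankingEndToEnd:
    def test_structured_samplers_not_worse_than_mc(self, space, library, grid):
        """Noise-dominated replicates: LHS/Sobol RMSEP never significantly above MC."""
        rmsep = {"mc": [], "lhs": [], "sobol": []}
        cal_design = designs.factorial_calibration_design(space)
        for rep in range(10):
            cal = spectra_sim.trim_wavelengths(spectra_sim.simulate_mixtures(
                cal_design, library, grid, spectra_sim.NoiseModel(seed=rep)), 200, 335)
            lv, _ = calibration.select_lv_loocv(cal.absorbance, cal.concentrations, 5)
            model = calibration.fit_pls(cal.absorbance, cal.concentrations, lv)
            vdesigns = {
                "mc": designs.monte_carlo_design(13, space, 100 + rep),
                "lhs": designs.latin_hypercube_design(13, space, 200 + rep),
                "sobol": designs.sobol_design(13, space),
            }
            for name, vd in vdesigns.items():
                vs = spectra_sim.trim_wavelengths(spectra_sim.simulate_mixtures(
                    vd, library, grid, spectra_sim.NoiseModel(seed=300 + rep)), 200, 335)
                pred = model.predict(vs.absorbance)
                rmsep[name].append(
                    float(np.sqrt(np.mean((pred - vs.concentrations) ** 2))))
        # structured samplers are never significantly worse than MC
        for name in ("lhs", "sobol"):
            t = stats.ttest_rel(rmsep[name], rmsep["mc"], alternative="greater")
            assert t.pvalue > 0.05, name
        # noise dominates: Friedman over replicates should not scream
        res = friedman_test(np.column_stack([rmsep["mc"], rmsep["lhs"], rmsep["sobol"]]))
        assert res["p_value"] > 1e-4
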