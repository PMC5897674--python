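import numpy as np
import pytest
from scipy import integrate, stats

from spiba.gamma_platform import (
    GammaFit,
    PlanePoint,
    compare_candidate_fits,
    condition_shift_report,
    fd_histogram,
    fit_gamma_mle,
    gamma_loglik,
    gamma_moments,
    gamma_pdf,
    ks_two_sample,
    ks_vs_normal,
    loglog_power_fit,
)
from spiba.signal_core import InputError, SpibaError


class TestFDHistogram:
    def test_uniform_bin_width_formula(self, rng):
        x = rng.uniform(0, 1, 1000)
        out = fd_histogram(x)
        iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
        expect = 2 * iqr * 1000 ** (-1 / 3)
        widths = np.diff(out["edges"])
        np.testing.assert_allclose(widths[:-1], expect, rtol=1e-9)

    def test_counts_conserved(self, rng):
        for n in (4, 57, 640):
            x = rng.gamma(2.0, 1.0, n)
            assert fd_histogram(x)["counts"].sum() == n

    def test_constant_sample_two_bin_fallback(self):
        with pytest.warns(UserWarning, match="zero IQR"):
            out = fd_histogram(np.full(50, 3.0))
        assert len(out["counts"]) == 2
        assert out["counts"].sum() == 50
        assert out["counts"].max() == 50

    def test_needs_four_samples(self):
        with pytest.raises(InputError):
            fd_histogram(np.array([1.0, 2.0, 3.0]))


class TestGammaMLE:
    def test_exponential_boundary_shape_near_one(self):
        x = np.random.default_rng(1).exponential(1.0, 100_000)
        fit = fit_gamma_mle(x)
        # asymptotic SE of the shape at a=1 is ~0.004 here
        assert fit.shape == pytest.approx(1.0, abs=0.02)

    def test_parameter_recovery_within_ci(self):
        x = np.random.default_rng(7).gamma(2.0, 0.5, 10_000)
        fit = fit_gamma_mle(x)
        assert fit.ci_shape[0] <= 2.0 <= fit.ci_shape[1]
        assert fit.ci_scale[0] <= 0.5 <= fit.ci_scale[1]

    def test_local_optimality_of_loglik(self, rng):
        x = rng.gamma(3.0, 0.2, 2000)
        fit = fit_gamma_mle(x)
        best = gamma_loglik(x, fit.shape, fit.scale)
        d = 1e-3
        for da, db in ((d, 0), (-d, 0), (0, d), (0, -d), (d, d), (-d, -d)):
            assert best >= gamma_loglik(x, fit.shape + da, fit.scale + db)

    def test_matches_scipy_mle(self, rng):
        """Independent cross-check against the scipy fitter."""
        x = rng.gamma(2.5, 0.08, 5000)
        fit = fit_gamma_mle(x)
        a_ref, _, b_ref = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a_ref, rel=1e-6)
        assert fit.scale == pytest.approx(b_ref, rel=1e-6)

    def test_scale_equivariance_exact(self, rng):
        x = rng.gamma(2.0, 1.0, 500)
        f1 = fit_gamma_mle(x)
        f2 = fit_gamma_mle(3.7 * x)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-9)
        assert f2.scale == pytest.approx(3.7 * f1.scale, rel=1e-9)

    def test_bias_shrinks_with_sample_size(self):
        biases = []
        for n, reps in ((100, 2000), (1000, 2000), (10000, 400)):
            rng = np.random.default_rng(11)
            est = [fit_gamma_mle(rng.gamma(2.0, 0.5, n)).shape
                   for _ in range(reps)]
            biases.append(abs(np.mean(est) - 2.0))
        assert biases[0] > biases[1] > biases[2]

    def test_nonpositive_samples_rejected(self, rng):
        x = rng.gamma(2.0, 1.0, 100)
        x[3] = 0.0
        with pytest.raises(InputError):
            fit_gamma_mle(x)

    def test_hard_floor_on_n(self):
        with pytest.raises(InputError):
            fit_gamma_mle(np.ones(5) + np.arange(5) * 0.1)

    def test_small_sample_warns_loose_ci(self, rng):
        with pytest.warns(UserWarning, match="tight"):
            fit_gamma_mle(rng.gamma(2, 1, 50))


class TestMomentsAndPdf:
    def _fit(self, a, b):
        return GammaFit(shape=a, scale=b, ci_shape=(a * 0.9, a * 1.1),
                        ci_scale=(b * 0.9, b * 1.1), conf_level=0.95,
                        n=100, loglik=0.0)

    def test_mean_variance_nsr_identity(self):
        m = gamma_moments(self._fit(4.0, 0.25))
        assert m.mean == pytest.approx(1.0)
        assert m.variance == pytest.approx(0.25)
        assert m.nsr == 0.25

    def test_nsr_equals_scale_exactly_for_any_fit(self, rng):
        for _ in range(10):
            x = rng.gamma(rng.uniform(0.5, 10), rng.uniform(0.01, 5), 500)
            fit = fit_gamma_mle(x)
            assert gamma_moments(fit).nsr == fit.scale  # exact, no tolerance

    def test_skewness_closed_form(self):
        assert gamma_moments(self._fit(4.0, 1.0)).skewness == pytest.approx(1.0)

    def test_exponential_case_moments(self):
        m = gamma_moments(self._fit(1.0, 1.0))
        assert m.skewness == pytest.approx(2.0)
        assert m.kurtosis == pytest.approx(9.0)

    def test_pdf_exponential_at_origin(self):
        assert gamma_pdf(0.0, 1.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("a", [0.5, 1.0, 5.0])
    def test_pdf_normalization_by_quadrature(self, a):
        b = 0.7
        val, _ = integrate.quad(lambda x: gamma_pdf(x, a, b), 0, 50 * b,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_mode_closed_form(self):
        a, b = 3.0, 0.4
        xs = np.linspace(1e-6, 10 * b, 20001)
        assert xs[np.argmax(gamma_pdf(xs, a, b))] == pytest.approx(
            (a - 1) * b, abs=1e-3
        )

    def test_pdf_matches_scipy(self, rng):
        xs = rng.uniform(0.01, 5, 50)
        np.testing.assert_allclose(
            gamma_pdf(xs, 2.3, 0.6), stats.gamma.pdf(xs, 2.3, scale=0.6),
            rtol=1e-12,
        )


class TestPowerLawFit:
    def _points(self, shapes, scales):
        return [
            PlanePoint(participant_id=f"p{i}", condition="c", kind="AM",
                       shape=a, scale=b, ci_shape=(a, a), ci_scale=(b, b))
            for i, (a, b) in enumerate(zip(shapes, scales))
        ]

    def test_constant_mean_gives_slope_minus_one_exactly(self):
        shapes = np.array([1.0, 2.0, 3.5, 5.0, 8.0])
        mu = 0.76
        fit = loglog_power_fit(self._points(shapes, mu / shapes))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(mu), abs=1e-12)

    def test_base10_option(self):
        shapes = np.array([1.0, 2.0, 4.0])
        fit = loglog_power_fit(self._points(shapes, 0.5 / shapes),
                               log_base="base10")
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log10(0.5), abs=1e-12)

    def test_replicated_point_degenerate(self):
        pts = self._points([2.0] * 5, [0.3] * 5)
        with pytest.raises(SpibaError):
            loglog_power_fit(pts)

    def test_needs_three_points(self):
        with pytest.raises(InputError):
            loglog_power_fit(self._points([1.0, 2.0], [1.0, 0.5]))

    def test_perturbed_means_slope_near_minus_one(self, rng):
        shapes = rng.uniform(1.0, 6.0, 30)
        mus = 0.5 * (1 + rng.uniform(-0.05, 0.05, 30))
        fit = loglog_power_fit(self._points(shapes, mus / shapes))
        assert -1.05 <= fit.slope <= -0.95


class TestKS:
    def test_identical_samples(self, rng):
        x = rng.gamma(2, 1, 100)
        res = ks_two_sample(x, x)
        assert res["D"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_disjoint_supports_maximal_d(self, rng):
        x = rng.gamma(2, 1, 200)
        res = ks_two_sample(x, x + 10)
        assert res["D"] == 1.0

    def test_two_sample_matches_ecdf_oracle(self, rng):
        x = rng.gamma(2, 1, 150)
        y = rng.gamma(3, 0.8, 120)
        pooled = np.sort(np.concatenate([x, y]))
        ecdf_x = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
        ecdf_y = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
        assert ks_two_sample(x, y)["D"] == pytest.approx(
            np.max(np.abs(ecdf_x - ecdf_y)), abs=1e-12
        )

    def test_skewed_gamma_departs_from_normality(self):
        x = np.random.default_rng(0).gamma(2.0, 0.1, 500)
        assert ks_vs_normal(x)["p"] < 0.01

    def test_gaussian_limit_of_gamma_not_rejected(self):
        x = np.random.default_rng(3).gamma(1000.0, 0.001, 500)
        assert ks_vs_normal(x)["p"] > 0.05

    def test_normality_d_matches_sup_oracle(self, rng):
        x = rng.gamma(2.0, 0.3, 180)
        m, s = x.mean(), x.std(ddof=1)
        xs = np.sort(x)
        n = len(x)
        cdf = stats.norm.cdf(xs, m, s)
        d_oracle = max(np.max(np.arange(1, n + 1) / n - cdf),
                       np.max(cdf - np.arange(n) / n))
        assert ks_vs_normal(x)["D"] == pytest.approx(d_oracle, abs=1e-12)

    def test_monte_carlo_p_available(self, rng):
        x = rng.gamma(2.0, 0.1, 100)
        res = ks_vs_normal(x, monte_carlo=True, n_mc=200, rng=rng)
        assert 0 <= res["p_mc"] <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            ks_vs_normal(np.full(50, 2.0))


class TestConditionShiftReport:
    def _fits_and_samples(self, laws, n=500, seed=0):
        rng = np.random.default_rng(seed)
        fits, samples = {}, {}
        for cond, (a, b) in laws.items():
            x = rng.gamma(a, b, n)
            samples[cond] = x
            fits[cond] = fit_gamma_mle(x)
        return fits, samples

    def test_null_case_not_significant(self):
        fits, samples = self._fits_and_samples(
            {"c1": (2.0, 0.1), "c2": (2.0, 0.1)}, seed=5
        )
        rep = condition_shift_report(fits, samples)
        assert rep["pairwise_ks"][0]["p"] > 0.05

    def test_separated_conditions_significant(self):
        fits, samples = self._fits_and_samples(
            {"low": (2.0, 0.1), "high": (4.0, 0.1)}, seed=6
        )
        rep = condition_shift_report(fits, samples)
        assert rep["pairwise_ks"][0]["p"] < 0.01
        assert rep["pairwise_ks"][0]["p_bh"] < 0.01

    def test_report_schema_one_plane_point_per_condition(self):
        laws = {"a": (2.0, 0.1), "b": (3.0, 0.2), "c": (4.0, 0.05)}
        fits, samples = self._fits_and_samples(laws, seed=7)
        rep = condition_shift_report(fits, samples,
                                     condition_order=list(laws))
        assert set(rep["plane_points"]) == set(laws)
        assert set(rep["moments"]) == set(laws)
        assert len(rep["pairwise_ks"]) == 3
        assert rep["arrows"] == [("a", "b"), ("b", "c")]

    def test_needs_two_conditions(self):
        fits, samples = self._fits_and_samples({"only": (2.0, 0.1)})
        with pytest.raises(InputError):
            condition_shift_report(fits, samples)


class TestCandidateComparison:
    def test_gamma_data_prefers_gamma(self):
        x = np.random.default_rng(2).gamma(2.0, 0.1, 2000)
        lls = compare_candidate_fits(x)
        assert set(lls) == {"gamma", "exponential", "lognormal", "normal"}
        assert lls["gamma"] > lls["exponential"]
        assert lls["gamma"] > lls["normal"]
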