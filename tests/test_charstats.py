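import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, xlogy

from clonodiverge.charstats import (
    divergence_test,
    fit_glm,
    strain_profile,
    summarize_tests,
)
from clonodiverge.data_io import ValidationError
from conftest import make_table


def poisson_nll(beta, y, X):
    eta = X @ beta
    return float(np.sum(np.exp(eta)) - y @ eta)


def binomial_nll(beta, y, X):
    eta = X @ beta
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


class TestFitGLM:
    def test_poisson_intercept_is_log_sample_mean(self):
        f = fit_glm([2, 4, 6], np.ones((3, 1)), "poisson")
        assert f.converged
        assert f.coefficients[0] == pytest.approx(np.log(4.0), abs=1e-9)
        assert f.fitted[0] == pytest.approx(4.0, abs=1e-9)

    def test_binomial_intercept_is_logit_sample_proportion(self):
        f = fit_glm([1, 1, 0, 0], np.ones((4, 1)), "binomial")
        assert f.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert expit(f.coefficients[0]) == pytest.approx(0.5)

    def test_two_group_poisson_matches_direct_likelihood_optimum(self):
        y = np.array([1.0, 3.0, 10.0, 14.0])
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        f = fit_glm(y, X, "poisson")
        np.testing.assert_allclose(np.exp(f.coefficients), [2.0, 12.0], atol=1e-8)
        res = minimize(poisson_nll, np.zeros(2), args=(y, X), method="BFGS")
        dev_direct = 2.0 * (res.fun - poisson_nll(np.log(np.maximum(y, 1e-12)), y, np.eye(4)))
        # deviance against the saturated model, from the independent optimizer
        sat = float(np.sum(xlogy(y, y) - y))
        assert f.deviance == pytest.approx(2.0 * (res.fun + sat), abs=1e-6)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_matches_generic_numerical_maximizer(self, family, rng):
        """IRLS deviance equals a brute-force likelihood optimum (20 instances)."""
        nll = binomial_nll if family == "binomial" else poisson_nll
        for _ in range(20):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(8, 25))
            g = rng.integers(0, k, size=n)
            X = np.zeros((n, k))
            X[np.arange(n), g] = 1.0
            if family == "binomial":
                y = rng.integers(0, 2, size=n).astype(float)
                if len(np.unique(y)) < 2:
                    y[0] = 1 - y[0]
            else:
                y = rng.poisson(4.0, size=n).astype(float)
            f = fit_glm(y, X, family)
            res = minimize(nll, np.zeros(k), args=(y, X), method="L-BFGS-B")
            # IRLS reaches the same (negative log-) likelihood optimum;
            # a 1e-6 deviance gap is a 5e-7 gap here
            assert nll(f.coefficients, y, X) <= res.fun + 5e-7

    def test_saturated_model_deviance_is_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        f = fit_glm(y, np.eye(4), "binomial")
        assert f.deviance == pytest.approx(0.0, abs=1e-8)
        yp = np.array([0.0, 3.0, 7.0])
        fp = fit_glm(yp, np.eye(3), "poisson")
        assert fp.deviance == pytest.approx(0.0, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            fit_glm([0, 2], np.ones((2, 1)), "binomial")
        with pytest.raises(ValidationError):
            fit_glm([1.5], np.ones((1, 1)), "poisson")
        with pytest.raises(ValidationError):
            fit_glm([1, 0], np.ones((3, 1)), "binomial")


class TestDivergenceTest:
    def test_three_strain_binary_equals_closed_form_lr(self, binomial_spec):
        t = make_table({"X": [1, 1, 1, 1], "Y": [0, 0, 0, 0], "Z": [1, 0, 1, 0]},
                       binomial_spec)
        res = divergence_test(t, binomial_spec)
        # exhaustive per-strain MLE: saturated strains contribute 0,
        # the mixed strain 4*log(1/2); null: 12 obs at p = 1/2
        ll_alt = 4 * np.log(0.5)
        ll_null = 12 * np.log(0.5)
        assert res.chi_square == pytest.approx(2 * (ll_alt - ll_null), abs=1e-6)
        assert res.df == 2
        assert res.significant

    def test_constant_character_gives_zero_chi2_p_one(self, poisson_spec):
        t = make_table({"X": [5, 5], "Y": [5, 5, 5]}, poisson_spec)
        res = divergence_test(t, poisson_spec)
        assert res.chi_square == 0.0 and res.p_value == 1.0
        assert not res.significant

    def test_df_is_strains_with_data_minus_one(self, binomial_spec):
        t = make_table({s: [0, 1, 1] for s in "ABCDEFGHIJKL"}, binomial_spec)
        assert divergence_test(t, binomial_spec).df == 11

    def test_count_character_binarized_before_testing(self, count_binomial_spec):
        # raw counts cross the <=3 / >=4 boundary: after grouping, X is all
        # state 0 and Y all state 1, so the test sees perfect divergence
        t = make_table({"X": [2, 3, 3, 2], "Y": [4, 5, 4, 4]}, count_binomial_spec)
        res = divergence_test(t, count_binomial_spec)
        assert res.family == "binomial"
        assert res.p_value < 0.01

    def test_fewer_than_two_strains_is_an_error(self, binomial_spec):
        t = make_table({"X": [0, 1]}, binomial_spec)
        with pytest.raises(ValidationError, match="2 strains"):
            divergence_test(t, binomial_spec)

    def test_invariant_under_strain_relabelling(self, poisson_spec, rng):
        vals = {s: rng.poisson(6, size=8) for s in "ABCD"}
        t1 = make_table(vals, poisson_spec)
        t2 = make_table({"Z" + s: v for s, v in vals.items()}, poisson_spec)
        a, b = divergence_test(t1, poisson_spec), divergence_test(t2, poisson_spec)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-9)

    def test_invariant_under_binary_encoding_flip(self, binomial_spec, rng):
        vals = {s: rng.integers(0, 2, size=10) for s in "ABCD"}
        t1 = make_table(vals, binomial_spec)
        t2 = make_table({s: 1 - v for s, v in vals.items()}, binomial_spec)
        a, b = divergence_test(t1, binomial_spec), divergence_test(t2, binomial_spec)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-7)


class TestStrainProfile:
    def test_balanced_binomial_cell(self, binomial_spec):
        t = make_table({"X": [1] * 5 + [0] * 5}, binomial_spec)
        p = strain_profile(t, binomial_spec).per_strain.loc["X"]
        assert p["mean"] == 0.5
        # symmetric on the logit scale
        lo, hi = np.log(p.ci_low / (1 - p.ci_low)), np.log(p.ci_high / (1 - p.ci_high))
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_poisson_cell_interval_from_fisher_information(self, poisson_spec):
        t = make_table({"X": [3, 5, 4, 4]}, poisson_spec)
        p = strain_profile(t, poisson_spec).per_strain.loc["X"]
        assert p["mean"] == 4.0
        se = np.sqrt(1.0 / 16.0)  # 1 / sqrt(n * lambda-hat)
        assert p.ci_low == pytest.approx(np.exp(np.log(4) - 1.96 * se), rel=1e-6)
        assert p.ci_high == pytest.approx(np.exp(np.log(4) + 1.96 * se), rel=1e-6)

    def test_boundary_cell_flagged_degenerate(self, binomial_spec):
        t = make_table({"X": [0] * 8, "Y": [0, 1]}, binomial_spec)
        ps = strain_profile(t, binomial_spec).per_strain
        assert ps.loc["X", "mean"] == 0.0
        assert ps.loc["X", "degenerate"] and not ps.loc["Y", "degenerate"]
        assert np.isnan(ps.loc["X", "ci_low"])


class TestSummarize:
    def test_threshold_count(self, binomial_spec):
        from clonodiverge.charstats import DivergenceTest

        tests = [
            DivergenceTest("01", "binomial", 1, 1, p, 2, 10, p < 0.05)
            for p in (0.01, 0.2, 0.003)
        ]
        assert summarize_tests(tests).n_significant == 2

    def test_empty_list(self):
        s = summarize_tests([])
        assert s.n_significant == 0 and len(s.table) == 0
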