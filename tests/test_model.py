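"""Model-engine tests: linear predictor, category probabilities, likelihood
and prior oracles, gradient exactness, sampler correctness, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

import arviz as az

from ordmm import cohort as sc
from ordmm import data as dio
from ordmm import diagnostics as diag
from ordmm import model as mdl
from ordmm.mcmc import nuts_sample


def make_data(y, counts, membership, student_idx, n_courses, students=None):
    if students is None:
        students = [f"s{i}" for i in range(int(np.max(student_idx)) + 1)]
    return dio.ModelData(
        y=np.asarray(y), counts=np.asarray(counts),
        membership=np.asarray(membership, dtype=float),
        student_idx=np.asarray(student_idx, dtype=int),
        students=students, n_courses=n_courses, skill=1)


class TestLinearPredictor:
    def test_worked_arithmetic(self):
        # beta=0.2, N=2, followed courses with u = (0.1, -0.05), theta=0.3
        data = make_data([2], [2], [[1, 1, 0]], [0], 3)
        eta = mdl.linear_predictor(0.2, [0.1, -0.05, 0.4], [0.3], data)
        assert eta[0] == pytest.approx(0.75)

    def test_empty_membership_and_zero_theta(self):
        data = make_data([1], [0], [[0, 0, 0]], [0], 3)
        eta = mdl.linear_predictor(0.5, [1.0, 1.0, 1.0], [0.0], data)
        assert eta[0] == 0.0

    def test_four_course_student_expands_to_beta_times_four_plus_us(self):
        u = np.array([0.3, -0.1, 0.2, 0.05, 0.0])
        data = make_data([3], [4], [[1, 1, 1, 1, 0]], [0], 5)
        eta = mdl.linear_predictor(0.2, u, [0.0], data)
        assert eta[0] == pytest.approx(0.2 * 4 + u[:4].sum())


class TestCategoryProbs:
    def test_unit_thresholds_at_zero_eta(self):
        p = mdl.category_probs(np.array([-1.0, 0.0, 1.0]), 0.0)
        s = expit(1.0)
        expected = [1 - s, s - 0.5, s - 0.5, 1 - s]
        np.testing.assert_allclose(p, expected, atol=1e-10)
        np.testing.assert_allclose(p, [0.2689, 0.2311, 0.2311, 0.2689], atol=1e-4)

    def test_symmetric_thresholds_are_uniform(self):
        p = mdl.category_probs(np.array([-np.log(3), 0.0, np.log(3)]), 0.0)
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_large_eta_concentrates_on_top_category(self):
        p = mdl.category_probs(np.array([-1.0, 0.0, 1.0]), 50.0)
        assert p[3] > 1 - 1e-10

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            mdl.category_probs(np.array([1.0, 0.0, 2.0]), 0.0)

    @given(st.floats(-8, 8), st.floats(-3, 1), st.floats(0.05, 3),
           st.floats(0.05, 3))
    @settings(max_examples=200, deadline=None)
    def test_probabilities_nonnegative_and_sum_to_one(self, eta, a1, gap2, gap3):
        thr = np.array([a1, a1 + gap2, a1 + gap2 + gap3])
        p = mdl.category_probs(thr, eta)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-4, 4), st.floats(0.1, 2))
    @settings(max_examples=100, deadline=None)
    def test_exceedance_strictly_increasing_in_eta(self, eta, step):
        thr = np.array([-0.5, 1.0, 2.5])
        p_lo = mdl.category_probs(thr, eta)
        p_hi = mdl.category_probs(thr, eta + step)
        for k in range(3):
            assert p_hi[k + 1:].sum() > p_lo[k + 1:].sum()


class TestLogLikelihood:
    def test_single_row_midpoint(self):
        data = make_data([1], [0], [[0]], [0], 1)
        params = mdl.ModelParams(beta=0.0, thresholds=np.array([0.0, 1.0, 2.0]),
                                 sigma_c=1.0, sigma_s=1.0,
                                 u=np.zeros(1), theta=np.zeros(1))
        assert mdl.log_likelihood(params, data) == pytest.approx(np.log(0.5))

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n, C, S = 10, 4, 3
            data = make_data(
                rng.integers(1, 5, n), rng.integers(0, 4, n),
                rng.integers(0, 2, (n, C)), rng.integers(0, S, n), C,
                students=[f"s{i}" for i in range(S)])
            params = mdl.ModelParams(
                beta=rng.normal(0, 0.3),
                thresholds=np.sort(rng.normal(0, 1.5, 3)) + [0, 0.1, 0.2],
                sigma_c=0.2, sigma_s=0.4,
                u=rng.normal(0, 0.2, C), theta=rng.normal(0, 0.4, S))
            eta = (params.beta * data.counts + data.membership @ params.u
                   + params.theta[data.student_idx])
            brute = sum(
                np.log(mdl.category_probs(params.thresholds, e)[y - 1])
                for e, y in zip(eta, data.y))
            assert mdl.log_likelihood(params, data) == pytest.approx(
                brute, abs=1e-10)

    def test_duplicated_row_doubles_contribution(self):
        base = make_data([2], [1], [[1, 0]], [0], 2)
        double = make_data([2, 2], [1, 1], [[1, 0], [1, 0]], [0, 0], 2)
        params = mdl.ModelParams(beta=0.3, thresholds=np.array([-1.0, 0.5, 2.0]),
                                 sigma_c=1.0, sigma_s=1.0,
                                 u=np.array([0.2, 0.0]), theta=np.array([0.1]))
        assert mdl.log_likelihood(params, double) == pytest.approx(
            2 * mdl.log_likelihood(params, base))


class TestLogPrior:
    def _params(self, **kw):
        defaults = dict(beta=0.4, thresholds=np.array([-0.5, 1.0, 2.5]),
                        sigma_c=0.15, sigma_s=0.35,
                        u=np.zeros(4), theta=np.zeros(6))
        defaults.update(kw)
        return mdl.ModelParams(**defaults)

    def test_flat_beta_contributes_nothing(self):
        assert mdl.log_prior(self._params(beta=0.0)) == pytest.approx(
            mdl.log_prior(self._params(beta=57.0)))

    def test_zero_effects_match_closed_form_normal_density(self):
        lp0 = mdl.log_prior(self._params(u=np.zeros(4)))
        lp1 = mdl.log_prior(self._params(u=np.full(4, 0.1)))
        expected_diff = 4 * (stats.norm.logpdf(0.0, scale=0.15)
                             - stats.norm.logpdf(0.1, scale=0.15))
        assert lp0 - lp1 == pytest.approx(expected_diff, abs=1e-10)

    def test_negative_sigma_outside_support(self):
        assert mdl.log_prior(self._params(sigma_c=-0.1)) == -np.inf

    def test_t_density_helper_matches_scipy(self):
        x = np.array([-3.0, -0.4, 0.0, 1.7, 6.0])
        np.testing.assert_allclose(
            mdl._t_logpdf(x, 3.0, 2.5), stats.t.logpdf(x, 3, scale=2.5),
            atol=1e-12)

    def test_half_t_mass_doubles_positive_density(self):
        p = self._params()
        lp = mdl.log_prior(p)
        manual = (stats.t.logpdf(p.thresholds, 3, scale=2.5).sum()
                  + 2 * np.log(2)
                  + stats.t.logpdf(p.sigma_c, 3, scale=2.5)
                  + stats.t.logpdf(p.sigma_s, 3, scale=2.5)
                  + stats.norm.logpdf(p.u, scale=p.sigma_c).sum()
                  + stats.norm.logpdf(p.theta, scale=p.sigma_s).sum())
        assert lp == pytest.approx(manual, abs=1e-10)


class TestSamplerTarget:
    def test_gradient_matches_finite_differences(self, complete_cohort):
        data = dio.to_model_inputs(complete_cohort.dataset, 2)
        lg = mdl._make_logp_grad(data, mdl.Priors())
        rng = np.random.default_rng(5)
        x = mdl._initial_point(data, rng)
        _, g = lg(x)
        h = 1e-6
        for i in rng.choice(len(x), 15, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (lg(xp)[0] - lg(xm)[0]) / (2 * h)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_course_label_symmetry_of_log_posterior(self, complete_cohort):
        # swapping two course labels (data columns and u entries together)
        # leaves the joint density unchanged, so the beta and sigma
        # posteriors are invariant to course labelling
        data = dio.to_model_inputs(complete_cohort.dataset, 1)
        perm = np.arange(data.n_courses)
        perm[[0, 3]] = perm[[3, 0]]
        data_p = dio.ModelData(
            y=data.y, counts=data.counts,
            membership=data.membership[:, perm],
            student_idx=data.student_idx, students=data.students,
            n_courses=data.n_courses, skill=1)
        lg = mdl._make_logp_grad(data, mdl.Priors())
        lg_p = mdl._make_logp_grad(data_p, mdl.Priors())
        rng = np.random.default_rng(6)
        x = mdl._initial_point(data, rng)
        x_p = x.copy()
        x_p[6:6 + data.n_courses] = x[6:6 + data.n_courses][perm]
        assert lg(x)[0] == pytest.approx(lg_p(x_p)[0], abs=1e-10)


class TestMcmcEngine:
    def test_recovers_correlated_gaussian(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def logp_grad(x):
            return -0.5 * x @ prec @ x, -prec @ x

        rng = np.random.default_rng(8)
        res = nuts_sample(logp_grad, np.zeros(2), 500, 2000, rng)
        mean = res.draws.mean(axis=0)
        emp_cov = np.cov(res.draws.T)
        np.testing.assert_allclose(mean, 0.0, atol=0.15)
        np.testing.assert_allclose(emp_cov, cov, atol=0.35)

    def test_seeded_determinism(self):
        def logp_grad(x):
            return -0.5 * x @ x, -x

        a = nuts_sample(logp_grad, np.zeros(3), 100, 100,
                        np.random.default_rng(9))
        b = nuts_sample(logp_grad, np.zeros(3), 100, 100,
                        np.random.default_rng(9))
        np.testing.assert_array_equal(a.draws, b.draws)


class TestMcmcConfig:
    def test_full_scale_preset_retains_sixteen_thousand_draws(self):
        cfg = mdl.McmcConfig.full_scale()
        assert cfg.n_chains == 4
        assert cfg.n_iter == 5000
        assert cfg.n_warmup == 1000
        assert cfg.n_retained == 16_000

    def test_warmup_must_precede_iterations(self):
        with pytest.raises(ValueError):
            mdl.McmcConfig(n_chains=2, n_iter=100, n_warmup=100)


class TestSplitRhat:
    def test_identical_iid_chains_round_to_one(self):
        rng = np.random.default_rng(10)
        draws = rng.standard_normal((4, 2000))
        assert round(diag.split_rhat(draws), 1) == 1.0

    def test_separated_chain_means_blow_up(self):
        rng = np.random.default_rng(11)
        draws = rng.standard_normal((2, 500))
        draws[1] += 10.0
        assert diag.split_rhat(draws) > 1.5

    def test_constant_parameter_defined_not_nan(self):
        draws = np.ones((4, 100))
        assert diag.split_rhat(draws) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            diag.split_rhat(np.zeros((1, 100)))

    def test_agrees_with_reference_rank_normalized_implementation(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            draws = rng.standard_normal((4, 250)) + rng.normal(
                0, 0.3, size=(4, 1))
            ours = diag.split_rhat(draws)
            ref = float(az.rhat(az.convert_to_dataset(draws))["x"].values)
            assert ours == pytest.approx(ref, abs=1e-6)


class TestFit:
    def test_fit_reports_all_parameters_and_mixes_on_small_data(
            self, complete_cohort, small_fit):
        data = dio.to_model_inputs(complete_cohort.dataset, 1)
        fit = small_fit
        expected = 6 + data.n_courses + data.n_students
        assert len(fit.summary) == expected
        assert fit.summary["rhat"].notna().all()
        # threshold draws ordered within every draw
        alpha = fit.draws["alpha"]
        assert (np.diff(alpha, axis=-1) > 0).all()
        assert (fit.draws["sigma_c"] > 0).all()

    def test_empty_data_rejected(self):
        data = make_data(np.empty(0, int), np.empty(0, int),
                         np.empty((0, 2)), np.empty(0, int), 2, students=[])
        with pytest.raises(ValueError):
            mdl.fit(data)
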