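"""Generator tests: parameter draws, enrollment structure, score law,
missingness mechanics, and end-to-end determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ordmm import cohort as sc
from ordmm import data as dio


class TestDrawTrueParams:
    def test_zero_course_sd_gives_zero_effects(self, small_design):
        hyper = sc.EffectHyper(sigma_c=0.0)
        params = sc.draw_true_params(small_design, hyper, seed=1)
        assert np.all(params.u == 0.0)

    def test_student_effect_sd_matches_hyper_at_large_n(self):
        # LLN: sample SD of theta within 3 Monte-Carlo SEs of sigma_s
        design = sc.CohortDesign(
            cohorts=(sc.CohortSpec("A", 10_000, {0: 10_000}),), n_courses=12)
        params = sc.draw_true_params(design, sc.EffectHyper(sigma_s=0.35), seed=2)
        sd = params.theta[0].std(ddof=1)
        mc_se = 0.35 / np.sqrt(2 * (10_000 - 1))
        assert abs(sd - 0.35) < 3 * mc_se

    def test_defaults_sit_at_reported_effect_magnitudes(self):
        hyper = sc.EffectHyper()
        assert hyper.beta == pytest.approx(0.2, abs=0.1)
        assert hyper.sigma_c == pytest.approx(0.15, abs=0.1)
        assert hyper.sigma_s == pytest.approx(0.35, abs=0.1)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sc.EffectHyper(thresholds=(0.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            sc.TrueParams(
                thresholds=np.array([[1.0, 0.5, 2.0]]), beta=np.array([0.2]),
                sigma_c=np.array([0.1]), sigma_s=np.array([0.1]),
                u=np.zeros((1, 3)), theta=np.zeros((1, 2)))

    def test_shared_course_factor_correlates_effects_across_skills(self):
        design = sc.CohortDesign(
            cohorts=(sc.CohortSpec("A", 10, {0: 10}),), n_courses=500)
        params = sc.draw_true_params(
            design, sc.EffectHyper(shared_course_frac=0.6), seed=3)
        r = np.corrcoef(params.u[0], params.u[1])[0, 1]
        assert r > 0.3


class TestSimulateEnrollment:
    def test_stage0_has_no_courses(self, small_design):
        mem = sc.simulate_enrollment(small_design, seed=4)
        stage0 = mem[mem["stage"] == 0]
        assert (stage0["N"] == 0).all()
        w_cols = [c for c in mem.columns if c.startswith("W_")]
        assert not stage0[w_cols].to_numpy().any()

    def test_count_is_row_sum_and_capped(self, small_design):
        mem = sc.simulate_enrollment(small_design, seed=4)
        w_cols = [c for c in mem.columns if c.startswith("W_")]
        assert (mem["N"].to_numpy() == mem[w_cols].to_numpy().sum(axis=1)).all()
        assert mem["N"].max() <= small_design.max_courses

    def test_default_design_caps_at_eleven_courses(self):
        mem = sc.simulate_enrollment(sc.CohortDesign.default(), seed=5)
        assert mem["N"].max() <= 11

    def test_membership_cumulative_across_stages(self, small_design):
        mem = sc.simulate_enrollment(small_design, seed=4)
        w_cols = [c for c in mem.columns if c.startswith("W_")]
        for _, grp in mem.sort_values("stage").groupby("student_id"):
            W = grp[w_cols].to_numpy()
            assert (np.diff(W, axis=0) >= 0).all()

    def test_increments_exceeding_cap_rejected(self):
        with pytest.raises(ValueError):
            sc.CohortDesign(
                cohorts=(sc.CohortSpec("A", 5, {0: 5}),),
                n_courses=20, max_courses=8, stage_increments={1: 6, 2: 5})


class TestSimulateScores:
    @staticmethod
    def _flat_params(design, thresholds):
        I = 10
        n = sum(c.n_students for c in design.cohorts)
        ids = [str(i + 1) for i in range(n)]
        return sc.TrueParams(
            thresholds=np.tile(thresholds, (I, 1)), beta=np.zeros(I),
            sigma_c=np.zeros(I), sigma_s=np.zeros(I),
            u=np.zeros((I, design.n_courses)), theta=np.zeros((I, n)),
            student_ids=ids)

    def test_symmetric_thresholds_give_uniform_categories(self):
        design = sc.CohortDesign.small(2000, 8)
        params = self._flat_params(design, np.array([-np.log(3), 0.0, np.log(3)]))
        mem = sc.simulate_enrollment(design, seed=6)
        scored = sc.simulate_scores(params, mem, seed=6)
        counts = scored["sskill_1"].value_counts(normalize=True)
        for k in range(1, 5):
            assert counts[k] == pytest.approx(0.25, abs=0.02)

    def test_linear_predictor_arithmetic(self):
        # beta=0.2, N=2, u members (0.1, -0.05), theta=0.3 -> eta = 0.75
        eta = 0.2 * 2 + (0.1 - 0.05) + 0.3
        assert eta == pytest.approx(0.75)
        probs = sc.category_probabilities(np.array([-1.0, 0.0, 1.0]), np.array([0.75]))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empirical_frequencies_match_analytic_probabilities(self):
        # chi-square GOF against the cumulative-logit law on >= 10,000 draws
        design = sc.CohortDesign(
            cohorts=(sc.CohortSpec("A", 12_000, {0: 12_000}),), n_courses=5,
            max_courses=5, stage_increments={1: 3, 2: 2})
        params = self._flat_params(design, np.array([-0.5, 1.3, 3.0]))
        mem = sc.simulate_enrollment(design, seed=8)
        scored = sc.simulate_scores(params, mem, seed=8)
        observed = scored["sskill_3"].value_counts().reindex(range(1, 5)).to_numpy()
        expected = sc.category_probabilities(
            np.array([-0.5, 1.3, 3.0]), np.array([0.0]))[0] * len(scored)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=3)

    def test_mean_score_nondecreasing_in_count_under_positive_beta(self):
        design = sc.CohortDesign.small(3000, 10)
        n = 3000
        params = sc.TrueParams(
            thresholds=np.tile(np.array([-0.5, 1.3, 3.0]), (10, 1)),
            beta=np.full(10, 0.25), sigma_c=np.zeros(10), sigma_s=np.zeros(10),
            u=np.zeros((10, 10)), theta=np.zeros((10, n)),
            student_ids=[str(i + 1) for i in range(n)])
        mem = sc.simulate_enrollment(design, seed=9)
        scored = sc.simulate_scores(params, mem, seed=9)
        means = scored.groupby("N")["sskill_1"].mean()
        assert means.is_monotonic_increasing


class TestApplyMissingness:
    def test_block_rule_masks_whole_cohort_stage(self, small_cohort):
        block = small_cohort.dataset[
            (small_cohort.dataset["cohort"] == "A")
            & (small_cohort.dataset["stage"] == 0)]
        score_cols = [dio.skill_col(i) for i in range(1, 11)]
        assert block[score_cols].isna().all().all()

    def test_no_plan_is_identity(self, small_design):
        params = sc.draw_true_params(small_design, sc.EffectHyper(), seed=1)
        mem = sc.simulate_enrollment(small_design, seed=1)
        scored = sc.simulate_scores(params, mem, seed=1)
        masked, mask = sc.apply_missingness(scored, sc.MissingnessPlan(), seed=1)
        pd.testing.assert_frame_equal(masked, scored)
        assert not mask.to_numpy().any()

    def test_item_rate_within_binomial_error(self):
        design = sc.CohortDesign.small(400, 6)
        params = sc.draw_true_params(design, sc.EffectHyper(), seed=2)
        mem = sc.simulate_enrollment(design, seed=2)
        scored = sc.simulate_scores(params, mem, seed=2)
        _, mask = sc.apply_missingness(
            scored, sc.MissingnessPlan(item_rate=0.1), seed=2)
        n_cells = mask.size
        frac = mask.to_numpy().mean()
        se = np.sqrt(0.1 * 0.9 / n_cells)
        assert abs(frac - 0.1) < 3 * se

    def test_unknown_block_cohort_rejected(self, small_design):
        plan = sc.MissingnessPlan(blocks=(("nope", 0),))
        with pytest.raises(ValueError):
            plan.check_against(small_design)


class TestGenerate:
    def test_fixed_seed_reproduces_dataset(self, small_design):
        plan = sc.MissingnessPlan(blocks=(("A", 0),), item_rate=0.05)
        a = sc.generate(small_design, sc.EffectHyper(), plan, seed=11)
        b = sc.generate(small_design, sc.EffectHyper(), plan, seed=11)
        pd.testing.assert_frame_equal(a.dataset, b.dataset)
        assert np.array_equal(a.true_params.u, b.true_params.u)

    def test_default_design_reproduces_published_stage_counts(self):
        gen = sc.generate(seed=1)
        df = gen.dataset
        counts = df.groupby(["cohort", "stage"]).size()
        assert counts[("2023", 0)] == 339
        assert counts[("2022", 0)] == 194
        assert counts[("2021", 1)] == 250
        assert counts[("2022", 2)] == 141
        assert ("2023", 2) not in counts.index

    def test_generated_dataset_passes_validation(self, small_cohort):
        assert dio.validate(small_cohort.dataset) == []
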