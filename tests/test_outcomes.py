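"""Outcome summaries, POP-Q staging, paired comparison and the risk model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lccusum as lc
from conftest import make_series


def exam(Ba, Aa=None, TVL=8.0, timing="12-month"):
    if Aa is None:
        Aa = min(max(Ba, -3.0), 3.0)
    return lc.PopqExam(Aa=Aa, Ba=Ba, TVL=TVL, timing=timing)


def study_like_series(n=114, event_positions=(5, 15, 25, 40, 49), n_failures=6):
    """n cases, events at the given positions, postop exams with
    ``n_failures`` anatomic failures (the rest cured)."""
    records = []
    for i in range(1, n + 1):
        post = exam(0.0) if i <= n_failures else exam(-2.8)
        records.append(
            lc.CaseRecord(
                case_index=i,
                outcome=int(i in event_positions),
                popq_pre=exam(2.5, timing="preoperative"),
                popq_post=post,
            )
        )
    return lc.CaseSeries(records)


class TestSummarizeOutcomes:
    def test_study_counts_reproduce_printed_rates(self):
        series = study_like_series()
        out = lc.summarize_outcomes(series, window=49)
        assert out.n == 114 and out.events == 5
        assert round(100 * out.overall_rate, 1) == 4.4
        assert round(100 * out.first_window_rate, 1) == 10.2
        assert out.after_window_rate == 0.0
        assert out.cure_count == 108
        assert round(100 * out.cure_rate, 1) == 94.7

    def test_zero_events(self):
        out = lc.summarize_outcomes(make_series([0] * 20), window=10)
        assert out.events == 0 and out.overall_rate == 0.0
        assert (out.running_rate == 0).all()

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(lc.ValidationError):
            lc.summarize_outcomes(make_series([0, 1]), window=3)

    def test_incomplete_followup_excluded_from_rates(self):
        records = [
            lc.CaseRecord(case_index=i, outcome=i == 1, followup_complete=i <= 4)
            for i in range(1, 7)
        ]
        out = lc.summarize_outcomes(lc.CaseSeries(records), window=2)
        assert out.n == 4 and out.events == 1

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_running_rate_consistency(self, outcomes):
        out = lc.summarize_outcomes(make_series(outcomes), window=1)
        counts = out.running_rate * np.arange(1, len(outcomes) + 1)
        assert np.all(np.diff(counts) >= -1e-12)  # cumulative events monotone
        assert out.running_rate[-1] == pytest.approx(out.overall_rate)


class TestStageAnterior:
    @pytest.mark.parametrize(
        "Aa, Ba, TVL, stage",
        [
            (-3.0, -3.0, 8.0, 0),
            (-3.0, -2.8, 8.0, 1),
            (-2.0, -1.5, 8.0, 1),
            (-1.0, -1.0, 8.0, 2),
            (1.0, 0.0, 8.0, 2),
            (1.0, 2.5, 8.0, 3),
            (3.0, 5.9, 8.0, 3),
            (3.0, 6.0, 8.0, 4),
            (3.0, 7.5, 8.0, 4),
        ],
    )
    def test_staging_rules(self, Aa, Ba, TVL, stage):
        assert lc.stage_anterior(lc.PopqExam(Aa=Aa, Ba=Ba, TVL=TVL)) == stage

    def test_missing_point_named(self):
        with pytest.raises(lc.ValidationError, match="TVL"):
            lc.stage_anterior(lc.PopqExam(Aa=-3.0, Ba=-3.0))

    @given(
        edge_lo=st.floats(-3.0, 6.0),
        edge_hi=st.floats(-3.0, 6.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_stage_monotone_in_leading_edge(self, edge_lo, edge_hi):
        lo, hi = sorted((edge_lo, edge_hi))
        stage = lambda e: lc.stage_anterior(
            lc.PopqExam(Aa=min(e, 3.0), Ba=e, TVL=8.0)
        )
        assert stage(lo) <= stage(hi)


class TestClassifyCure:
    def test_full_support_is_cure(self):
        assert lc.classify_cure(exam(-3.0, Aa=-3.0)) == "cure"

    def test_stage_two_is_failure(self):
        assert lc.classify_cure(exam(0.0)) == "failure"

    def test_stage_one_is_cure(self):
        assert lc.classify_cure(exam(-1.5, Aa=-2.0)) == "cure"


class TestCompareBaPrepost:
    @staticmethod
    def series_from_pairs(pairs):
        return lc.CaseSeries(
            lc.CaseRecord(
                case_index=i + 1,
                outcome=0,
                popq_pre=exam(pre, timing="preoperative"),
                popq_post=exam(post),
            )
            for i, (pre, post) in enumerate(pairs)
        )

    def test_identical_vectors_give_null_result(self):
        cmp_ = lc.compare_ba_prepost(self.series_from_pairs([(1.0, 1.0)] * 4))
        assert cmp_.mean_diff == 0.0 and cmp_.t_stat == 0.0 and cmp_.p_value == 1.0

    def test_three_pair_hand_oracle(self):
        # pairs (2,-3), (3,-2), (1,-3): diffs (-5,-5,-4), mean -14/3,
        # sd 1/sqrt(3), t = mean / (sd/sqrt(3)) = -14
        cmp_ = lc.compare_ba_prepost(
            self.series_from_pairs([(2.0, -3.0), (3.0, -2.0), (1.0, -3.0)])
        )
        assert cmp_.mean_pre == pytest.approx(2.0)
        assert cmp_.sd_pre == pytest.approx(1.0)
        assert cmp_.mean_post == pytest.approx(-8 / 3)
        assert cmp_.t_stat == pytest.approx(-14.0)
        assert cmp_.p_value == pytest.approx(0.0050633236738, rel=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(lc.ValidationError):
            lc.compare_ba_prepost(self.series_from_pairs([(2.0, -2.0)]))

    def test_generator_parameters_recovered(self):
        # pool 20 seeded cohorts: the pre/post means should sit at the
        # generator's targets within Monte-Carlo error
        pres, posts = [], []
        for seed in range(20):
            series = lc.generate_cohort(lc.study_like_defaults(seed=seed))
            cmp_ = lc.compare_ba_prepost(series)
            pres.append(cmp_.mean_pre)
            posts.append(cmp_.mean_post)
        se_pre = 1.6 / math.sqrt(20 * 114)
        se_post = 0.8 / math.sqrt(20 * 114)
        assert abs(np.mean(pres) - 2.5) < 4 * se_pre
        assert abs(np.mean(posts) - (-2.8)) < 4 * se_post
        assert lc.compare_ba_prepost(series).p_value < 0.01


class TestFitHealingModel:
    def test_balanced_independent_design_gives_unit_or(self):
        # 4-cell balanced design: outcome independent of the binary
        # covariate, so the MLE coefficient is exactly zero by symmetry
        records = []
        idx = 1
        for parity in (0, 1):
            for outcome in (0, 1):
                for _ in range(5):
                    records.append(
                        lc.CaseRecord(case_index=idx, outcome=outcome, parity=parity)
                    )
                    idx += 1
        fit = lc.fit_healing_model(lc.CaseSeries(records), covariates=("parity",))
        assert fit.table.loc["parity", "odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_coefficient_matches_grid_search_oracle(self):
        # 8-case toy problem; grid maximizer frozen from an independent
        # coarse-to-fine scan of the log-likelihood over (b0, b1)
        y = [1, 1, 0, 1, 0, 0, 1, 0]
        records = [
            lc.CaseRecord(case_index=i + 1, outcome=y[i], operation_time=float(i + 1))
            for i in range(8)
        ]
        fit = lc.fit_healing_model(
            lc.CaseSeries(records), covariates=("operation_time",)
        )
        assert fit.table.loc["operation_time", "coef"] == pytest.approx(
            -0.43320, abs=1e-3
        )
        assert fit.intercept == pytest.approx(1.94941, abs=1e-3)

    def test_complete_separation_raises(self):
        records = [
            lc.CaseRecord(case_index=i, outcome=int(i > 10), age=float(i + 20))
            for i in range(1, 21)
        ]
        with pytest.raises(lc.ConvergenceError):
            lc.fit_healing_model(lc.CaseSeries(records), covariates=("age",))

    def test_constant_covariate_named(self):
        records = [
            lc.CaseRecord(case_index=i, outcome=i % 2, bmi=25.0) for i in range(1, 11)
        ]
        with pytest.raises(lc.ValidationError, match="bmi"):
            lc.fit_healing_model(lc.CaseSeries(records), covariates=("bmi",))

    def test_constant_outcome_rejected(self):
        records = [
            lc.CaseRecord(case_index=i, outcome=0, age=float(20 + i))
            for i in range(1, 11)
        ]
        with pytest.raises(lc.ValidationError, match="outcome"):
            lc.fit_healing_model(lc.CaseSeries(records), covariates=("age",))

    def test_null_model_has_zero_cox_snell(self):
        fit = lc.fit_healing_model(make_series([0, 1] * 10), covariates=())
        assert fit.cox_snell_r2 == pytest.approx(0.0, abs=1e-10)
        assert fit.llf == pytest.approx(fit.llnull)

    def test_wald_ci_brackets_odds_ratio(self):
        series = lc.generate_cohort(
            lc.CohortSpec(n=300, p_novice=0.3, p_expert=0.05, tau=100, seed=4)
        )
        fit = lc.fit_healing_model(series)
        tab = fit.table
        assert ((tab["ci_low"] <= tab["odds_ratio"]) & (tab["odds_ratio"] <= tab["ci_high"])).all()
        assert np.allclose(tab["odds_ratio"], np.exp(tab["coef"]))

    def test_case_volume_ci_coverage(self):
        """Wald 95% CI covers the generating case-volume OR ~95% of the time
        (500 seeded replicates, n = 2000, direct logistic mechanism)."""
        slope = math.log(0.96)
        covered = 0
        for seed in range(500):
            spec = lc.CohortSpec(
                n=2000,
                logit_intercept=2.0,
                logit_slopes={"case_index": slope},
                seed=10_000 + seed,
            )
            fit = lc.fit_healing_model(
                lc.generate_cohort(spec), covariates=("case_index",)
            )
            row = fit.table.loc["case_index"]
            covered += row["ci_low"] <= 0.96 <= row["ci_high"]
        # binomial 3-sigma band around 0.95 at 500 replicates is ~+/-0.03
        assert 0.92 <= covered / 500 <= 0.98
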