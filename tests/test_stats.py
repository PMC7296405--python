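"""Validation statistics against hand formulas, scipy oracles, and nulls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cogbattery.respondent import simulate_cohort
from cogbattery.session import Session
from cogbattery.stats import (
    benjamini_hochberg,
    describe,
    format_p,
    measures_table,
    one_way_anova,
    paired_t,
    pearson,
    repeated_measures_anova,
    validation_report,
)


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson([1, 2, 3], [2, 4, 6])
        assert res.r == 1.0 and res.p == 0.0
        assert format_p(res.p) == "<1e-12"

    def test_perfect_anti_linearity(self):
        assert pearson([1, 2, 3], [3, 2, 1]).r == -1.0

    def test_hand_product_moment_oracle(self):
        # cross products sum to 4, each sum of squares is 5 -> r = 0.8
        res = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.df == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50).filter(lambda v: abs(v) > 1e-6),
        b=st.floats(min_value=-100, max_value=100),
        sign=st.sampled_from([1.0, -1.0]),
        n=st.integers(min_value=3, max_value=30),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_affine_images_are_perfectly_correlated(self, a, b, sign, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        if np.var(x) == 0:
            return
        assert pearson(x, sign * a * x + b).r == pytest.approx(sign, abs=1e-12)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_infinite_t(self):
        res = paired_t([2, 3, 4, 5], [1, 2, 3, 4])
        assert math.isinf(res.t_stat) and res.t_stat > 0 and res.p == 0.0

    def test_hand_formula_oracle(self):
        # d = (2,0,2,0): mean 1, sd sqrt(4/3), t = 1 / (1.1547/2) = sqrt(3)
        res = paired_t([2, 0, 2, 0], [0, 0, 0, 0])
        assert res.t_stat == pytest.approx(math.sqrt(3), abs=1e-12)
        assert res.df == 3


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.p == 1.0

    def test_hand_sum_of_squares_oracle(self):
        # groups (1,2) and (3,4): SSB=4, SSW=1, df=(1,2) -> F=8
        res = one_way_anova([[1, 2], [3, 4]])
        assert res.F == pytest.approx(8.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 10))
            b = rng.normal(1.0, size=rng.integers(3, 10))
            F = one_way_anova([a, b]).F
            t = sps.ttest_ind(a, b).statistic
            assert F == pytest.approx(t**2, rel=1e-10)

    def test_invariance_under_constant_shift(self, rng):
        groups = [rng.normal(size=6), rng.normal(2, size=5), rng.normal(size=7)]
        base = one_way_anova(groups)
        shifted = one_way_anova([g + 1234.5 for g in groups])
        assert shifted.F == pytest.approx(base.F, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])

    def test_repeated_measures_removes_subject_variance(self, rng):
        # add huge per-subject offsets: between-groups F is swamped but the
        # within-subject F still detects the condition effect
        n, k = 12, 3
        effect = np.array([0.0, 1.0, 2.0])
        data = rng.normal(size=(n, k)) + effect + rng.normal(0, 50, size=(n, 1))
        rm = repeated_measures_anova(data)
        between = one_way_anova(list(data.T))
        assert rm.F > between.F
        assert rm.p < 0.05


class TestScipyOracleEquivalence:
    def test_matches_scipy_on_random_instances(self):
        # 200 random small datasets; agreement to 1e-10 relative
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 20))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            ours = pearson(x, y)
            ref = sps.pearsonr(x, y)
            assert ours.r == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-300)

            ours_t = paired_t(x, y)
            ref_t = sps.ttest_rel(x, y)
            assert ours_t.t_stat == pytest.approx(ref_t.statistic, rel=1e-10)
            assert ours_t.p == pytest.approx(ref_t.pvalue, rel=1e-10, abs=1e-300)

            groups = [rng.normal(size=int(rng.integers(3, 10))) for _ in range(3)]
            ours_f = one_way_anova(groups)
            ref_f = sps.f_oneway(*groups)
            assert ours_f.F == pytest.approx(ref_f.statistic, rel=1e-10)
            assert ours_f.p == pytest.approx(ref_f.pvalue, rel=1e-10, abs=1e-300)

    def test_describe_matches_numpy(self, rng):
        x = rng.normal(size=50)
        d = describe(x)
        assert d.mean == pytest.approx(np.mean(x))
        assert d.sd == pytest.approx(np.std(x, ddof=1))
        assert d.n == 50


class TestNullCalibration:
    def test_pearson_p_uniform_under_null(self):
        # 2,000 independent null datasets; KS test on the p-values
        rng = np.random.default_rng(99)
        pvals = [pearson(rng.normal(size=10), rng.normal(size=10)).p for _ in range(2000)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.001


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)


class TestValidationReport:
    def test_report_contains_all_measures_plus_overall(self, small_study):
        report = validation_report(small_study)
        assert len(report) == 11
        assert report["measure"].iloc[-1] == "overall_total_correct"
        assert report["p_display"].notna().all()

    def test_copied_platform_gives_perfect_correlations(self, small_study):
        watch = [s for s in small_study.sessions if s.platform == "watch"]
        mirrored = watch + [
            Session(s.participant_id, s.test, "computer", s.repetition, s.difficulty_N, s.results)
            for s in watch
        ]
        report = validation_report(mirrored)
        assert np.allclose(report["r"], 1.0)

    def test_missing_pairs_drop_participants_not_rows(self, small_study):
        sessions = [
            s
            for s in small_study.sessions
            if not (
                s.test == "stroop"
                and s.platform == "computer"
                and s.participant_id in ("p000", "p001")
            )
        ]
        report = validation_report(sessions).set_index("measure")
        assert report.loc["stroop_congruent_rt", "n"] == small_study.n_participants - 2
        assert report.loc["arrow_avg_correct", "n"] == small_study.n_participants

    def test_zero_loading_overall_r_within_permutation_null_interval(self):
        from cogbattery.respondent import PopulationParams

        study = simulate_cohort(100, PopulationParams(shared_loading=0.0), seed=17)
        table = measures_table(study)["overall_total_correct"]
        w = table["watch"].to_numpy()
        c = table["computer"].to_numpy()
        observed = pearson(w, c).r
        rng = np.random.default_rng(5)
        null = np.array([pearson(w, rng.permutation(c)).r for _ in range(2000)])
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= observed <= hi
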