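"""Simulated respondent: RT law, condition effects, cohort sampling, recovery."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cogbattery.respondent import (
    PopulationParams,
    RespondentParams,
    estimate_exgauss,
    sample_participant,
    sample_response,
    simulate_cohort,
)
from cogbattery.session import Condition
from cogbattery.stimuli import ArrowStimulus, ColorStimulus
from cogbattery.io import session_to_document
from cogbattery.stats import measures_table, pearson

ARROW = ArrowStimulus("right", "left")
COND_WATCH = Condition("arrow", "watch")
COND_COMPUTER = Condition("arrow", "computer")


def draw_rts(params, condition, n, seed, stimulus=ARROW):
    rng = np.random.default_rng(seed)
    rts = []
    while len(rts) < n:
        resp = sample_response(stimulus, condition, params, rng)
        if resp is not None:
            rts.append(resp[1])
    return np.array(rts)


class TestSampleResponse:
    def test_degenerate_distribution_collapses_to_mu(self):
        params = RespondentParams(rt_sigma=0.0, rt_tau=1e-9, platform_offset_ms=0.0)
        rts = draw_rts(params, COND_COMPUTER, 100, 1)
        assert np.allclose(rts, params.rt_mu, atol=1e-6)

    def test_perfect_respondent_never_errs(self):
        params = RespondentParams(p_correct=1.0, lapse_prob=0.0)
        rng = np.random.default_rng(2)
        for _ in range(500):
            choice, _ = sample_response(ARROW, COND_WATCH, params, rng)
            assert choice == "right"

    def test_exgauss_mean_matches_mu_plus_tau(self):
        # mean = mu + tau for the ex-Gaussian; check within 3 SE at n=50,000
        params = RespondentParams(
            rt_mu=400.0, rt_sigma=50.0, rt_tau=150.0, platform_offset_ms=0.0, lapse_prob=0.0
        )
        rts = draw_rts(params, COND_COMPUTER, 50_000, 3)
        se = rts.std(ddof=1) / math.sqrt(rts.size)
        assert abs(rts.mean() - 550.0) < 3 * se

    def test_accuracy_within_exact_binomial_interval(self):
        # empirical accuracy vs configured p over 10,000 trials, 99% CI
        n = 10_000
        for p in (0.7, 0.95):
            params = RespondentParams(p_correct=p, lapse_prob=0.0)
            rng = np.random.default_rng(4)
            correct = sum(
                sample_response(ARROW, COND_WATCH, params, rng)[0] == "right" for _ in range(n)
            )
            assert sps.binom.ppf(0.005, n, p) <= correct <= sps.binom.ppf(0.995, n, p)

    def test_lapse_rate_recovered(self):
        # pooled over independent streams to damp single-batch noise
        params = RespondentParams(lapse_prob=0.1)
        n = 50_000
        lapses = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lapses += sum(
                sample_response(ARROW, COND_WATCH, params, rng) is None for _ in range(n // 5)
            )
        assert sps.binom.ppf(0.005, n, 0.1) <= lapses <= sps.binom.ppf(0.995, n, 0.1)

    def test_platform_offset_contract(self):
        # mean(watch) - mean(computer) ~= platform_offset_ms within 3 SE
        params = RespondentParams(lapse_prob=0.0)
        w = draw_rts(params, COND_WATCH, 50_000, 6)
        c = draw_rts(params, COND_COMPUTER, 50_000, 7)
        se = math.sqrt(w.var(ddof=1) / w.size + c.var(ddof=1) / c.size)
        assert abs((w.mean() - c.mean()) - params.platform_offset_ms) < 3 * se

    def test_congruency_delta_applies_to_incongruent_only(self):
        params = RespondentParams(lapse_prob=0.0, platform_offset_ms=0.0)
        cond = Condition("stroop", "watch")
        congruent = draw_rts(params, cond, 20_000, 8, ColorStimulus("red", "red"))
        incongruent = draw_rts(params, cond, 20_000, 9, ColorStimulus("red", "blue"))
        se = math.sqrt(
            congruent.var(ddof=1) / congruent.size + incongruent.var(ddof=1) / incongruent.size
        )
        diff = incongruent.mean() - congruent.mean()
        assert abs(diff - params.congruency_delta_ms) < 3 * se

    def test_load_effect_monotone_in_delta(self):
        cond3 = Condition("nback", "watch", N=3)
        means = []
        for delta in (100.0, 300.0):
            params = RespondentParams(load_rt_delta_ms=(0.0, 120.0, delta), lapse_prob=0.0)
            means.append(draw_rts(params, cond3, 5_000, 10).mean())
        assert means[1] > means[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RespondentParams(p_correct=1.2)
        with pytest.raises(ValueError):
            RespondentParams(lapse_prob=1.0)
        with pytest.raises(ValueError):
            RespondentParams(rt_tau=0.0)


class TestExGaussRecovery:
    def test_moment_recovery_within_ten_percent(self):
        mu, sigma, tau = 400.0, 50.0, 150.0
        rng = np.random.default_rng(11)
        rts = rng.normal(mu, sigma, 20_000) + rng.exponential(tau, 20_000)
        fit = estimate_exgauss(rts)
        assert abs(fit.mu - mu) / mu < 0.10
        assert abs(fit.sigma - sigma) / sigma < 0.10
        assert abs(fit.tau - tau) / tau < 0.10
        assert not fit.degenerate

    def test_constant_rts_flagged_degenerate(self):
        fit = estimate_exgauss(np.full(100, 500.0))
        assert (fit.mu, fit.sigma, fit.tau) == (500.0, 0.0, 0.0)
        assert fit.degenerate

    def test_symmetric_gaussian_gives_near_zero_tau(self):
        # under zero skew, tau^3-hat = skew * sd^3 / 2; skew has SE ~ sqrt(6/n)
        n, sd = 5_000, 50.0
        bound = (3 * math.sqrt(6 / n) * sd**3 / 2) ** (1 / 3)
        taus = []
        for seed in range(20):
            rts = np.random.default_rng(seed).normal(500.0, sd, n)
            taus.append(estimate_exgauss(rts).tau)
        assert all(t <= bound for t in taus)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            estimate_exgauss(np.arange(49, dtype=float))


class TestCohort:
    def test_session_bookkeeping(self, small_study):
        # each participant: (2 arrow + 3 nback + 2 stroop) x 2 platforms = 14
        assert len(small_study.sessions) == small_study.n_participants * 14
        per = {}
        for s in small_study.sessions:
            per.setdefault(s.participant_id, []).append((s.platform, s.test, s.difficulty_N, s.repetition))
        for sessions in per.values():
            assert len(set(sessions)) == 14

    def test_full_sharing_duplicates_abilities_across_platforms(self):
        pop = PopulationParams(shared_loading=1.0)
        drawn = sample_participant(pop, np.random.default_rng(1))
        assert drawn["watch"].p_correct == drawn["computer"].p_correct
        assert drawn["watch"].rt_mu == drawn["computer"].rt_mu

    def test_high_loading_induces_strong_cross_platform_correlation(self):
        # Monte-Carlo check at large n; agreement across 3 independent runs
        for seed in (101, 202, 303):
            study = simulate_cohort(200, PopulationParams(shared_loading=0.9), seed=seed)
            table = measures_table(study)["overall_total_correct"]
            res = pearson(table["watch"], table["computer"])
            assert res.r > 0.7

    def test_cohort_determinism(self):
        a = simulate_cohort(3, seed=5)
        b = simulate_cohort(3, seed=5)
        assert [session_to_document(s) for s in a.sessions] == [
            session_to_document(s) for s in b.sessions
        ]
        assert a.orders == b.orders

    def test_growing_cohort_preserves_earlier_participants(self):
        small = simulate_cohort(3, seed=5)
        large = simulate_cohort(5, seed=5)
        docs_small = [session_to_document(s) for s in small.sessions]
        docs_large = [session_to_document(s) for s in large.sessions[: len(docs_small)]]
        assert docs_small == docs_large

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(1, seed=1)

    def test_negative_population_sd_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams(rt_mu_sd=-1.0)
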