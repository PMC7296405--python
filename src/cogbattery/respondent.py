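"""Parametric simulated respondent and cohort sampler.

The respondent model replaces human participants in validation runs. Its
response time (RT) law is the ex-Gaussian — the sum of a Normal(mu, sigma)
and an independent Exponential(tau) — the standard right-skewed RT model,
chosen here because its moments are closed-form (mean = mu + tau,
var = sigma^2 + tau^2, skew = 2 tau^3 / (sigma^2 + tau^2)^{3/2}), which
makes moment-based parameter recovery testable. Condition effects enter as
additive shifts on mu:

* ``platform_offset_ms`` — added for watch sessions; captures the slower
  tap-on-glass interaction compared with resting fingers on a keyboard
  (the two-choice fastest RTs differ by roughly 230 ms between platforms);
* ``congruency_delta_ms`` — Stroop interference, added on incongruent
  trials;
* ``load_rt_delta_ms[N]`` / ``load_acc_delta[N]`` — working-memory load
  effects per N-back level.

Accuracy is Bernoulli with condition-adjusted p; errors pick uniformly
among the wrong choices. With probability ``lapse_prob`` the respondent
gives no response at all (attentional lapse), which the session engine
records as a timeout. RTs exceeding the response window are likewise
censored to timeouts by the engine, mirroring a real device.

The cohort sampler draws per-participant parameters around population
means. A *shared-ability loading* in [0, 1] sets the fraction of
between-subject accuracy and speed variance common to a participant's
watch and computer incarnations; loading near 1 induces the strong
cross-platform correlation a valid battery should show, loading 0 makes
the platforms independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .session import (
    ButtonLayout,
    Condition,
    Session,
    Stimulus,
    run_session,
    schedule_trials,
    correct_choice,
    choice_vocabulary,
)
from .stimuli import (
    ColorStimulus,
    DEFAULT_PALETTE,
    SeedLike,
    generate_arrow_sequence,
    generate_nback_sequence,
    generate_stroop_sequence,
)
from .study import DEFAULT_DESIGN, StudyDesign, assign_orders

__all__ = [
    "RespondentParams",
    "PopulationParams",
    "SimulatedRespondent",
    "ExGaussFit",
    "StudyDataset",
    "sample_response",
    "sample_exgauss_rt",
    "estimate_exgauss",
    "sample_participant",
    "simulate_cohort",
]


@dataclass(frozen=True)
class RespondentParams:
    """Ability and RT parameters of one simulated respondent.

    Defaults put the simulated two-choice fastest RT near 545 ms on the
    watch and 315 ms on the computer — the scale a wrist-worn deployment
    shows against a keyboard comparator — without claiming to be fitted to
    any human cohort.
    """

    p_correct: float = 0.95
    rt_mu: float = 330.0  # ms, Gaussian component mean (computer baseline)
    rt_sigma: float = 30.0  # ms, Gaussian component SD
    rt_tau: float = 60.0  # ms, exponential component mean
    congruency_delta_ms: float = 100.0
    load_rt_delta_ms: Tuple[float, float, float] = (0.0, 120.0, 150.0)  # N = 1, 2, 3
    load_acc_delta: Tuple[float, float, float] = (0.0, -0.08, -0.15)
    platform_offset_ms: float = 230.0
    lapse_prob: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError("lapse_prob must lie in [0, 1)")
        if self.rt_mu <= 0 or self.rt_sigma < 0 or self.rt_tau <= 0:
            raise ValueError("require rt_mu > 0, rt_sigma >= 0, rt_tau > 0")

    def mu_for(self, condition: Condition, stimulus: Optional[Stimulus] = None) -> float:
        """Gaussian-component mean with all applicable additive shifts."""
        mu = self.rt_mu
        if condition.platform == "watch":
            mu += self.platform_offset_ms
        if condition.test == "nback" and condition.N is not None:
            mu += self.load_rt_delta_ms[condition.N - 1]
        if condition.test == "stroop" and isinstance(stimulus, ColorStimulus):
            if not stimulus.congruent:
                mu += self.congruency_delta_ms
        return mu

    def p_correct_for(self, condition: Condition) -> float:
        p = self.p_correct
        if condition.test == "nback" and condition.N is not None:
            p += self.load_acc_delta[condition.N - 1]
        return float(np.clip(p, 0.0, 1.0))


def sample_exgauss_rt(mu: float, sigma: float, tau: float, rng: np.random.Generator) -> float:
    """One ex-Gaussian RT draw, resampled until positive."""
    while True:
        rt = rng.normal(mu, sigma) + rng.exponential(tau)
        if rt > 0:
            return float(rt)


def sample_response(
    stimulus: Stimulus,
    condition: Condition,
    params: RespondentParams,
    rng: np.random.Generator,
    layout: Optional[ButtonLayout] = None,
) -> Optional[Tuple[str, float]]:
    """Draw one simulated response: ``(choice, rt_ms)`` or ``None`` (lapse)."""
    if rng.random() < params.lapse_prob:
        return None
    rt = sample_exgauss_rt(params.mu_for(condition, stimulus), params.rt_sigma, params.rt_tau, rng)
    right = correct_choice(stimulus)
    if rng.random() < params.p_correct_for(condition):
        return right, rt
    wrong = [c for c in choice_vocabulary(stimulus, layout) if c != right]
    return wrong[rng.integers(0, len(wrong))], rt


class SimulatedRespondent:
    """Callable responder wrapping params and an RNG stream.

    Satisfies the session engine's responder contract
    ``(stimulus, layout, condition) -> (choice, rt_ms) | None``.
    """

    def __init__(self, params: RespondentParams, rng: SeedLike = None):
        self.params = params
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def __call__(self, stimulus, layout, condition):
        return sample_response(stimulus, condition, self.params, self.rng, layout)


# ---------------------------------------------------------------------------
# Moment-based ex-Gaussian recovery


@dataclass(frozen=True)
class ExGaussFit:
    mu: float
    sigma: float
    tau: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.mu, self.sigma, self.tau))


def estimate_exgauss(rts) -> ExGaussFit:
    """Moment-based ex-Gaussian estimates from a sample of RTs.

    tau is recovered from the third central moment (skew * sd^3 = 2 tau^3),
    sigma^2 from the variance remainder, mu from the mean. A negative skew
    or a variance smaller than tau^2 has no ex-Gaussian solution; the
    offending component is floored at zero and the fit flagged degenerate.
    Requires at least 50 observations for the third moment to be usable.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 50:
        raise ValueError(f"need at least 50 RTs for moment estimation, got {rts.size}")
    mean = float(np.mean(rts))
    var = float(np.var(rts, ddof=1))
    sd = math.sqrt(var)
    degenerate = False
    if sd == 0.0:
        return ExGaussFit(mean, 0.0, 0.0, degenerate=True)
    skew = float(sps.skew(rts, bias=False))
    m3_half = skew * sd**3 / 2.0
    if m3_half <= 0.0:
        tau = 0.0
        degenerate = True
    else:
        tau = m3_half ** (1.0 / 3.0)
    sigma_sq = var - tau**2
    if sigma_sq < 0.0:
        sigma_sq = 0.0
        degenerate = True
    return ExGaussFit(mean - tau, math.sqrt(sigma_sq), tau, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Population model and cohort simulation


@dataclass(frozen=True)
class PopulationParams:
    """Means and between-subject SDs for the respondent parameters.

    ``shared_loading`` is the fraction of between-subject accuracy/speed
    variance shared between a participant's two platform incarnations
    (1 = one common ability, 0 = independent platforms).
    """

    p_correct_mean: float = 0.92
    p_correct_sd: float = 0.05
    rt_mu_mean: float = 330.0
    rt_mu_sd: float = 40.0
    rt_sigma_mean: float = 30.0
    rt_sigma_sd: float = 5.0
    rt_tau_mean: float = 60.0
    rt_tau_sd: float = 15.0
    congruency_delta_mean: float = 100.0
    congruency_delta_sd: float = 30.0
    platform_offset_mean: float = 230.0
    platform_offset_sd: float = 40.0
    lapse_mean: float = 0.02
    lapse_sd: float = 0.01
    load_rt_delta_ms: Tuple[float, float, float] = (0.0, 120.0, 150.0)
    load_acc_delta: Tuple[float, float, float] = (0.0, -0.08, -0.15)
    shared_loading: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "p_correct_sd",
            "rt_mu_sd",
            "rt_sigma_sd",
            "rt_tau_sd",
            "congruency_delta_sd",
            "platform_offset_sd",
            "lapse_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.shared_loading <= 1.0:
            raise ValueError("shared_loading must lie in [0, 1]")


def _blend(loading: float, shared: float, unique: float) -> float:
    """Combine shared and unique standard-normal components at unit variance."""
    return math.sqrt(loading) * shared + math.sqrt(1.0 - loading) * unique


def sample_participant(
    pop: PopulationParams, rng: np.random.Generator
) -> dict[str, RespondentParams]:
    """Draw one participant: a RespondentParams per platform.

    Accuracy and speed each get a latent standard-normal ability; the
    watch and computer incarnations mix a shared component with a
    platform-unique one according to ``shared_loading``. Faster ability
    means higher accuracy and lower rt_mu. The remaining parameters are
    drawn once and shared across platforms.
    """
    L = pop.shared_loading
    acc_shared, speed_shared = rng.normal(size=2)
    sigma = max(1.0, rng.normal(pop.rt_sigma_mean, pop.rt_sigma_sd))
    tau = max(1.0, rng.normal(pop.rt_tau_mean, pop.rt_tau_sd))
    congr = max(0.0, rng.normal(pop.congruency_delta_mean, pop.congruency_delta_sd))
    offset = max(0.0, rng.normal(pop.platform_offset_mean, pop.platform_offset_sd))
    lapse = float(np.clip(rng.normal(pop.lapse_mean, pop.lapse_sd), 0.0, 0.5))
    out: dict[str, RespondentParams] = {}
    for platform in ("watch", "computer"):
        acc_u, speed_u = rng.normal(size=2)
        z_acc = _blend(L, acc_shared, acc_u)
        z_speed = _blend(L, speed_shared, speed_u)
        p = float(np.clip(pop.p_correct_mean + pop.p_correct_sd * z_acc, 0.05, 1.0))
        mu = max(100.0, pop.rt_mu_mean - pop.rt_mu_sd * z_speed)
        out[platform] = RespondentParams(
            p_correct=p,
            rt_mu=mu,
            rt_sigma=sigma,
            rt_tau=tau,
            congruency_delta_ms=congr,
            load_rt_delta_ms=pop.load_rt_delta_ms,
            load_acc_delta=pop.load_acc_delta,
            platform_offset_ms=offset,
            lapse_prob=lapse,
        )
    return out


@dataclass
class StudyDataset:
    """A complete simulated crossover study: all sessions for all participants."""

    sessions: list[Session]
    orders: list[tuple[str, str]]
    design: StudyDesign
    n_participants: int
    seed: Optional[int] = None


def simulate_cohort(
    n_participants: int,
    pop: PopulationParams = PopulationParams(),
    design: StudyDesign = DEFAULT_DESIGN,
    seed: Optional[int] = None,
    nback_target_mode: str = "uncontrolled",
) -> StudyDataset:
    """Simulate the full balanced study for a cohort.

    Every participant completes the whole design on both platforms; the
    counterbalanced administration order is recorded in ``orders``. Because
    the engine is headless and the respondent model has no practice or
    fatigue carryover, sessions are *generated* in canonical platform
    order regardless of the assigned administration order — the order is
    metadata. Each participant owns an independent RNG stream spawned from
    the master seed, so enlarging the cohort never perturbs earlier
    participants' data.

    ``nback_target_mode`` is forwarded to the letter-stream generator:
    ``"uncontrolled"`` reproduces independent random letter draws per
    platform (target counts differ between paired sessions, diluting the
    cross-platform correlation of N-back correct counts), while
    ``"controlled"`` fixes the target count exactly.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    master = np.random.SeedSequence(seed)
    order_ss, *participant_ss = master.spawn(n_participants + 1)
    orders = assign_orders(n_participants, np.random.default_rng(order_ss))

    sessions: list[Session] = []
    for idx in range(n_participants):
        pid = f"p{idx:03d}"
        prng = np.random.default_rng(participant_ss[idx])
        params_by_platform = sample_participant(pop, prng)
        for platform in ("watch", "computer"):
            respondent = SimulatedRespondent(params_by_platform[platform], prng)
            for plan in design.sessions:
                if plan.test == "arrow":
                    stimuli = generate_arrow_sequence(40, prng)
                elif plan.test == "nback":
                    stimuli = generate_nback_sequence(
                        40, plan.difficulty_N, target_mode=nback_target_mode, seed=prng
                    )
                else:
                    stimuli = generate_stroop_sequence(7, 23, DEFAULT_PALETTE, prng)
                specs = schedule_trials(stimuli, plan.test, prng)
                sessions.append(
                    run_session(
                        specs,
                        respondent,
                        participant_id=pid,
                        test=plan.test,
                        platform=platform,
                        repetition=plan.repetition,
                        difficulty_N=plan.difficulty_N,
                        seed=prng,
                    )
                )
    return StudyDataset(sessions, orders, design, n_participants, seed)
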