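# Methods

## Scope and model

`cogbattery` is a headless re-implementation of a three-test smartwatch
cognitive battery (two-choice reaction time, N-back, Stroop color-word)
plus the instruments and statistics used to validate such a battery
against desktop comparator tools. Rendering, touch sensing and real-time
administration are out of scope: time is logical (millisecond offsets),
and responses come from any callable satisfying the responder contract.
Human participants are replaced by a parametric simulated respondent.

## Stimulus generation

**Arrow.** Direction and screen position are independent fair coin flips.
The joint scheme (independent p = 0.5 each) is a design choice; position
is non-informative for the response, so only independence matters for the
measures. No constraint is placed on runs of identical stimuli.

**N-back.** The default *uncontrolled* mode draws letters iid uniformly
from the 26 uppercase Latin letters (configurable alphabet) and labels
targets post hoc. Its realised target count is binomial, so two platforms
given independent streams face slightly different difficulty — a real
source of attenuation in cross-platform correlations of N-back correct
counts. The *controlled* mode fixes the count at
`round(rate x (n_trials - N))` (half-away-from-zero rounding, stated so
derived counts are platform-stable), places targets uniformly among
eligible indices, and excludes the letter N back at non-target slots so no
accidental targets occur. Near-miss "lures" (matches at other lags) are
deliberately not controlled in either mode.

**Stroop.** Words uniform over a 4-color palette (red/green/blue/yellow;
a pink-for-yellow variant for small screens where yellow reads poorly);
incongruent inks uniform over the three non-word colors (the ink
distribution is a design choice); presentation order is a uniform shuffle
of the exact 7 congruent + 23 incongruent multiset.

## Scheduling and administration

Arrow: 2000 ms response window, integer ISI uniform on the closed interval
[1000, 3000] ms. N-back and Stroop: 2500 ms windows; their ISI is not
pinned down by the battery's design, so it defaults to a fixed 500 ms and
is configurable. A response exactly at the window boundary is valid
(closed interval, stated for determinism). Responses slower than the
window, and lapses, are recorded as timeouts with no RT — censoring, as a
real device behaves — and no input is accepted during the ISI. For the
Stroop test a button layout (bijection of palette to 4 slots) is drawn per
session and held fixed within it. An out-of-vocabulary choice is recorded
as incorrect and logged rather than raised: a malformed responder should
contaminate one trial, not destroy a session.

## The simulated respondent

RT law: ex-Gaussian, `RT = N(mu', sigma) + Exp(tau)`, resampled until
positive. The ex-Gaussian is the standard right-skewed RT model and has
closed-form moments (mean mu + tau, variance sigma^2 + tau^2, third
central moment 2 tau^3), which makes moment-based recovery exactly
testable. `mu'` adds, when applicable: the watch platform offset (default
230 ms — the interaction-modality cost of tapping glass vs resting fingers
on keys; exposed as a single additive parameter without claiming to
decompose modality from alertness), the Stroop incongruency delta (default
100 ms), and the per-N load delta (defaults 0/120/150 ms). Accuracy is
Bernoulli with per-N adjustments (defaults 0/-0.08/-0.15, clipped to
[0, 1]); errors are uniform over the wrong alternatives (1 for
arrow/N-back, 3 for Stroop). Defaults were chosen once to put simulated
two-choice fastest RTs near the 545 ms (watch) / 315 ms (computer) scale;
they are plausible study conditions, not fitted truth.

Moment-based ex-Gaussian recovery: `tau = (skew * sd^3 / 2)^(1/3)`
(bias-corrected sample skewness), `sigma^2 = var - tau^2`, `mu = mean -
tau`; negative intermediates are floored at zero and flagged degenerate.
At n = 20,000 the mu and tau estimates carry well under 10% relative
error; sigma's sampling error is itself around 7% median at that n, so
single-draw checks sit near a 10% bound and the calibration test asserts
the median over fixed replicate seeds.

## Cohort model

Each participant gets two latent standard-normal abilities (accuracy,
speed). For each, the watch and computer incarnations mix a shared
component with a platform-unique one: `z = sqrt(L) z_shared +
sqrt(1-L) z_unique`, L the shared-ability loading (default 0.9). Accuracy
is `clip(0.92 + 0.05 z_acc)`; the Gaussian RT mean is
`max(100, 330 - 40 z_speed)` ms (higher ability, faster). Sigma, tau,
congruency delta, platform offset and lapse probability are drawn once per
participant from independent normals (floored at small positive values).
L = 1 with these floors makes a participant's two platform incarnations
identical in ability; L = 0 makes platforms independent, under which the
overall cross-platform correlation is statistically indistinguishable from
zero (checked against a permutation null).

The full design is arrow x2, N-back at N = 1, 2, 3, Stroop x2, on both
platforms — 14 sessions per participant. Administration order
(watch-first vs computer-first) is counterbalanced to within one
participant and recorded as metadata; because the respondent model has no
practice or fatigue carryover, sessions are generated in canonical
platform order, which keeps every participant's data invariant to cohort
size (per-participant RNG streams are spawned from the master seed).

## Scoring

RT statistics use correct trials only by default (the comparator tools'
convention; an all-trials variant sits behind a flag). Timeouts count
against accuracy (the on-device feedback is correct-over-total) but never
contribute an RT; with no correct trial the RT statistics are absent, not
zero. The Stroop interference (incongruent minus congruent mean RT) is
emitted as a derived convenience. Averaging over repeated runs takes the
arithmetic mean of each defined field; the "fastest RT" of a two-run test
is the mean of the two per-run minima, not the pooled minimum. No
anticipatory-RT floor is applied: a sub-100 ms correct response still
enters the fastest-RT statistic, since the battery's own definition sets
no floor.

## Questionnaires

Raw (unweighted) TLX only — per-subscale 7-point ratings and their plain
mean; no pairwise weighting. MARS factor scores are item means with
configurable item counts (the exact item subset is institution-specific).
Aggregation reports per-cell mean, sample SD (n-1; validated against a
two-pass oracle) and n, printed at 2 decimals. The questionnaire cohort
simulator draws integer ratings from a rounded truncated normal around
per-cell population values chosen to emulate a realistic study: workload
rising steeply from 1-back to 3-back on both devices, app-quality factors
above 4 of 5, discomfort below 3 of 7.

## Statistics

Pearson r, paired t and one-way ANOVA are computed from the textbook
formulas (scipy supplies only the t and F tail probabilities), because
these statistics are part of the package's contract and are
oracle-verified against independent implementations to 1e-10. Two-sided
p-values throughout; p below 1e-12 displays as an inequality while the
float is retained. The ANOVA is independent-groups as named; a
repeated-measures variant is provided because difficulty-level designs are
within-subject and the two conventions differ materially in power — both
are exposed so either analysis can be reproduced. No multiple-testing
correction by default; a Benjamini-Hochberg column is optional.

The validation report correlates each performance measure between
platforms across participants: two arrow rows (average correct over the
two runs, average fastest RT — the two-run average, consistent with the
adjacent averaged correct counts), six N-back rows (mean RT and correct
count at each N), two Stroop rows (congruent and incongruent mean RT), and
a final overall row (total correct across the battery) — 11 rows.
Participants missing either platform's value for a measure are dropped
from that row with a logged count.

## Session logs

One JSON document per session: schema-versioned header plus a trial array
with contiguous indices. Unknown top-level fields round-trip untouched;
schema mismatches and malformed trials raise errors naming the version or
the trial index. Flat CSV exports (per-trial, per-session-score) use a
strict comma/UTF-8 dialect.

## Problem sizes and numerical choices

Statistical test suites use sizes at which their exact bounds are sharp:
binomial/multinomial uniformity at 10,000–24,000 draws with exact
quantile bounds (Bonferroni across cells), null p-value calibration on
2,000 simulated datasets (KS at alpha = 0.001), formula-oracle agreement
on 200 random small instances at 1e-10 relative, and end-to-end studies at
the 21-participant scale of a typical feasibility cohort (plus
150–200-participant cohorts where a correlation's asymptotic value is the
claim). All randomness flows from explicit seeds through
`numpy.random.Generator`; no global RNG state is touched.

## Known limitations

The respondent model is statistical, not cognitive: no drift-diffusion
dynamics, no practice, fatigue or order effects (which is also why
counterbalancing is metadata here), no trial-to-trial autocorrelation, and
no device artefacts such as missed taps. Passing validation on simulated
cohorts demonstrates that the engine, scoring and statistics are correct
and internally consistent — not that a particular hardware deployment
would reach any given correlation with desktop tools. The shared-ability
loading is a single knob standing in for whatever mixture of traits real
platforms share; its default is a plausible setting, not an estimate.
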