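"""Per-session performance measures.

The battery's performance measures are: number of correct responses and
fastest (minimum) RT for the two-choice arrow test; number of correct
responses and mean RT for the N-back test; mean RT to congruent and to
incongruent stimuli for the Stroop test. RT statistics are computed over
correct trials only by default (the convention of the comparator desktop
tools); pass ``correct_only=False`` for all-responded-trials statistics.
Timeouts always count against accuracy but never contribute an RT.

No anticipatory-response floor is applied: an implausibly fast correct
response (< 100 ms) still enters the fastest-RT statistic. See the methods
note for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .session import Session
from .stimuli import ColorStimulus, LetterStimulus

__all__ = ["ScoreReport", "score_session", "feedback_fraction", "average_over_repetitions"]


@dataclass
class ScoreReport:
    """Performance summary of one session (or an average over repetitions).

    ``mean_rt_ms`` and ``fastest_rt_ms`` are None when no trial
    contributed an RT (e.g. all timeouts) — absent, not zero.
    ``interference_ms`` (Stroop only) is the incongruent-minus-congruent
    mean-RT difference, a derived convenience rather than a primary
    measure.
    """

    test: str
    n_trials: float
    n_correct: float
    n_incorrect: float
    n_timeout: float
    accuracy: float
    mean_rt_ms: Optional[float] = None
    fastest_rt_ms: Optional[float] = None
    cond_mean_rt_ms: dict = field(default_factory=dict)
    interference_ms: Optional[float] = None


def _condition_of(stimulus) -> Optional[str]:
    if isinstance(stimulus, ColorStimulus):
        return "congruent" if stimulus.congruent else "incongruent"
    if isinstance(stimulus, LetterStimulus):
        return "target" if stimulus.is_target else "nontarget"
    return None


def score_session(session: Session, correct_only: bool = True) -> ScoreReport:
    """Compute the performance measures for one session."""
    if not session.results:
        raise ValueError("cannot score an empty session")
    results = session.results
    n = len(results)
    n_correct = sum(r.outcome == "correct" for r in results)
    n_incorrect = sum(r.outcome == "incorrect" for r in results)
    n_timeout = sum(r.outcome == "timeout" for r in results)

    def usable(r) -> bool:
        if r.rt_ms is None:
            return False
        return r.outcome == "correct" if correct_only else True

    rts = [r.rt_ms for r in results if usable(r)]
    cond_rts: dict[str, list[float]] = {}
    for r in results:
        if usable(r):
            cond = _condition_of(r.stimulus)
            if cond is not None:
                cond_rts.setdefault(cond, []).append(r.rt_ms)

    cond_means = {c: float(np.mean(v)) for c, v in cond_rts.items()}
    interference = None
    if session.test == "stroop" and "congruent" in cond_means and "incongruent" in cond_means:
        interference = cond_means["incongruent"] - cond_means["congruent"]

    return ScoreReport(
        test=session.test,
        n_trials=n,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_timeout=n_timeout,
        accuracy=n_correct / n,
        mean_rt_ms=float(np.mean(rts)) if rts else None,
        fastest_rt_ms=float(np.min(rts)) if rts else None,
        cond_mean_rt_ms=cond_means,
        interference_ms=interference,
    )


def feedback_fraction(session: Session) -> float:
    """The on-device feedback: correct responses over total trials.

    Timeouts count in the denominator, so silence lowers the score.
    """
    if not session.results:
        raise ValueError("cannot compute feedback for an empty session")
    return sum(r.outcome == "correct" for r in session.results) / len(session.results)


def _mean_defined(values: list[Optional[float]]) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def average_over_repetitions(reports: list[ScoreReport]) -> ScoreReport:
    """Arithmetic mean of each defined field across repeated sessions.

    The fastest RT is averaged across repetitions (an average of
    per-session minima, not a minimum over the pooled trials), matching how
    repeated two-choice runs are summarised. All reports must come from
    the same test.
    """
    if not reports:
        raise ValueError("need at least one report")
    tests = {r.test for r in reports}
    if len(tests) != 1:
        raise ValueError(f"cannot average reports from different tests: {sorted(tests)}")

    conds = {c for r in reports for c in r.cond_mean_rt_ms}
    cond_means = {}
    for c in conds:
        m = _mean_defined([r.cond_mean_rt_ms.get(c) for r in reports])
        if m is not None:
            cond_means[c] = m
    return ScoreReport(
        test=reports[0].test,
        n_trials=float(np.mean([r.n_trials for r in reports])),
        n_correct=float(np.mean([r.n_correct for r in reports])),
        n_incorrect=float(np.mean([r.n_incorrect for r in reports])),
        n_timeout=float(np.mean([r.n_timeout for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        mean_rt_ms=_mean_defined([r.mean_rt_ms for r in reports]),
        fastest_rt_ms=_mean_defined([r.fastest_rt_ms for r in reports]),
        cond_mean_rt_ms=cond_means,
        interference_ms=_mean_defined([r.interference_ms for r in reports]),
    )
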