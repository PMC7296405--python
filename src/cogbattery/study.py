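"""Study-design utilities: the crossover schedule and counterbalancing.

The validation study administers, to every participant and on both
platforms (smartwatch and computer): the arrow test twice, the N-back test
once at each difficulty N = 1, 2, 3, and the Stroop test twice — 7 sessions
per platform, 14 per participant. The order in which a participant starts
(watch first vs computer first) is counterbalanced across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .stimuli import SeedLike, _rng

__all__ = ["SessionPlan", "StudyDesign", "DEFAULT_DESIGN", "assign_orders"]

PLATFORMS = ("watch", "computer")


@dataclass(frozen=True)
class SessionPlan:
    """One cell of the design: a test at a difficulty, repetition index."""

    test: str
    repetition: int = 1
    difficulty_N: Optional[int] = None


@dataclass(frozen=True)
class StudyDesign:
    """Per-platform session list; identical for both platforms."""

    sessions: tuple[SessionPlan, ...] = (
        SessionPlan("arrow", 1),
        SessionPlan("arrow", 2),
        SessionPlan("nback", 1, difficulty_N=1),
        SessionPlan("nback", 1, difficulty_N=2),
        SessionPlan("nback", 1, difficulty_N=3),
        SessionPlan("stroop", 1),
        SessionPlan("stroop", 2),
    )
    platforms: tuple[str, ...] = PLATFORMS

    @property
    def sessions_per_participant(self) -> int:
        return len(self.sessions) * len(self.platforms)


DEFAULT_DESIGN = StudyDesign()


def assign_orders(n_participants: int, seed: SeedLike = None) -> list[tuple[str, str]]:
    """Counterbalanced platform orders, one per participant.

    Exactly ``ceil(n/2)`` participants get one order and ``floor(n/2)`` the
    other, assigned by a uniform random permutation, so order effects cancel
    to within one participant.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = _rng(seed)
    n_first = (n_participants + 1) // 2
    orders = [("watch", "computer")] * n_first + [("computer", "watch")] * (
        n_participants - n_first
    )
    perm = rng.permutation(n_participants)
    return [orders[i] for i in perm]
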