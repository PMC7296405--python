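"""Trial scheduling and headless session administration.

A session is a sequence of trials. Each trial displays one stimulus for at
most a test-specific response window, then a blank interstimulus interval
(ISI) during which no input is accepted. The engine is headless: time is
logical (millisecond offsets from session start), and responses come from a
pluggable *responder* — any callable ``(stimulus, layout, condition) ->
(choice, rt_ms) | None`` — so the same machinery drives simulated cohorts
and replayed logs.

Timing defaults: the arrow test shows each stimulus for at most 2000 ms
with an ISI drawn uniformly from [1000, 3000] ms; the letter (N-back) and
color (Stroop) tests allow 2500 ms per stimulus with a fixed configurable
ISI. A response landing exactly on the window boundary counts as valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple, Union

from .stimuli import (
    ArrowStimulus,
    ColorPalette,
    ColorStimulus,
    DEFAULT_PALETTE,
    LetterStimulus,
    SeedLike,
    _rng,
)

__all__ = [
    "ARROW_WINDOW_MS",
    "NBACK_WINDOW_MS",
    "STROOP_WINDOW_MS",
    "ARROW_ISI_RANGE_MS",
    "DEFAULT_ISI_MS",
    "Condition",
    "TrialSpec",
    "TrialResult",
    "Session",
    "ButtonLayout",
    "schedule_trials",
    "correct_choice",
    "choice_vocabulary",
    "run_session",
    "shuffle_button_layout",
]

logger = logging.getLogger(__name__)

ARROW_WINDOW_MS = 2000
NBACK_WINDOW_MS = 2500
STROOP_WINDOW_MS = 2500
ARROW_ISI_RANGE_MS = (1000, 3000)
DEFAULT_ISI_MS = 500

Stimulus = Union[ArrowStimulus, LetterStimulus, ColorStimulus]


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one trial: which test, difficulty, platform."""

    test: str
    platform: str = "watch"  # "watch" | "computer"
    N: Optional[int] = None

    def __post_init__(self) -> None:
        if self.test not in ("arrow", "nback", "stroop"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.platform not in ("watch", "computer"):
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class TrialSpec:
    stimulus: Stimulus
    response_window_ms: int
    isi_ms: int

    def __post_init__(self) -> None:
        if self.response_window_ms <= 0:
            raise ValueError("response_window_ms must be positive")
        if self.isi_ms < 0:
            raise ValueError("isi_ms must be non-negative")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one administered trial.

    ``outcome == "timeout"`` iff no response was recorded iff ``rt_ms`` is
    None; a recorded RT never exceeds the response window.
    """

    stimulus: Stimulus
    response: Optional[str]
    rt_ms: Optional[float]
    outcome: str  # "correct" | "incorrect" | "timeout"

    def __post_init__(self) -> None:
        if self.outcome not in ("correct", "incorrect", "timeout"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "timeout") != (self.response is None) or (
            (self.response is None) != (self.rt_ms is None)
        ):
            raise ValueError("timeout <=> response is None <=> rt_ms is None")


@dataclass
class Session:
    participant_id: str
    test: str
    platform: str
    repetition: int = 1
    difficulty_N: Optional[int] = None
    results: list[TrialResult] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None


@dataclass(frozen=True)
class ButtonLayout:
    """Bijective assignment of palette colors to the four screen slots."""

    slots: tuple[str, ...]  # slots[i] = color name shown at screen slot i

    def __post_init__(self) -> None:
        if len(set(self.slots)) != len(self.slots):
            raise ValueError("layout must be a bijection: duplicate color")

    def slot_of(self, color: str) -> int:
        return self.slots.index(color)


def schedule_trials(
    stimuli: Sequence[Stimulus],
    test: str,
    seed: SeedLike = None,
    isi_ms: int = DEFAULT_ISI_MS,
) -> list[TrialSpec]:
    """Attach response windows and ISIs to a stimulus sequence.

    Arrow trials get a 2000 ms window and an integer ISI uniform on
    [1000, 3000] ms (inclusive); N-back and Stroop trials get 2500 ms
    windows and the fixed ``isi_ms``.
    """
    if len(stimuli) == 0:
        raise ValueError("stimuli must be nonempty")
    if test == "arrow":
        rng = _rng(seed)
        lo, hi = ARROW_ISI_RANGE_MS
        isis = rng.integers(lo, hi + 1, size=len(stimuli))
        return [TrialSpec(s, ARROW_WINDOW_MS, int(i)) for s, i in zip(stimuli, isis)]
    if test == "nback":
        return [TrialSpec(s, NBACK_WINDOW_MS, isi_ms) for s in stimuli]
    if test == "stroop":
        return [TrialSpec(s, STROOP_WINDOW_MS, isi_ms) for s in stimuli]
    raise ValueError(f"unknown test {test!r}")


def correct_choice(stimulus: Stimulus) -> str:
    """The choice a perfectly accurate respondent would make."""
    if isinstance(stimulus, ArrowStimulus):
        return stimulus.direction
    if isinstance(stimulus, LetterStimulus):
        return "yes" if stimulus.is_target else "no"
    if isinstance(stimulus, ColorStimulus):
        return stimulus.ink
    raise ValueError(f"unknown stimulus type {type(stimulus).__name__}")


def choice_vocabulary(stimulus: Stimulus, layout: Optional[ButtonLayout] = None) -> tuple[str, ...]:
    """All choices available for a stimulus (button labels on screen)."""
    if isinstance(stimulus, ArrowStimulus):
        return ("left", "right")
    if isinstance(stimulus, LetterStimulus):
        return ("yes", "no")
    if isinstance(stimulus, ColorStimulus):
        return layout.slots if layout is not None else DEFAULT_PALETTE.names
    raise ValueError(f"unknown stimulus type {type(stimulus).__name__}")


def shuffle_button_layout(palette: ColorPalette, seed: SeedLike = None) -> ButtonLayout:
    """Uniform random assignment of the palette's colors to the 4 slots.

    The color-test button order is reshuffled between runs so respondents
    cannot learn fixed button positions.
    """
    rng = _rng(seed)
    order = rng.permutation(len(palette.names))
    return ButtonLayout(tuple(palette.names[i] for i in order))


Responder = Callable[[Stimulus, Optional[ButtonLayout], Condition], Optional[Tuple[str, float]]]


def run_session(
    specs: Sequence[TrialSpec],
    responder: Responder,
    participant_id: str = "p0",
    test: str = "arrow",
    platform: str = "watch",
    repetition: int = 1,
    difficulty_N: Optional[int] = None,
    palette: ColorPalette = DEFAULT_PALETTE,
    seed: SeedLike = None,
) -> Session:
    """Administer scheduled trials against a responder and record results.

    For the color test a fresh button layout is drawn from ``seed`` and
    held fixed for the whole session. A missing response, or one slower
    than the window, is recorded as a timeout with no RT (the device stops
    listening when the stimulus disappears). A choice outside the stimulus
    vocabulary is recorded as incorrect and logged.
    """
    if len(specs) == 0:
        raise ValueError("specs must be nonempty")
    rng = _rng(seed)
    condition = Condition(test=test, platform=platform, N=difficulty_N)
    layout = shuffle_button_layout(palette, rng) if test == "stroop" else None

    results: list[TrialResult] = []
    for i, spec in enumerate(specs):
        answer = responder(spec.stimulus, layout, condition)
        if answer is None:
            results.append(TrialResult(spec.stimulus, None, None, "timeout"))
            continue
        choice, rt = answer
        if rt > spec.response_window_ms:
            # response landed after the stimulus disappeared: censored
            results.append(TrialResult(spec.stimulus, None, None, "timeout"))
            continue
        vocab = choice_vocabulary(spec.stimulus, layout)
        if choice not in vocab:
            logger.warning(
                "trial %d: choice %r outside vocabulary %r; recorded as incorrect", i, choice, vocab
            )
            outcome = "incorrect"
        else:
            outcome = "correct" if choice == correct_choice(spec.stimulus) else "incorrect"
        results.append(TrialResult(spec.stimulus, choice, float(rt), outcome))

    return Session(
        participant_id=participant_id,
        test=test,
        platform=platform,
        repetition=repetition,
        difficulty_N=difficulty_N,
        results=results,
        config={
            "n_trials": len(specs),
            "response_window_ms": specs[0].response_window_ms,
        },
        seed=seed if isinstance(seed, int) else None,
    )
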