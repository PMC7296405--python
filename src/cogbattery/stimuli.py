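"""Stimulus sequence generators for the three cognitive tests.

The battery comprises three brief tests designed for a smartwatch form
factor:

* **Arrow** — a two-choice reaction-time test. Each trial shows a single
  arrow pointing left or right, drawn on the left or right half of the
  screen; the respondent indicates the arrow's *direction*. Direction and
  screen position are independent coin flips, so position is
  non-informative.
* **Letter** — an N-back working-memory test over uppercase letters. A
  trial is a *target* when its letter equals the letter shown N positions
  earlier; N (1, 2 or 3) sets the difficulty and is fixed within a run.
* **Color** — a Stroop color-word interference test. Each trial shows a
  color name printed in some ink color; the respondent names the *ink*.
  Congruent trials (word == ink) are outnumbered by incongruent ones.

All generators are driven by :func:`numpy.random.default_rng` and are fully
reproducible from a seed.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ArrowStimulus",
    "LetterStimulus",
    "ColorStimulus",
    "ColorPalette",
    "SequenceConfig",
    "DEFAULT_ALPHABET",
    "DEFAULT_PALETTE",
    "PINK_PALETTE",
    "generate_arrow_sequence",
    "generate_nback_sequence",
    "generate_stroop_sequence",
    "generate_sequence",
    "label_targets",
    "round_half_away",
]

DEFAULT_ALPHABET: tuple[str, ...] = tuple(string.ascii_uppercase)

SeedLike = Union[None, int, np.random.Generator, np.random.SeedSequence]


def _rng(seed: SeedLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Used for derived trial counts so results do not depend on the host's
    banker's-rounding behaviour.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ArrowStimulus:
    """One arrow trial: where the arrow points and where it is drawn."""

    direction: str  # "left" | "right"
    position: str  # "left" | "right"

    def __post_init__(self) -> None:
        for attr in ("direction", "position"):
            if getattr(self, attr) not in ("left", "right"):
                raise ValueError(f"{attr} must be 'left' or 'right', got {getattr(self, attr)!r}")


@dataclass(frozen=True)
class LetterStimulus:
    """One letter trial in an N-back stream."""

    letter: str
    index: int
    is_target: bool

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isupper():
            raise ValueError(f"letter must be a single uppercase character, got {self.letter!r}")
        if self.index < 0:
            raise ValueError("index must be non-negative")


@dataclass(frozen=True)
class ColorPalette:
    """The set of four color names a Stroop run draws from.

    The default palette is red/green/blue/yellow; a pink-for-yellow variant
    is provided for respondents who find yellow hard to distinguish on a
    small screen.
    """

    names: tuple[str, ...] = ("red", "green", "blue", "yellow")

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != 4:
            raise ValueError(f"palette must have exactly 4 colors, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("palette colors must be distinct")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_PALETTE = ColorPalette()
PINK_PALETTE = ColorPalette(("red", "green", "blue", "pink"))


@dataclass(frozen=True)
class ColorStimulus:
    """One Stroop trial: a color word rendered in some ink color."""

    word: str
    ink: str
    congruent: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "congruent", self.word == self.ink)


@dataclass
class SequenceConfig:
    """Declarative description of one stimulus sequence.

    ``target_mode`` applies to the N-back test only: ``"uncontrolled"``
    draws letters independently and labels targets post hoc (so the number
    of targets varies run to run, as in naive implementations);
    ``"controlled"`` places an exact number of targets,
    ``round(target_rate * (n_trials - N))``, at uniformly random eligible
    positions and forbids accidental matches elsewhere, so difficulty is
    identical across platforms and sessions.
    """

    test: str  # "arrow" | "nback" | "stroop"
    n_trials: int = 40
    N: Optional[int] = None
    n_congruent: Optional[int] = None
    n_incongruent: Optional[int] = None
    target_mode: str = "uncontrolled"
    target_rate: float = 0.3
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    palette: ColorPalette = field(default_factory=ColorPalette)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.test not in ("arrow", "nback", "stroop"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.test == "nback" and self.N is None:
            self.N = 2
        if self.test == "stroop":
            if self.n_congruent is None and self.n_incongruent is None:
                self.n_congruent, self.n_incongruent = 7, 23
                self.n_trials = 30
            if self.n_congruent + self.n_incongruent != self.n_trials:
                raise ValueError("n_congruent + n_incongruent must equal n_trials")
        if self.target_mode not in ("uncontrolled", "controlled"):
            raise ValueError(f"unknown target_mode {self.target_mode!r}")
        if not 0 < self.target_rate < 1 and self.target_mode == "controlled":
            raise ValueError("target_rate must lie in (0, 1)")


def generate_arrow_sequence(n: int, seed: SeedLike = None) -> list[ArrowStimulus]:
    """Generate ``n`` arrow stimuli with direction and position each uniform.

    Direction and screen position are sampled independently with p=0.5,
    so a rightward arrow is equally likely to appear on either side.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = _rng(seed)
    sides = ("left", "right")
    directions = rng.integers(0, 2, size=n)
    positions = rng.integers(0, 2, size=n)
    return [ArrowStimulus(sides[d], sides[p]) for d, p in zip(directions, positions)]


def label_targets(letters: Sequence[str], N: int) -> list[bool]:
    """Label each position as target iff it repeats the letter N back.

    Positions with index < N can never be targets. This is the definitional
    scan used both to label uncontrolled sequences and as the independent
    check on controlled ones.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return [i >= N and letters[i] == letters[i - N] for i in range(len(letters))]


def generate_nback_sequence(
    n_trials: int = 40,
    N: int = 2,
    target_mode: str = "uncontrolled",
    target_rate: float = 0.3,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    seed: SeedLike = None,
) -> list[LetterStimulus]:
    """Generate an N-back letter stream.

    In uncontrolled mode letters are iid uniform over ``alphabet`` and the
    target labels are whatever the draw happens to produce — matching how a
    naive generator behaves, where the realised number of targets differs
    between runs and platforms. In controlled mode exactly
    ``round(target_rate * (n_trials - N))`` targets are placed uniformly at
    random among the eligible positions (index >= N); every other eligible
    position draws from the alphabet *excluding* the letter N back, so no
    accidental targets arise and the target count is exact by construction.

    Near-miss "lure" repeats (e.g. a letter matching N-1 back) are not
    controlled in either mode.
    """
    if N not in (1, 2, 3):
        raise ValueError(f"N must be 1, 2 or 3, got {N}")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if N >= n_trials:
        raise ValueError(f"N={N} must be smaller than n_trials={n_trials}")
    alphabet = tuple(alphabet)
    rng = _rng(seed)

    if target_mode == "uncontrolled":
        letters = [alphabet[i] for i in rng.integers(0, len(alphabet), size=n_trials)]
    elif target_mode == "controlled":
        if len(alphabet) < 2:
            raise ValueError("controlled mode requires an alphabet of at least 2 letters")
        if not 0 < target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")
        n_eligible = n_trials - N
        k = round_half_away(target_rate * n_eligible)
        target_idx = set(N + rng.choice(n_eligible, size=k, replace=False))
        letters: list[str] = []
        for i in range(n_trials):
            if i < N:
                letters.append(alphabet[rng.integers(0, len(alphabet))])
            elif i in target_idx:
                letters.append(letters[i - N])
            else:
                # draw from the alphabet minus the letter N back: no accidental target
                choices = [c for c in alphabet if c != letters[i - N]]
                letters.append(choices[rng.integers(0, len(choices))])
    else:
        raise ValueError(f"unknown target_mode {target_mode!r}")

    labels = label_targets(letters, N)
    return [LetterStimulus(c, i, t) for i, (c, t) in enumerate(zip(letters, labels))]


def generate_stroop_sequence(
    n_congruent: int = 7,
    n_incongruent: int = 23,
    palette: ColorPalette = DEFAULT_PALETTE,
    seed: SeedLike = None,
) -> list[ColorStimulus]:
    """Generate a shuffled Stroop sequence with exact congruency counts.

    Words are uniform over the palette. Congruent trials use the word's own
    color as ink; incongruent trials draw the ink uniformly from the three
    remaining colors. The assembled list is uniformly shuffled so congruency
    is unpredictable trial to trial. The default 7:23 split gives the 1:3
    ratio (within rounding) used to match difficulty across platforms.
    """
    if n_congruent < 0 or n_incongruent < 0:
        raise ValueError("stimulus counts must be non-negative")
    if n_incongruent > 0 and len(palette) < 2:
        raise ValueError("incongruent stimuli require at least 2 palette colors")
    rng = _rng(seed)
    names = palette.names
    stimuli: list[ColorStimulus] = []
    for _ in range(n_congruent):
        word = names[rng.integers(0, len(names))]
        stimuli.append(ColorStimulus(word, word))
    for _ in range(n_incongruent):
        word = names[rng.integers(0, len(names))]
        others = [c for c in names if c != word]
        stimuli.append(ColorStimulus(word, others[rng.integers(0, len(others))]))
    rng.shuffle(stimuli)
    return stimuli


def generate_sequence(cfg: SequenceConfig):
    """Generate a stimulus sequence from a :class:`SequenceConfig`."""
    if cfg.test == "arrow":
        return generate_arrow_sequence(cfg.n_trials, cfg.seed)
    if cfg.test == "nback":
        return generate_nback_sequence(
            cfg.n_trials, cfg.N, cfg.target_mode, cfg.target_rate, cfg.alphabet, cfg.seed
        )
    return generate_stroop_sequence(cfg.n_congruent, cfg.n_incongruent, cfg.palette, cfg.seed)
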