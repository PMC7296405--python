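"""Questionnaire instruments: raw NASA-TLX, a MARS subset, wrist discomfort.

Three self-report instruments accompany the cognitive tests:

* **NASA-TLX** (raw, unweighted) on a 7-point scale with five subscales —
  mental demand, temporal demand, performance, effort, frustration. The
  physical-demand subscale is omitted as irrelevant to a seated tapping
  task, and no pairwise-weighting procedure is applied: the summary is the
  plain subscale mean.
* **MARS subset** — app-quality ratings on the aesthetics, functionality
  and information factors, items scored 1-5 and averaged within a factor.
  Item counts per factor are configurable.
* **Wrist discomfort** — a single 1-7 rating per app (1 = least
  discomfort).

Cohort aggregation produces mean / sample-SD (n-1) tables per cell
(device x task x subscale, or app x factor), printed at 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimuli import SeedLike, _rng

__all__ = [
    "TLX_SUBSCALES",
    "MARS_FACTORS",
    "TLXRating",
    "MARSRating",
    "DiscomfortRating",
    "score_tlx",
    "score_mars",
    "aggregate_cohort",
    "format_mean_sd_table",
    "simulate_likert_ratings",
    "simulate_tlx_cohort",
    "simulate_mars_cohort",
    "simulate_discomfort_cohort",
    "DEFAULT_TLX_POPULATION",
    "DEFAULT_MARS_POPULATION",
    "DEFAULT_DISCOMFORT_POPULATION",
]

TLX_SUBSCALES = ("mental", "temporal", "performance", "effort", "frustration")
MARS_FACTORS = ("aesthetics", "functionality", "information")


def _check_range(name: str, value, lo: int, hi: int) -> None:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class TLXRating:
    """One raw-TLX response: five 7-point subscales, no physical demand."""

    mental: int
    temporal: int
    performance: int
    effort: int
    frustration: int

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_range(f.name, getattr(self, f.name), 1, 7)


@dataclass(frozen=True)
class MARSRating:
    """Item scores for one MARS factor, each on a 1-5 scale."""

    factor: str
    item_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.factor not in MARS_FACTORS:
            raise ValueError(f"factor must be one of {MARS_FACTORS}, got {self.factor!r}")
        object.__setattr__(self, "item_scores", tuple(self.item_scores))
        if not self.item_scores:
            raise ValueError("item_scores must be nonempty")
        for i, s in enumerate(self.item_scores):
            _check_range(f"item_scores[{i}]", s, 1, 5)


@dataclass(frozen=True)
class DiscomfortRating:
    """Wrist-discomfort rating after one app, 1 (least) to 7 (most)."""

    score: int
    app: str

    def __post_init__(self) -> None:
        _check_range("score", self.score, 1, 7)
        if self.app not in ("arrow", "letter", "color"):
            raise ValueError(f"app must be arrow/letter/color, got {self.app!r}")


def score_tlx(rating: TLXRating) -> dict[str, float]:
    """Echo the five subscales and add the raw (unweighted) mean."""
    out = {s: float(getattr(rating, s)) for s in TLX_SUBSCALES}
    out["raw_mean"] = float(np.mean(list(out.values())))
    return out


def score_mars(rating: MARSRating) -> float:
    """Factor score: mean of the factor's item scores."""
    return float(np.mean(rating.item_scores))


def aggregate_cohort(
    records: pd.DataFrame,
    index: Sequence[str],
    columns: Optional[Sequence[str]] = None,
    value: str = "score",
) -> pd.DataFrame:
    """Aggregate long-format ratings into a mean / SD / n table.

    ``records`` is long format with one rating per row. The result has a
    row per combination of ``index`` levels (and a column level per
    ``columns`` entry if given), holding ``mean``, ``sd`` (sample SD, n-1
    denominator) and ``n`` per cell. Cells with a single rating get NaN
    SD; empty cells are simply absent.
    """
    if value not in records.columns:
        raise ValueError(f"no column {value!r} in records")
    keys = list(index) + (list(columns) if columns else [])
    grouped = records.groupby(keys, sort=True)[value].agg(mean="mean", sd="std", n="count")
    if columns:
        grouped = grouped.unstack(list(columns))
    return grouped


def format_mean_sd_table(agg: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Render an aggregate table as ``mean (SD)`` strings."""
    if isinstance(agg.columns, pd.MultiIndex):
        cols = agg["mean"].columns
        out = pd.DataFrame(index=agg.index)
        for c in cols:
            out[c] = [
                f"{m:.{decimals}f} ({s:.{decimals}f})"
                for m, s in zip(agg[("mean", c)], agg[("sd", c)])
            ]
        return out
    return pd.DataFrame(
        {"score": [f"{m:.{decimals}f} ({s:.{decimals}f})" for m, s in zip(agg["mean"], agg["sd"])]},
        index=agg.index,
    )


#: Population (mean, SD) per cell used when simulating questionnaire
#: responses for a cohort: perceived workload rises with N and is broadly
#: similar across platforms; app-quality ratings sit above 4 of 5;
#: wrist discomfort stays below 3 of 7.
DEFAULT_TLX_POPULATION: dict[tuple[str, int, str], tuple[float, float]] = {
    ("watch", 1, "mental"): (2.81, 1.50),
    ("watch", 1, "temporal"): (2.81, 1.29),
    ("watch", 1, "performance"): (2.05, 1.32),
    ("watch", 1, "effort"): (3.05, 1.20),
    ("watch", 1, "frustration"): (2.52, 1.60),
    ("watch", 2, "mental"): (4.71, 1.27),
    ("watch", 2, "temporal"): (4.19, 1.50),
    ("watch", 2, "performance"): (4.29, 1.49),
    ("watch", 2, "effort"): (4.43, 1.17),
    ("watch", 2, "frustration"): (3.86, 1.80),
    ("watch", 3, "mental"): (5.19, 1.33),
    ("watch", 3, "temporal"): (4.05, 1.75),
    ("watch", 3, "performance"): (4.67, 1.62),
    ("watch", 3, "effort"): (5.10, 1.10),
    ("watch", 3, "frustration"): (3.95, 1.80),
    ("computer", 1, "mental"): (2.76, 0.99),
    ("computer", 1, "temporal"): (2.86, 1.62),
    ("computer", 1, "performance"): (2.91, 1.84),
    ("computer", 1, "effort"): (2.67, 1.07),
    ("computer", 1, "frustration"): (2.48, 1.47),
    ("computer", 2, "mental"): (4.50, 1.54),
    ("computer", 2, "temporal"): (3.50, 1.61),
    ("computer", 2, "performance"): (3.10, 1.52),
    ("computer", 2, "effort"): (4.35, 1.35),
    ("computer", 2, "frustration"): (2.95, 1.64),
    ("computer", 3, "mental"): (5.52, 1.29),
    ("computer", 3, "temporal"): (4.24, 1.76),
    ("computer", 3, "performance"): (4.76, 1.76),
    ("computer", 3, "effort"): (5.00, 1.18),
    ("computer", 3, "frustration"): (4.00, 1.73),
}

DEFAULT_MARS_POPULATION: dict[tuple[str, str], tuple[float, float]] = {
    ("arrow", "aesthetics"): (4.02, 0.76),
    ("arrow", "functionality"): (4.55, 0.52),
    ("arrow", "information"): (4.24, 0.86),
    ("letter", "aesthetics"): (4.19, 0.75),
    ("letter", "functionality"): (4.36, 0.62),
    ("letter", "information"): (4.33, 0.60),
    ("color", "aesthetics"): (4.14, 0.83),
    ("color", "functionality"): (4.64, 0.45),
    ("color", "information"): (4.31, 0.64),
}

DEFAULT_DISCOMFORT_POPULATION: dict[str, tuple[float, float]] = {
    "arrow": (2.71, 1.79),
    "letter": (2.24, 1.18),
    "color": (2.14, 1.32),
}


def simulate_tlx_cohort(
    n_participants: int,
    population: dict = DEFAULT_TLX_POPULATION,
    seed: SeedLike = None,
) -> pd.DataFrame:
    """Simulated raw-TLX ratings for a cohort, long format.

    One row per participant x device x N-back level x subscale, scores
    drawn per cell from :func:`simulate_likert_ratings` on the 1-7 scale.
    MARS factor scores are item averages, so they are simulated on the
    continuous scale in :func:`simulate_mars_cohort` instead.
    """
    rng = _rng(seed)
    rows = []
    for (device, task, subscale), (mean, sd) in population.items():
        scores = simulate_likert_ratings(mean, sd, n_participants, 1, 7, rng)
        for i, s in enumerate(scores):
            rows.append(
                {
                    "participant_id": f"p{i:03d}",
                    "instrument": "tlx",
                    "device": device,
                    "task": f"{task}-back",
                    "field": subscale,
                    "score": int(s),
                }
            )
    return pd.DataFrame(rows)


def simulate_mars_cohort(
    n_participants: int,
    population: dict = DEFAULT_MARS_POPULATION,
    seed: SeedLike = None,
) -> pd.DataFrame:
    """Simulated MARS factor scores (item means, so non-integer) per app."""
    rng = _rng(seed)
    rows = []
    for (app, factor), (mean, sd) in population.items():
        filled = 0
        scores = np.empty(n_participants)
        while filled < n_participants:
            draw = rng.normal(mean, sd, size=2 * (n_participants - filled) + 8)
            ok = draw[(draw >= 1.0) & (draw <= 5.0)][: n_participants - filled]
            scores[filled : filled + ok.size] = ok
            filled += ok.size
        for i, s in enumerate(scores):
            rows.append(
                {
                    "participant_id": f"p{i:03d}",
                    "instrument": "mars",
                    "app": app,
                    "field": factor,
                    "score": float(s),
                }
            )
    return pd.DataFrame(rows)


def simulate_discomfort_cohort(
    n_participants: int,
    population: dict = DEFAULT_DISCOMFORT_POPULATION,
    seed: SeedLike = None,
) -> pd.DataFrame:
    """Simulated 1-7 wrist-discomfort ratings per app."""
    rng = _rng(seed)
    rows = []
    for app, (mean, sd) in population.items():
        scores = simulate_likert_ratings(mean, sd, n_participants, 1, 7, rng)
        for i, s in enumerate(scores):
            rows.append(
                {
                    "participant_id": f"p{i:03d}",
                    "instrument": "discomfort",
                    "app": app,
                    "field": "discomfort",
                    "score": int(s),
                }
            )
    return pd.DataFrame(rows)


def simulate_likert_ratings(
    mean: float,
    sd: float,
    n: int,
    lo: int = 1,
    hi: int = 7,
    seed: SeedLike = None,
) -> np.ndarray:
    """Draw integer Likert ratings from a rounded truncated normal.

    Samples a normal(mean, sd) restricted to [lo - 0.5, hi + 0.5) by
    rejection, then rounds to the nearest integer, so the realised mean
    tracks the requested one closely for scales whose bounds are more than
    about one SD from the mean.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _rng(seed)
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(8, 2 * (n - filled)))
        ok = draw[(draw >= lo - 0.5) & (draw < hi + 0.5)]
        take = ok[: n - filled]
        out[filled : filled + take.size] = np.rint(take).astype(int)
        filled += take.size
    return np.clip(out, lo, hi)
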