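"""Validation statistics: Pearson correlation, paired t, one-way ANOVA.

These are the statistics used to validate a wrist-worn test battery
against desktop comparator tools: per-measure Pearson correlations between
platforms (with t-based two-sided p-values), paired-sample t tests for
platform differences, and one-way ANOVA for the effect of N-back
difficulty. All statistics are computed from the textbook formulas with
p-values from the corresponding scipy distributions; tests cross-check
them against scipy.stats' own implementations.

Conventions: two-sided p-values throughout; sample SDs use the n-1
denominator; no multiple-testing correction by default (an optional
Benjamini-Hochberg column can be added to reports); p-values below 1e-12
display as "<1e-12" while the exact float is retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .respondent import StudyDataset
from .scoring import average_over_repetitions, score_session
from .session import Session

__all__ = [
    "CorrelationResult",
    "PairedTResult",
    "AnovaResult",
    "DescriptiveSummary",
    "pearson",
    "paired_t",
    "one_way_anova",
    "repeated_measures_anova",
    "describe",
    "format_p",
    "measures_table",
    "validation_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    df: int
    p: float


@dataclass(frozen=True)
class PairedTResult:
    t_stat: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class DescriptiveSummary:
    mean: float
    sd: float
    n: int


def format_p(p: float, floor: float = 1e-12) -> str:
    """Display helper: extreme p-values print as an inequality."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"


def describe(x) -> DescriptiveSummary:
    x = np.asarray(x, dtype=float)
    return DescriptiveSummary(float(np.mean(x)), float(np.std(x, ddof=1)), int(x.size))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with t-based two-sided p.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom. Perfect
    correlation yields an infinite t and p = 0 (displayed as "<1e-12").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = float(dx @ dy) / math.sqrt(ssx * ssy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r, n, math.copysign(math.inf, r), df, 0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r, n, t, df, p)


def paired_t(x, y) -> PairedTResult:
    """Paired-sample t test on d = x - y, two-sided, df = n-1.

    Degenerate cases: identical differences with nonzero mean give an
    infinite t with p = 0; all-zero differences give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, df, 1.0, 0.0)
        return PairedTResult(math.copysign(math.inf, mean_d), df, 0.0, mean_d)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTResult(t, df, p, mean_d)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Independent-groups one-way ANOVA from the standard sums of squares.

    F = MS_between / MS_within with df (k-1, N-k). For a within-subject
    layout see :func:`repeated_measures_anova`.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    n_total = sum(g.size for g in arrays)
    grand = sum(float(g.sum()) for g in arrays) / n_total
    ss_between = sum(g.size * (float(g.mean()) - grand) ** 2 for g in arrays)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    df_b = k - 1
    df_w = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p)


def repeated_measures_anova(data) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions array.

    Removes between-subject variance from the error term:
    SS_error = SS_total - SS_subjects - SS_conditions, with df
    (k-1, (n-1)(k-1)). Provided because a within-subject design analysed
    with the independent-groups formula understates power; both variants
    are exposed so either convention can be reproduced.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (subjects x conditions)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_cond = float((n * (data.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float((k * (data.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_c = k - 1
    df_e = (n - 1) * (k - 1)
    if ss_err <= 0.0:
        return AnovaResult(math.inf if ss_cond > 0 else 0.0, df_c, df_e, 0.0 if ss_cond > 0 else 1.0)
    F = (ss_cond / df_c) / (ss_err / df_e)
    p = float(sps.f.sf(F, df_c, df_e))
    return AnovaResult(F, df_c, df_e, p)


# ---------------------------------------------------------------------------
# Study-level report

#: Ordered measure keys in the validation report, mirroring how the
#: battery's measures are tabulated: two-choice first, then N-back mean RT
#: and correct counts per level, then Stroop condition RTs.
REPORT_MEASURES = (
    "arrow_avg_correct",
    "arrow_fastest_rt",
    "nback1_mean_rt",
    "nback2_mean_rt",
    "nback3_mean_rt",
    "nback1_correct",
    "nback2_correct",
    "nback3_correct",
    "stroop_congruent_rt",
    "stroop_incongruent_rt",
)


def measures_table(study: StudyDataset | Sequence[Session]) -> pd.DataFrame:
    """Per-participant, per-platform measure table for a study dataset.

    Rows are participants; columns are a (measure, platform) MultiIndex.
    Repeated sessions (arrow and stroop, twice each) are averaged before entering the
    table; ``overall_total_correct`` sums correct responses over every
    session a participant completed on a platform.
    """
    sessions = study.sessions if isinstance(study, StudyDataset) else list(study)
    cells: dict[tuple[str, str, str], float] = {}
    by_key: dict[tuple[str, str, str, Optional[int]], list[Session]] = {}
    totals: dict[tuple[str, str], float] = {}
    for s in sessions:
        by_key.setdefault((s.participant_id, s.platform, s.test, s.difficulty_N), []).append(s)
    for (pid, platform, test, N), group in by_key.items():
        reports = [score_session(s) for s in sorted(group, key=lambda s: s.repetition)]
        avg = average_over_repetitions(reports)
        totals[(pid, platform)] = totals.get((pid, platform), 0.0) + sum(
            r.n_correct for r in reports
        )
        if test == "arrow":
            cells[(pid, "arrow_avg_correct", platform)] = avg.n_correct
            if avg.fastest_rt_ms is not None:
                cells[(pid, "arrow_fastest_rt", platform)] = avg.fastest_rt_ms
        elif test == "nback":
            cells[(pid, f"nback{N}_correct", platform)] = avg.n_correct
            if avg.mean_rt_ms is not None:
                cells[(pid, f"nback{N}_mean_rt", platform)] = avg.mean_rt_ms
        elif test == "stroop":
            for cond in ("congruent", "incongruent"):
                if cond in avg.cond_mean_rt_ms:
                    cells[(pid, f"stroop_{cond}_rt", platform)] = avg.cond_mean_rt_ms[cond]
    for (pid, platform), total in totals.items():
        cells[(pid, "overall_total_correct", platform)] = total

    records = [
        {"participant_id": pid, "measure": m, "platform": pf, "value": v}
        for (pid, m, pf), v in cells.items()
    ]
    df = pd.DataFrame.from_records(records)
    return df.pivot(index="participant_id", columns=["measure", "platform"], values="value")


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR), monotone-enforced."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def validation_report(
    study: StudyDataset | Sequence[Session],
    add_bh: bool = False,
) -> pd.DataFrame:
    """Cross-platform Pearson correlation per performance measure.

    One row per measure (two-choice average correct and fastest RT; N-back
    mean RT and correct count at each difficulty; Stroop congruent and
    incongruent mean RT) plus a final ``overall_total_correct`` row — the
    correlation of participants' total correct responses across the whole
    battery. Participants missing either platform's value for a measure
    are dropped from that row (with a log message), mirroring how lost
    sessions are handled in practice.
    """
    table = measures_table(study)
    rows = []
    for measure in REPORT_MEASURES + ("overall_total_correct",):
        if measure not in table.columns.get_level_values(0):
            logger.warning("measure %s absent from dataset; row skipped", measure)
            continue
        sub = table[measure]
        if not {"watch", "computer"} <= set(sub.columns):
            logger.warning("measure %s lacks a platform; row skipped", measure)
            continue
        paired = sub[["watch", "computer"]].dropna()
        n_dropped = len(sub) - len(paired)
        if n_dropped:
            logger.info("measure %s: %d participant(s) without a complete pair", measure, n_dropped)
        if len(paired) < 3:
            logger.warning("measure %s: fewer than 3 complete pairs; row skipped", measure)
            continue
        res = pearson(paired["watch"], paired["computer"])
        rows.append(
            {
                "measure": measure,
                "n": res.n,
                "r": res.r,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p,
                "p_display": format_p(res.p),
            }
        )
    report = pd.DataFrame(rows)
    if add_bh and len(report):
        report["p_bh"] = benjamini_hochberg(report["p"].to_numpy())
    return report
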