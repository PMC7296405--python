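"""Session-log documents and flat CSV exports.

One session is persisted as one JSON document: a header (participant,
test, platform, repetition, difficulty, seed, config snapshot, schema
version) plus an array of trial records with contiguous indices. JSON was
chosen because the logs stay greppable and diffable. Unknown top-level
fields written by future producers survive a read/write round-trip
untouched. All durations are integer-or-float milliseconds in the log;
statistics downstream are floating point.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .scoring import ScoreReport, score_session
from .session import Session, TrialResult
from .stimuli import ArrowStimulus, ColorStimulus, LetterStimulus

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "MalformedLogError",
    "write_session",
    "read_session",
    "read_sessions",
    "trials_to_frame",
    "scores_to_frame",
]

SCHEMA_VERSION = 1

_HEADER_KEYS = (
    "schema_version",
    "participant_id",
    "test",
    "platform",
    "repetition",
    "difficulty_N",
    "seed",
    "config",
    "trials",
)


class SchemaError(ValueError):
    """Log document declares an unsupported schema version."""


class MalformedLogError(ValueError):
    """Log document structurally invalid; message names the trial index."""


def _stimulus_fields(stimulus) -> dict:
    if isinstance(stimulus, ArrowStimulus):
        return {"direction": stimulus.direction, "position": stimulus.position}
    if isinstance(stimulus, LetterStimulus):
        return {"letter": stimulus.letter, "index": stimulus.index, "is_target": stimulus.is_target}
    if isinstance(stimulus, ColorStimulus):
        return {"word": stimulus.word, "ink": stimulus.ink, "congruent": stimulus.congruent}
    raise ValueError(f"unknown stimulus type {type(stimulus).__name__}")


def _stimulus_from_fields(test: str, fields: dict, trial_index: int):
    try:
        if test == "arrow":
            return ArrowStimulus(fields["direction"], fields["position"])
        if test == "nback":
            return LetterStimulus(fields["letter"], fields["index"], fields["is_target"])
        if test == "stroop":
            return ColorStimulus(fields["word"], fields["ink"])
    except (KeyError, ValueError, TypeError) as exc:
        raise MalformedLogError(f"trial {trial_index}: bad stimulus record ({exc})") from exc
    raise MalformedLogError(f"trial {trial_index}: unknown test {test!r}")


def session_to_document(session: Session) -> dict:
    """Serialise a session to the schema-versioned log document (a dict)."""
    extra = session.config.get("_extra", {}) if isinstance(session.config, dict) else {}
    config = {k: v for k, v in session.config.items() if k != "_extra"}
    doc = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": session.participant_id,
        "test": session.test,
        "platform": session.platform,
        "repetition": session.repetition,
        "difficulty_N": session.difficulty_N,
        "seed": session.seed,
        "config": config,
        "trials": [
            {
                "index": i,
                "stimulus": _stimulus_fields(r.stimulus),
                "response": r.response,
                "rt_ms": r.rt_ms,
                "outcome": r.outcome,
            }
            for i, r in enumerate(session.results)
        ],
    }
    doc.update(extra)
    return doc


def document_to_session(doc: dict) -> Session:
    """Parse a log document back into a Session, preserving unknown fields."""
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {version!r} (supported: {SCHEMA_VERSION})")
    test = doc["test"]
    results = []
    for pos, trial in enumerate(doc["trials"]):
        if not isinstance(trial, dict) or "stimulus" not in trial or "outcome" not in trial:
            raise MalformedLogError(f"trial {pos}: missing stimulus or outcome")
        if trial.get("index") != pos:
            raise MalformedLogError(
                f"trial {pos}: non-contiguous index {trial.get('index')!r}"
            )
        stim = _stimulus_from_fields(test, trial["stimulus"], pos)
        try:
            results.append(
                TrialResult(stim, trial.get("response"), trial.get("rt_ms"), trial["outcome"])
            )
        except ValueError as exc:
            raise MalformedLogError(f"trial {pos}: {exc}") from exc
    config = dict(doc.get("config") or {})
    extra = {k: v for k, v in doc.items() if k not in _HEADER_KEYS}
    if extra:
        config["_extra"] = extra
    return Session(
        participant_id=doc["participant_id"],
        test=test,
        platform=doc["platform"],
        repetition=doc.get("repetition", 1),
        difficulty_N=doc.get("difficulty_N"),
        results=results,
        config=config,
        seed=doc.get("seed"),
    )


def write_session(session: Session, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(session_to_document(session), indent=1) + "\n", encoding="utf-8")
    return path


def read_session(path: Union[str, Path]) -> Session:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise MalformedLogError(f"{path}: invalid JSON at line {exc.lineno}, col {exc.colno}") from exc
    return document_to_session(doc)


def read_sessions(directory: Union[str, Path]) -> list[Session]:
    """Read every ``*.json`` session log in a directory (sorted by name)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.json"))
    return [read_session(p) for p in paths]


def trials_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """Flat per-trial table across sessions (one row per trial)."""
    rows = []
    for s in sessions:
        for i, r in enumerate(s.results):
            row = {
                "participant_id": s.participant_id,
                "test": s.test,
                "platform": s.platform,
                "repetition": s.repetition,
                "difficulty_N": s.difficulty_N,
                "trial": i,
                "response": r.response,
                "rt_ms": r.rt_ms,
                "outcome": r.outcome,
            }
            row.update(_stimulus_fields(r.stimulus))
            rows.append(row)
    return pd.DataFrame(rows)


_SCORE_COLUMNS = [
    "participant_id",
    "test",
    "platform",
    "repetition",
    "difficulty_N",
    "n_trials",
    "n_correct",
    "n_incorrect",
    "n_timeout",
    "accuracy",
    "mean_rt_ms",
    "fastest_rt_ms",
    "congruent_mean_rt_ms",
    "incongruent_mean_rt_ms",
    "target_mean_rt_ms",
    "nontarget_mean_rt_ms",
    "interference_ms",
]


def scores_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """One score row per session, fixed column order."""
    rows = []
    for s in sessions:
        rep: ScoreReport = score_session(s)
        rows.append(
            {
                "participant_id": s.participant_id,
                "test": s.test,
                "platform": s.platform,
                "repetition": s.repetition,
                "difficulty_N": s.difficulty_N,
                "n_trials": rep.n_trials,
                "n_correct": rep.n_correct,
                "n_incorrect": rep.n_incorrect,
                "n_timeout": rep.n_timeout,
                "accuracy": rep.accuracy,
                "mean_rt_ms": rep.mean_rt_ms,
                "fastest_rt_ms": rep.fastest_rt_ms,
                "congruent_mean_rt_ms": rep.cond_mean_rt_ms.get("congruent"),
                "incongruent_mean_rt_ms": rep.cond_mean_rt_ms.get("incongruent"),
                "target_mean_rt_ms": rep.cond_mean_rt_ms.get("target"),
                "nontarget_mean_rt_ms": rep.cond_mean_rt_ms.get("nontarget"),
                "interference_ms": rep.interference_ms,
            }
        )
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)
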