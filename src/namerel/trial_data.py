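"""Trial-level picture-naming data: I/O, validation, classification, exclusion.

Trials live in a pandas DataFrame with one row per naming trial. A trial is
classified as ``correct``, ``wrong_word`` (a different word was produced),
``disfluency`` (false start, repair, hesitation), or ``no_response`` (no
vocal onset within the response window). Only correct trials enter the
latency analyses; exclusion counts are reported per session/condition as a
percentage of all trials of that session.

CSV schema (UTF-8, comma-delimited, header row; empty string = absent):
``participant_id, session, condition, trial_index, item_id, target_word,
picture_onset_ms, vocal_onset_ms, response_word, disfluent, response_class``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "RESPONSE_CLASSES",
    "read_trials",
    "write_trials",
    "validate_trials",
    "classify_response",
    "normalize_word",
    "filter_trials",
    "gate_participants",
    "exclusion_report",
]

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "condition",
    "trial_index",
    "item_id",
    "target_word",
    "picture_onset_ms",
    "vocal_onset_ms",
    "response_word",
    "disfluent",
    "response_class",
]

RESPONSE_CLASSES = ["correct", "wrong_word", "disfluency", "no_response"]

_ARTICLES = re.compile(r"^(a|an|the)\s+", flags=re.IGNORECASE)


class TrialValidationError(ValueError):
    """A trial table violates the schema or a trial-level invariant."""


def normalize_word(word: str) -> str:
    """Normalize a word for identity scoring: casefold, trim, drop leading article."""
    word = str(word).strip().casefold()
    word = _ARTICLES.sub("", word)
    return re.sub(r"\s+", " ", word)


def classify_response(
    target_word: str,
    response_word: str | None,
    disfluent: bool,
    vocal_onset_present: bool,
) -> str:
    """Classify a single trial's response.

    Precedence: no vocal onset -> ``no_response``; else a disfluent
    production -> ``disfluency``; else a response that does not match the
    target after normalization -> ``wrong_word``; else ``correct``.
    """
    if not str(target_word).strip():
        raise ValueError("target_word must be non-empty")
    if not vocal_onset_present:
        return "no_response"
    if disfluent:
        return "disfluency"
    if response_word is None or normalize_word(response_word) != normalize_word(
        target_word
    ):
        return "wrong_word"
    return "correct"


def _compute_latency(df: pd.DataFrame) -> pd.Series:
    return df["vocal_onset_ms"] - df["picture_onset_ms"]


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table and add the derived ``latency_ms`` column.

    Raises :class:`TrialValidationError` naming offending rows (0-based row
    numbers within the table) on any violation.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    # absent response is represented uniformly as NaN (empty field in CSV)
    df["response_word"] = df["response_word"].replace("", np.nan)

    df["trial_index"] = pd.to_numeric(df["trial_index"], errors="coerce")
    bad = df.index[df["trial_index"].isna() | (df["trial_index"] < 1)]
    if len(bad):
        raise TrialValidationError(f"malformed trial_index at rows {list(bad[:10])}")
    df["trial_index"] = df["trial_index"].astype(int)

    for col in ("picture_onset_ms", "vocal_onset_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df["picture_onset_ms"].isna() | (df["picture_onset_ms"] < 0)]
    if len(bad):
        raise TrialValidationError(f"malformed picture_onset_ms at rows {list(bad[:10])}")

    df["disfluent"] = df["disfluent"].map(
        {True: True, False: False, "True": True, "False": False, "true": True,
         "false": False, 1: True, 0: False, "1": True, "0": False}
    )
    if df["disfluent"].isna().any():
        bad = df.index[df["disfluent"].isna()]
        raise TrialValidationError(f"malformed disfluent flag at rows {list(bad[:10])}")
    df["disfluent"] = df["disfluent"].astype(bool)

    unknown = ~df["response_class"].isin(RESPONSE_CLASSES)
    if unknown.any():
        raise TrialValidationError(
            f"unknown response_class at rows {list(df.index[unknown][:10])}"
        )

    has_onset = df["vocal_onset_ms"].notna()
    mism = (df["response_class"] == "no_response") != ~has_onset
    if mism.any():
        raise TrialValidationError(
            "no_response must coincide with absent vocal onset at rows "
            f"{list(df.index[mism][:10])}"
        )

    lat = _compute_latency(df)
    nonpos = has_onset & (lat <= 0)
    if nonpos.any():
        rows = list(df.index[nonpos][:10])
        raise TrialValidationError(
            f"vocal onset at or before picture onset (non-positive latency) at rows {rows}"
        )
    df["latency_ms"] = lat

    dup = df.duplicated(subset=["participant_id", "session", "trial_index"])
    if dup.any():
        raise TrialValidationError(
            f"duplicate trial_index within participant/session at rows "
            f"{list(df.index[dup][:10])}"
        )
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV; returns the table with ``latency_ms`` added."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "item_id": str,
            "target_word": str,
            "response_word": str,
            "condition": str,
        },
        keep_default_na=True,
    )
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to CSV in the canonical column order (absent = empty)."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def exclusion_report(trials: pd.DataFrame, by: str = "session") -> pd.DataFrame:
    """Tabulate response classes per session/condition.

    Percentages use all trials of that session/condition as denominator and
    are rounded to 2 decimals, matching the convention of reporting error
    trials as a share of all administered trials.
    """
    rows = []
    for key, grp in trials.groupby(by, sort=True):
        denom = len(grp)
        counts = grp["response_class"].value_counts()
        for cls in RESPONSE_CLASSES:
            n = int(counts.get(cls, 0))
            rows.append(
                {
                    by: key,
                    "response_class": cls,
                    "count": n,
                    "percent_of_all_trials": round(100.0 * n / denom, 2),
                    "denominator": denom,
                }
            )
    return pd.DataFrame(rows)


def filter_trials(
    trials: pd.DataFrame, by: str = "session"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep correct trials only; return (correct_trials, exclusion report)."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    report = exclusion_report(trials, by=by)
    correct = trials[trials["response_class"] == "correct"].copy()
    return correct, report


def gate_participants(
    trials: pd.DataFrame, threshold: float = 0.60
) -> tuple[list, list]:
    """Apply the minimum-accuracy inclusion gate.

    A participant is excluded if their proportion of correct responses falls
    below ``threshold`` in any session they completed; exactly meeting the
    threshold retains them. Returns (retained_ids, excluded_ids), each sorted.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    acc = (
        trials.assign(correct=trials["response_class"].eq("correct"))
        .groupby(["participant_id", "session"])["correct"]
        .mean()
    )
    worst = acc.groupby("participant_id").min()
    excluded = sorted(worst.index[worst < threshold])
    retained = sorted(worst.index[worst >= threshold])
    return retained, excluded
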