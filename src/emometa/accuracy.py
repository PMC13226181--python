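"""Trial-level correctness: the participant-based interval rule and 2AFC matching.

For slider ratings there is no external ground truth, so correctness is
defined relative to the participant's own response distribution: compute the
rating-minus-norm difference for every trial, take that participant's mean
and sample SD of the differences, and score a trial correct when its
difference lies within mean +/- k*SD. With k = 0.675 (the 75th percentile of
the standard normal) and Gaussian differences, about half of all trials are
scored correct and half incorrect, giving a balanced type-1 split for the
type-2 analysis regardless of the participant's bias or spread.

For the forced-choice design correctness is categorical: the response must
match the stimulus's database class ('pleasant' <-> high valence, 'high' <->
high arousal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_K",
    "FAMILIARITY_CUTOFF",
    "AccuracyInterval",
    "AccuracyVector",
    "participant_accuracy",
    "afc_accuracy",
    "familiarity_split",
]

#: Standard-normal quantile multiplier giving a ~50/50 correct/incorrect split.
DEFAULT_K = 0.675

#: Familiarity rating at or above which a trial counts as high-familiarity.
FAMILIARITY_CUTOFF = 50


@dataclass(frozen=True)
class AccuracyInterval:
    """Decision band mean +/- k*SD of a participant's difference series."""

    avg_diff: float
    sd_diff: float
    k: float = DEFAULT_K

    @property
    def lower(self) -> float:
        return self.avg_diff - self.k * self.sd_diff

    @property
    def upper(self) -> float:
        return self.avg_diff + self.k * self.sd_diff

    def contains(self, x) -> np.ndarray:
        """Inclusive membership test (boundary-exact differences are correct)."""
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)


@dataclass
class AccuracyVector:
    """Per-trial correctness and confidence for one participant-session.

    ``trials`` has columns stimulus_id, correct (bool), confidence (int);
    ``interval`` is the decision band for rating data and None for 2AFC.
    """

    participant_id: str
    session: int
    condition: str
    trials: pd.DataFrame = field(repr=False)
    interval: AccuracyInterval | None = None

    @property
    def correct(self) -> np.ndarray:
        return self.trials["correct"].to_numpy(dtype=bool)

    @property
    def confidence(self) -> np.ndarray:
        return self.trials["confidence"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.trials)


def _single_key(df: pd.DataFrame) -> tuple[str, int]:
    keys = df[["participant_id", "session"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("expected trials of a single participant-session")
    pid, session = keys.iloc[0]
    return str(pid), int(session)


def participant_accuracy(
    series: pd.DataFrame,
    k: float = DEFAULT_K,
    condition: str = "",
    ddof: int = 1,
) -> AccuracyVector:
    """Score a difference series with the participant-based interval rule.

    Parameters
    ----------
    series : DataFrame
        One participant-session's output of
        :func:`emometa.normative.compute_differences` (columns participant_id,
        session, stimulus_id, difference, confidence).
    k : float
        Band half-width in SD units. The default 0.675 targets a 50/50 split
        under Gaussian differences.
    ddof : int
        Delta degrees of freedom for the SD; 1 (sample SD) by default.

    Notes
    -----
    Boundaries are inclusive. A zero-SD series yields a zero-width band, so
    only trials whose difference equals the mean exactly are correct.
    """
    if len(series) < 2:
        raise ValueError("participant accuracy needs at least 2 trials (SD undefined)")
    pid, session = _single_key(series)
    d = series["difference"].to_numpy(dtype=float)
    interval = AccuracyInterval(float(np.mean(d)), float(np.std(d, ddof=ddof)), k)
    out = series[["stimulus_id", "confidence"]].copy()
    out["correct"] = interval.contains(d)
    return AccuracyVector(pid, session, condition or "interval", out, interval)


_MATCH = {
    "valence": ("valence_response", "pleasant", "valence_class"),
    "arousal": ("arousal_response", "high", "arousal_class"),
}


def afc_accuracy(
    trials: pd.DataFrame, meta: pd.DataFrame, dimension: str
) -> AccuracyVector:
    """Score 2AFC trials of one participant-session against database classes.

    A valence trial is correct iff the response is 'pleasant' exactly when the
    stimulus is high-valence in the database; arousal analogously with
    'high' <-> high-arousal.
    """
    if dimension not in _MATCH:
        raise ValueError(f"unknown dimension {dimension!r}")
    resp_col, high_label, class_col = _MATCH[dimension]
    pid, session = _single_key(trials)
    classes = meta.set_index("stimulus_id")[class_col]
    missing = set(trials["stimulus_id"]) - set(classes.index)
    if missing:
        raise KeyError(f"stimulus {sorted(missing)[0]!r} missing from metadata")
    said_high = trials[resp_col].to_numpy() == high_label
    is_high = trials["stimulus_id"].map(classes).to_numpy() == "high"
    out = trials[["stimulus_id"]].copy()
    out["confidence"] = trials[f"{dimension}_confidence"].astype(int)
    out["correct"] = said_high == is_high
    return AccuracyVector(pid, session, "afc", out[["stimulus_id", "confidence", "correct"]])


def familiarity_split(
    trials: pd.DataFrame, cutoff: int = FAMILIARITY_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition trials into (high, low) familiarity at the cutoff.

    Familiarity >= cutoff (default 50) is high, < cutoff is low; the split is
    exhaustive and disjoint.
    """
    high = trials["familiarity"] >= cutoff
    return trials.loc[high].copy(), trials.loc[~high].copy()
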