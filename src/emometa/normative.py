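"""Per-trial differences between a participant's rating and normative standards.

Four normative standards are supported per dimension. Writing V for the
participant's own valence rating (A for arousal, analogously):

- ``diff``  : V - V_others, the participant's own estimate of what most
  people would feel for that stimulus.
- ``diff2`` : V - database norm for the stimulus (9-point norm rescaled onto
  the 0-100 collection scale).
- ``avg``   : V - mean of all participants' own ratings of that stimulus.
- ``oavg``  : V - mean of all participants' others-estimates for that stimulus.

The difference series is the raw material for the participant-based accuracy
rule: a trial is scored correct when its difference falls inside the
participant's own mean +/- 0.675 SD band (see :mod:`emometa.accuracy`).
"""

from __future__ import annotations

import pandas as pd

from .io import rescale_db_rating

__all__ = [
    "CONDITIONS",
    "DIMENSIONS",
    "per_stimulus_group_mean",
    "compute_differences",
    "difference_table",
]

CONDITIONS: tuple[str, ...] = ("diff", "diff2", "avg", "oavg")
DIMENSIONS: tuple[str, ...] = ("valence", "arousal")

_SELF_COL = {"valence": "valence", "arousal": "arousal"}
_OTHERS_COL = {"valence": "others_valence", "arousal": "others_arousal"}
_DB_COL = {"valence": "db_valence", "arousal": "db_arousal"}
_CONF_COL = {"valence": "valence_confidence", "arousal": "arousal_confidence"}


def _check(dimension: str, condition: str | None = None) -> None:
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if condition is not None and condition not in CONDITIONS:
        raise ValueError(f"unknown normative condition {condition!r}")


def per_stimulus_group_mean(
    trials: pd.DataFrame,
    dimension: str,
    source: str = "self_rating",
    leave_one_out: bool = False,
) -> pd.Series | pd.DataFrame:
    """Arithmetic mean rating per stimulus over all participants in the sample.

    ``source`` selects the averaged field: ``'self_rating'`` uses the
    participants' own ratings (the ``avg`` standard), ``'others_rating'``
    their estimates of what others would feel (the ``oavg`` standard). The
    averaging set includes every participant in ``trials``; pass
    ``leave_one_out=True`` to get, per participant, the mean over everyone
    else (returns a DataFrame indexed by (stimulus_id, participant_id)).
    """
    _check(dimension)
    if source == "self_rating":
        col = _SELF_COL[dimension]
    elif source == "others_rating":
        col = _OTHERS_COL[dimension]
    else:
        raise ValueError(f"unknown source {source!r}")
    if not leave_one_out:
        return trials.groupby("stimulus_id")[col].mean()
    g = trials.groupby("stimulus_id")[col]
    total, n = g.transform("sum"), g.transform("count")
    loo = (total - trials[col]) / (n - 1)
    out = trials[["stimulus_id", "participant_id"]].copy()
    out["mean"] = loo
    return out.set_index(["stimulus_id", "participant_id"])["mean"]


def compute_differences(
    trials: pd.DataFrame,
    dimension: str,
    condition: str,
    stimulus_meta: pd.DataFrame | None = None,
    group_means: pd.Series | None = None,
) -> pd.DataFrame:
    """Rating-minus-norm difference for every trial of one participant-session.

    Parameters
    ----------
    trials : DataFrame
        Rating-design trials of a single participant and session.
    dimension : {'valence', 'arousal'}
    condition : {'diff', 'diff2', 'avg', 'oavg'}
    stimulus_meta : DataFrame, required for ``diff2``
        Database norms; the 9-point rating is rescaled to 0-100 before
        subtraction.
    group_means : Series indexed by stimulus_id, required for ``avg``/``oavg``
        Output of :func:`per_stimulus_group_mean` with the matching source.

    Returns
    -------
    DataFrame with columns participant_id, session, stimulus_id, difference,
    confidence (the confidence report for the chosen dimension, carried along
    for the type-2 analysis).
    """
    _check(dimension, condition)
    own = trials[_SELF_COL[dimension]].astype(float)
    if condition == "diff":
        norm = trials[_OTHERS_COL[dimension]].astype(float)
        norm.index = trials.index
    elif condition == "diff2":
        if stimulus_meta is None:
            raise ValueError("condition 'diff2' requires stimulus_meta")
        db = stimulus_meta.set_index("stimulus_id")[_DB_COL[dimension]]
        missing = set(trials["stimulus_id"]) - set(db.index)
        if missing:
            raise KeyError(
                f"no database norm for stimulus {sorted(missing)[0]!r} "
                f"(condition 'diff2', dimension {dimension!r})"
            )
        norm = trials["stimulus_id"].map(db).map(rescale_db_rating)
    else:  # avg / oavg
        if group_means is None:
            raise ValueError(f"condition {condition!r} requires group_means")
        missing = set(trials["stimulus_id"]) - set(group_means.index)
        if missing:
            raise KeyError(
                f"no group mean for stimulus {sorted(missing)[0]!r} "
                f"(condition {condition!r}, dimension {dimension!r})"
            )
        norm = trials["stimulus_id"].map(group_means)
    out = trials[["participant_id", "session", "stimulus_id"]].copy()
    out["difference"] = own - norm
    out["confidence"] = trials[_CONF_COL[dimension]].astype(int)
    return out.reset_index(drop=True)


def difference_table(
    trials: pd.DataFrame,
    dimension: str,
    condition: str,
    stimulus_meta: pd.DataFrame | None = None,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Differences for every participant-session in a multi-participant table.

    For the sample-average standards (``avg``/``oavg``) the per-stimulus group
    means are computed within session, so multi-session designs with distinct
    stimulus sets per session are handled naturally.
    """
    _check(dimension, condition)
    pieces = []
    for session, strials in trials.groupby("session"):
        gm = None
        if condition in ("avg", "oavg"):
            source = "self_rating" if condition == "avg" else "others_rating"
            gm = per_stimulus_group_mean(
                strials, dimension, source, leave_one_out=leave_one_out
            )
        for _, ptrials in strials.groupby("participant_id"):
            if leave_one_out and gm is not None:
                pid = ptrials["participant_id"].iloc[0]
                means = gm.xs(pid, level="participant_id")
            else:
                means = gm
            pieces.append(
                compute_differences(
                    ptrials, dimension, condition, stimulus_meta, means
                )
            )
    return pd.concat(pieces, ignore_index=True)
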