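"""Trial-level data model: CSV schemas, validation, exclusions, scale conversion.

Two experimental designs are supported:

``rating``
    Slider-based reports. Each trial carries a valence and an arousal rating
    on the 0-100 scale, a 1-100 confidence report for each dimension, the
    participant's estimate of what most other people would feel
    (``others_valence`` / ``others_arousal``), and a 0-100 familiarity rating.

``afc``
    Two-alternative forced choice. Each trial carries a categorical valence
    response (``pleasant`` / ``unpleasant``), a categorical arousal response
    (``high`` / ``low``), per-dimension confidence (1-100), and familiarity.

Trial tables are plain :class:`pandas.DataFrame` objects in long format (one
trial per row, UTF-8 CSV on disk); the schemas below are the contract.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "RATING_COLUMNS",
    "AFC_COLUMNS",
    "STIMULUS_COLUMNS",
    "load_trials",
    "save_trials",
    "validate_trials",
    "load_stimulus_meta",
    "save_stimulus_meta",
    "validate_stimulus_meta",
    "exclude_invariant_participants",
    "rescale_db_rating",
    "class_from_db_rating",
    "category_label",
]


class SchemaError(ValueError):
    """The table is missing required columns or has an unknown design."""


class ValidationError(ValueError):
    """A cell value violates the schema (range, label set, or uniqueness)."""


# column -> (min, max) for numeric range checks
_RATING_RANGES = {
    "valence": (0, 100),
    "arousal": (0, 100),
    "valence_confidence": (1, 100),
    "arousal_confidence": (1, 100),
    "others_valence": (0, 100),
    "others_arousal": (0, 100),
    "familiarity": (0, 100),
}

_AFC_RANGES = {
    "valence_confidence": (1, 100),
    "arousal_confidence": (1, 100),
    "familiarity": (0, 100),
}

_AFC_LABELS = {
    "valence_response": ("pleasant", "unpleasant"),
    "arousal_response": ("high", "low"),
}

_KEY_COLUMNS = ["participant_id", "session", "stimulus_id"]

RATING_COLUMNS: tuple[str, ...] = tuple(_KEY_COLUMNS) + tuple(_RATING_RANGES)
AFC_COLUMNS: tuple[str, ...] = (
    tuple(_KEY_COLUMNS) + tuple(_AFC_LABELS) + tuple(_AFC_RANGES)
)
STIMULUS_COLUMNS: tuple[str, ...] = (
    "stimulus_id",
    "database",
    "db_valence",
    "db_arousal",
    "valence_class",
    "arousal_class",
    "category",
)

#: Per-design rated parameters scanned by the invariant-participant exclusion.
RATED_PARAMETERS = {
    "rating": tuple(_RATING_RANGES),
    "afc": tuple(_AFC_LABELS) + tuple(_AFC_RANGES),
}


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def validate_trials(trials: pd.DataFrame, design: str) -> None:
    """Validate a trial table in place; raise on the first violation.

    Checks column presence, numeric ranges (closed intervals as collected),
    categorical label sets for the forced-choice design, and uniqueness of
    the (participant_id, session, stimulus_id) key. Error messages carry
    0-based row indices into the table.
    """
    if design == "rating":
        _require_columns(trials, RATING_COLUMNS)
        ranges, labels = _RATING_RANGES, {}
    elif design == "afc":
        _require_columns(trials, AFC_COLUMNS)
        ranges, labels = _AFC_RANGES, _AFC_LABELS
    else:
        raise SchemaError(f"unknown design {design!r}; expected 'rating' or 'afc'")

    for col, (lo, hi) in ranges.items():
        values = pd.to_numeric(trials[col], errors="coerce")
        bad = values.isna() | (values < lo) | (values > hi)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}, row {row}: value {trials[col].iloc[row]!r} "
                f"outside [{lo}, {hi}]"
            )
    for col, allowed in labels.items():
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}, row {row}: label {trials[col].iloc[row]!r} "
                f"not in {allowed}"
            )
    dup = trials.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (participant_id, session, stimulus_id) key "
            f"{tuple(trials.loc[trials.index[row], _KEY_COLUMNS])}"
        )


def load_trials(path, design: str) -> pd.DataFrame:
    """Read a trial CSV and validate it against the design's schema."""
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    validate_trials(df, design)
    df["session"] = df["session"].astype(int)
    numeric = _RATING_RANGES if design == "rating" else _AFC_RANGES
    for col in numeric:
        df[col] = df[col].astype(int)
    return df


def save_trials(trials: pd.DataFrame, path, design: str) -> None:
    """Write a validated trial table as UTF-8 CSV (RFC-4180 quoting)."""
    validate_trials(trials, design)
    cols = list(RATING_COLUMNS if design == "rating" else AFC_COLUMNS)
    trials[cols].to_csv(path, index=False)


def validate_stimulus_meta(meta: pd.DataFrame) -> None:
    _require_columns(meta, STIMULUS_COLUMNS)
    for col in ("db_valence", "db_arousal"):
        values = pd.to_numeric(meta[col], errors="coerce")
        bad = values.isna() | (values < 1) | (values > 9)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}, row {row}: database rating "
                f"{meta[col].iloc[row]!r} outside [1, 9]"
            )
    for col in ("valence_class", "arousal_class"):
        bad = ~meta[col].isin(("high", "low"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"column {col!r}, row {row}: expected 'high'/'low'")
    expected = meta.apply(
        lambda r: category_label(r["valence_class"], r["arousal_class"]), axis=1
    )
    bad = meta["category"] != expected
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {row}: category {meta['category'].iloc[row]!r} inconsistent with "
            f"classes ({meta['valence_class'].iloc[row]}, {meta['arousal_class'].iloc[row]})"
        )
    if meta["stimulus_id"].duplicated().any():
        raise ValidationError("duplicate stimulus_id in stimulus metadata")


def load_stimulus_meta(path) -> pd.DataFrame:
    """Read the stimulus-metadata CSV (database norms and class labels)."""
    meta = pd.read_csv(path, dtype={"stimulus_id": str})
    validate_stimulus_meta(meta)
    return meta


def save_stimulus_meta(meta: pd.DataFrame, path) -> None:
    validate_stimulus_meta(meta)
    meta[list(STIMULUS_COLUMNS)].to_csv(path, index=False)


def category_label(valence_class: str, arousal_class: str) -> str:
    """Quadrant label (HVHA/HVLA/LVLA/LVHA) from the two class labels."""
    v = "HV" if valence_class == "high" else "LV"
    a = "HA" if arousal_class == "high" else "LA"
    return v + a


def exclude_invariant_participants(
    trials: pd.DataFrame,
    design: str = "rating",
    whole_participant: bool = False,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Drop participants who gave the same value on every trial of a parameter.

    A participant-session is excluded if, for at least one rated parameter
    (each rating, each confidence, each others-rating, familiarity, or a
    forced-choice response), every trial of that participant in that session
    carries an identical value. Flat responding on any single parameter is
    treated as non-compliance with the task.

    Parameters
    ----------
    trials : DataFrame
        Validated trial table.
    design : {'rating', 'afc'}
        Which parameter set to scan.
    whole_participant : bool
        When True, a participant flagged in any session is removed from all
        sessions; by default only the offending sessions are dropped.

    Returns
    -------
    kept : DataFrame
        The surviving trials (original row order preserved).
    excluded : list of (participant_id, session)
        Keys of the dropped participant-sessions, sorted.
    """
    params = RATED_PARAMETERS[design]
    if trials.empty:
        return trials.copy(), []
    nunique = trials.groupby(["participant_id", "session"])[list(params)].nunique()
    flagged = nunique[(nunique == 1).any(axis=1)].index
    excluded = sorted((str(p), int(s)) for p, s in flagged)
    if whole_participant:
        bad_pids = {p for p, _ in excluded}
        mask = trials["participant_id"].isin(bad_pids)
        excluded = sorted(
            (str(p), int(s))
            for p, s in trials.loc[mask, ["participant_id", "session"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
    else:
        keys = pd.MultiIndex.from_frame(trials[["participant_id", "session"]])
        mask = keys.isin(flagged)
    return trials.loc[~mask].copy(), excluded


def rescale_db_rating(x):
    """Map a 9-point database norm onto the 0-100 collection scale.

    Linear with the endpoints pinned (1 -> 0, 9 -> 100), so 5 -> 50; the only
    affine map that preserves order and the scale midpoint. Accepts scalars
    or arrays.

    Raises
    ------
    ValueError
        If any value falls outside [1, 9].
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 1) or np.any(arr > 9) or np.any(np.isnan(arr)):
        raise ValueError("database rating outside the 9-point scale [1, 9]")
    out = (arr - 1.0) / 8.0 * 100.0
    return float(out) if np.isscalar(x) else out


def class_from_db_rating(rating: float) -> str:
    """'high'/'low' class from a 9-point norm: above 5 is high, below 5 low.

    A rating of exactly 5 is ambiguous under this rule and raises.
    """
    if rating > 5:
        return "high"
    if rating < 5:
        return "low"
    raise ValidationError("database rating of exactly 5 has no high/low class")
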