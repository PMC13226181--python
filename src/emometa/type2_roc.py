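"""Type-2 ROC curves and AUROC2 from (correct, confidence) pairs.

The type-2 task asks how well confidence discriminates the participant's own
correct from incorrect type-1 responses. Sweeping a criterion X over the
confidence scale, each trial is classified

    true positive   correct   and confidence >= X
    false negative  correct   and confidence <  X
    false positive  incorrect and confidence >= X
    true negative   incorrect and confidence <  X

giving TPR = TP/(TP+FN) and FPR = FP/(FP+TN) per criterion. The criterion
grid is 5, 10, ..., 100; the curve is completed with the (0,0) and (1,1)
anchors and integrated with the trapezoidal rule. AUROC2 = 0.5 is chance
(confidence carries no information about accuracy), 1.0 is perfect
metacognitive access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import AccuracyVector, afc_accuracy, participant_accuracy
from .normative import difference_table

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_MIN_CLASS",
    "Confusion",
    "Roc2Curve",
    "UndefinedCurveWarning",
    "confusion_at_criterion",
    "roc_points",
    "auroc2",
    "auroc2_from_vector",
    "auroc2_for_participant",
    "rating_auroc2_table",
    "afc_auroc2_table",
]

#: Confidence criteria swept to build the curve: 5, 10, ..., 100.
DEFAULT_GRID: tuple[int, ...] = tuple(range(5, 101, 5))

#: Minimum number of correct and of incorrect trials for a usable curve.
DEFAULT_MIN_CLASS = 5


class UndefinedCurveWarning(UserWarning):
    """The trial set cannot support a type-2 ROC curve (single class / too few)."""


@dataclass(frozen=True)
class Confusion:
    """Type-2 confusion counts at a single confidence criterion."""

    criterion: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)


@dataclass
class Roc2Curve:
    """Type-2 ROC curve: per-criterion confusions, (FPR, TPR) points, area."""

    confusions: list[Confusion] = field(default_factory=list)
    points: list[tuple[float, float]] = field(default_factory=list)
    n_correct: int = 0
    n_incorrect: int = 0

    @property
    def defined(self) -> bool:
        return bool(self.points)

    def integration_points(self) -> np.ndarray:
        """Unique curve points with (0,0)/(1,1) anchors, sorted by (fpr, tpr)."""
        pts = set(self.points) | {(0.0, 0.0), (1.0, 1.0)}
        return np.array(sorted(pts))


def _as_arrays(acc) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(acc, AccuracyVector):
        return acc.correct, acc.confidence
    correct, confidence = acc
    return np.asarray(correct, dtype=bool), np.asarray(confidence, dtype=int)


def confusion_at_criterion(acc, criterion: int) -> Confusion:
    """Count TP/FP/TN/FN at one criterion (confidence >= X counts as high)."""
    if not 1 <= criterion <= 100:
        raise ValueError("criterion must lie in 1..100")
    correct, conf = _as_arrays(acc)
    high = conf >= criterion
    return Confusion(
        criterion=int(criterion),
        tp=int(np.sum(correct & high)),
        fn=int(np.sum(correct & ~high)),
        fp=int(np.sum(~correct & high)),
        tn=int(np.sum(~correct & ~high)),
    )


def roc_points(acc, grid=DEFAULT_GRID) -> Roc2Curve:
    """Build the per-criterion curve; undefined (empty) when a class is absent."""
    correct, conf = _as_arrays(acc)
    n_correct = int(np.sum(correct))
    n_incorrect = int(correct.size - n_correct)
    curve = Roc2Curve(n_correct=n_correct, n_incorrect=n_incorrect)
    if n_correct == 0 or n_incorrect == 0:
        return curve
    for x in grid:
        c = confusion_at_criterion((correct, conf), x)
        curve.confusions.append(c)
        curve.points.append((c.fpr, c.tpr))
    return curve


def auroc2(curve: Roc2Curve) -> float:
    """Trapezoidal area under the anchored, de-duplicated, sorted curve.

    Returns NaN (with an :class:`UndefinedCurveWarning`) when the curve is
    undefined, mirroring participants dropped for lacking enough trials in a
    correctness class.
    """
    if not curve.defined:
        warnings.warn(
            "type-2 ROC undefined (needs both correct and incorrect trials); "
            "returning NaN",
            UndefinedCurveWarning,
            stacklevel=2,
        )
        return float("nan")
    pts = curve.integration_points()
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auroc2_from_vector(
    acc: AccuracyVector,
    grid=DEFAULT_GRID,
    min_class: int = DEFAULT_MIN_CLASS,
) -> float:
    """AUROC2 for one participant-session, NaN if either class is too small."""
    correct = acc.correct
    n_correct = int(correct.sum())
    n_incorrect = int(correct.size - n_correct)
    if min(n_correct, n_incorrect) < min_class:
        warnings.warn(
            f"participant {acc.participant_id} session {acc.session}: only "
            f"{n_correct} correct / {n_incorrect} incorrect trials "
            f"(minimum {min_class} each); AUROC2 set to NaN",
            UndefinedCurveWarning,
            stacklevel=2,
        )
        return float("nan")
    return auroc2(roc_points(acc, grid))


def auroc2_for_participant(
    trials: pd.DataFrame,
    dimension: str,
    condition: str,
    stimulus_meta: pd.DataFrame | None = None,
    group_means=None,
    k: float = 0.675,
    grid=DEFAULT_GRID,
    min_class: int = DEFAULT_MIN_CLASS,
) -> float:
    """Full pipeline for one participant-session of rating trials.

    Composition of difference computation, the participant-based interval
    accuracy rule, and the type-2 ROC sweep; deterministic given inputs.
    For the sample-average standards pass the per-stimulus ``group_means``
    computed over the whole (kept) sample.
    """
    from .normative import compute_differences

    series = compute_differences(trials, dimension, condition, stimulus_meta, group_means)
    acc = participant_accuracy(series, k=k, condition=condition)
    return auroc2_from_vector(acc, grid, min_class)


def rating_auroc2_table(
    trials: pd.DataFrame,
    dimension: str,
    condition: str,
    stimulus_meta: pd.DataFrame | None = None,
    k: float = 0.675,
    grid=DEFAULT_GRID,
    min_class: int = DEFAULT_MIN_CLASS,
) -> pd.DataFrame:
    """Per participant-session AUROC2 for a rating-design trial table.

    Group means for the ``avg``/``oavg`` standards are computed within
    session over all participants present in ``trials`` (apply exclusions
    first). Returns columns participant_id, session, dimension, condition,
    n_correct, n_incorrect, auroc2.
    """
    diffs = difference_table(trials, dimension, condition, stimulus_meta)
    rows = []
    for (pid, session), series in diffs.groupby(["participant_id", "session"]):
        acc = participant_accuracy(series, k=k, condition=condition)
        rows.append(
            {
                "participant_id": pid,
                "session": int(session),
                "dimension": dimension,
                "condition": condition,
                "n_correct": int(acc.correct.sum()),
                "n_incorrect": int((~acc.correct).sum()),
                "auroc2": auroc2_from_vector(acc, grid, min_class),
            }
        )
    return pd.DataFrame(rows)


def afc_auroc2_table(
    trials: pd.DataFrame,
    meta: pd.DataFrame,
    dimension: str,
    grid=DEFAULT_GRID,
    min_class: int = DEFAULT_MIN_CLASS,
) -> pd.DataFrame:
    """Per participant-session AUROC2 for a forced-choice trial table."""
    rows = []
    for (pid, session), ptrials in trials.groupby(["participant_id", "session"]):
        acc = afc_accuracy(ptrials, meta, dimension)
        rows.append(
            {
                "participant_id": pid,
                "session": int(session),
                "dimension": dimension,
                "condition": "afc",
                "n_correct": int(acc.correct.sum()),
                "n_incorrect": int((~acc.correct).sum()),
                "auroc2": auroc2_from_vector(acc, grid, min_class),
            }
        )
    return pd.DataFrame(rows)
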