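"""One-predictor linear discriminant of shunt response on log NPV.

The predictor is the (natural) log of NPV at the voxel/band selected by the
group comparison. With equal priors and pooled variance the 1-D Fisher
discriminant boundary sits at the midpoint of the class means, so the model
normalizes to a unit weight on log NPV:

    score = w * ln(NPV) + intercept,   w in {+1, -1},

with positive score predicting shunt response. Generalization is assessed by
leave-one-subject-out cross-validation: each subject is classified by the
model refitted on the remaining cohort, and the confusion counts yield
accuracy, positive predictive value and negative predictive value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "responder"


class DegenerateDataError(ValueError):
    """The training data cannot support a discriminant fit."""


@dataclass
class DiscriminantModel:
    """score = weight * log(NPV) + intercept; score > 0 predicts response."""

    voxel_id: int
    band: str
    weight: float
    intercept: float
    positive_class: str = POSITIVE_CLASS
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise ValueError("a fitted discriminant must have a nonzero weight")


@dataclass
class CVReport:
    """Leave-one-subject-out confusion counts and derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    scores: tuple[float, ...] = field(default=())       # per left-out subject
    predicted: tuple[bool, ...] = field(default=())     # True = responder

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv_pred(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "ppv": self.ppv, "npv_pred": self.npv_pred,
        }


def _check_xy(x: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype == bool:
        y = lab
    else:
        y = np.array([str(lbl) == POSITIVE_CLASS for lbl in lab])
    if x.ndim != 1 or x.shape[0] != y.shape[0]:
        raise ValueError("x and labels must be aligned 1-D sequences")
    return x, y


def fit_discriminant(
    x: np.ndarray,
    labels,
    voxel_id: int = -1,
    band: str = "",
    log_base: float = math.e,
) -> DiscriminantModel:
    """Equal-prior 1-D Fisher discriminant on per-subject log NPV values.

    ``x`` holds the already-log-transformed NPV per subject. The boundary is
    the midpoint of the two class means; the weight is normalized to +1 when
    responders have the larger mean (and -1 otherwise) so that a positive
    score always predicts response.
    """
    x, y = _check_xy(x, labels)
    if y.all() or not y.any():
        raise DegenerateDataError("both classes must be present to fit")
    m_pos, m_neg = x[y].mean(), x[~y].mean()
    ss = ((x[y] - m_pos) ** 2).sum() + ((x[~y] - m_neg) ** 2).sum()
    if ss <= 0:
        raise DegenerateDataError("zero pooled within-class variance")
    w = 1.0 if m_pos >= m_neg else -1.0
    intercept = -w * 0.5 * (m_pos + m_neg)
    return DiscriminantModel(
        voxel_id=voxel_id, band=band, weight=w, intercept=intercept,
        log_base=log_base,
    )


def predict_score(model: DiscriminantModel, npv_value: float) -> float:
    """Evaluate the prediction score at an NPV value (> 0).

    score = weight * log(npv_value) + intercept, with the model's log base
    (natural by default); positive scores predict shunt response.
    """
    if npv_value <= 0:
        raise ValueError(f"NPV must be positive, got {npv_value}")
    return model.weight * math.log(npv_value, model.log_base) + model.intercept


def _score_x(model: DiscriminantModel, x: float) -> float:
    """Score directly from an already-log-transformed value."""
    return model.weight * x + model.intercept


def loocv(x: np.ndarray, labels, log_base: float = math.e) -> CVReport:
    """Leave-one-subject-out cross-validation of the 1-D discriminant.

    Deterministic: every fold refits on the remaining n-1 subjects and
    classifies the held-out subject by the sign of its score (score > 0
    predicts response; a boundary score of exactly 0 counts as negative).
    """
    x, y = _check_xy(x, labels)
    n = x.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs a cohort of at least 4 subjects")
    tp = fp = tn = fn = 0
    scores, preds = [], []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if y[keep].all() or not y[keep].any():
            raise DegenerateDataError(
                f"fold {i} loses one class entirely; cohort too small"
            )
        model = fit_discriminant(x[keep], y[keep], log_base=log_base)
        s = _score_x(model, x[i])
        pred = s > 0
        scores.append(s)
        preds.append(bool(pred))
        if pred and y[i]:
            tp += 1
        elif pred and not y[i]:
            fp += 1
        elif not pred and not y[i]:
            tn += 1
        else:
            fn += 1
    return CVReport(tp=tp, fp=fp, tn=tn, fn=fn,
                    scores=tuple(scores), predicted=tuple(preds))


def export_scores_csv(report: CVReport, x: np.ndarray, labels, path) -> None:
    """Per-subject CSV: subject_id, x, score, label, predicted."""
    import pandas as pd

    pd.DataFrame({
        "subject_id": np.arange(len(x)),
        "x": np.asarray(x, dtype=float),
        "score": report.scores,
        "label": list(labels),
        "predicted": [POSITIVE_CLASS if p else "nonresponder" for p in report.predicted],
    }).to_csv(path, index=False)
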