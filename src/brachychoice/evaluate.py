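"""Evaluation metrics, threshold utilities, and the ablation harness.

An insertion needing the interstitial Syed applicator is the *positive*
case: sensitivity is the rate at which necessary invasive applicators are
recognized, specificity the rate at which unnecessary invasive procedures
are avoided.  Metrics with an empty denominator are reported as NaN, never
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassMissing, InputError
from .structures import SYED, TANDO


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with Syed as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred, truth) -> ConfusionMatrix:
    """Standard 2x2 counts; labels are SYED (1) / TANDO (0)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth lengths differ")
    return ConfusionMatrix(
        tp=int(((pred == SYED) & (truth == SYED)).sum()),
        fp=int(((pred == SYED) & (truth == TANDO)).sum()),
        tn=int(((pred == TANDO) & (truth == TANDO)).sum()),
        fn=int(((pred == TANDO) & (truth == SYED)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions; NaN when undefined."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else float("nan")
    acc = (cm.tp + cm.tn) / cm.total if cm.total else float("nan")
    return sens, spec, acc


def metrics_percent(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Metrics as percentages rounded to one decimal (table convention)."""
    return tuple(round(m * 100, 1) for m in metrics(cm))


def threshold_sweep(scores, truth, thresholds=None):
    """Threshold maximizing accuracy, with the full sweep curve.

    Ties break toward 0.5 (then toward the smaller threshold).  Returns
    (best threshold, DataFrame of threshold/accuracy).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ClassMissing("threshold sweep needs both classes")
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 201), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    acc = np.array([((scores >= t).astype(int) == truth).mean() for t in thresholds])
    best = acc.max()
    candidates = thresholds[acc == best]
    order = np.lexsort((candidates, np.abs(candidates - 0.5)))
    curve = pd.DataFrame({"threshold": thresholds, "accuracy": acc})
    return float(candidates[order[0]]), curve


def ablation_table(full_cv, mask_cv) -> pd.DataFrame:
    """Paired per-fold table for FULL vs MASK_ONLY input modes.

    2 modes x (k folds + 1 summary row), mirroring the paired comparison of
    validation accuracy with and without the distance channels.
    """
    rows = []
    for mode, cv in (("full", full_cv), ("mask_only", mask_cv)):
        for _, r in cv.per_fold.iterrows():
            rows.append(
                {
                    "mode": mode,
                    "fold": int(r["fold"]),
                    "train_accuracy": r["train_accuracy"],
                    "val_accuracy": r["val_accuracy"],
                }
            )
        rows.append(
            {
                "mode": mode,
                "fold": "mean",
                "train_accuracy": cv.per_fold["train_accuracy"].mean(),
                "val_accuracy": cv.mean_val_accuracy,
            }
        )
    return pd.DataFrame(rows)
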