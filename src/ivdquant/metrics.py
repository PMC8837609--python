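"""Segmentation overlap metrics and agreement statistics.

mDice and mIoU average the per-class Dice coefficient 2|G∩P|/(|G|+|P|) and
Jaccard index |G∩P|/|G∪P| over the C segmentation classes.  macro-F1
summarises a grade confusion table.  ICC(A,1) is the single-measure,
absolute-agreement intraclass correlation from a two-way model (McGraw &
Wong type A), the statistic used to compare automated and manual disc
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "dice_per_class",
    "iou_per_class",
    "mdice",
    "miou",
    "macro_f1",
    "icc_absolute_agreement",
    "ICCResult",
]


def _per_class_counts(pred: np.ndarray, truth: np.ndarray, n_classes: int):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = np.bincount(truth.ravel()[(pred == truth).ravel()],
                        minlength=n_classes)[:n_classes]
    np_ = np.bincount(pred.ravel(), minlength=n_classes)[:n_classes]
    nt = np.bincount(truth.ravel(), minlength=n_classes)[:n_classes]
    return inter.astype(float), np_.astype(float), nt.astype(float)


def dice_per_class(pred, truth, n_classes: int = 14):
    """Per-class Dice; classes absent from both masks score 1 (flagged).

    Returns ``(dice, vacuous)`` where ``vacuous[c]`` marks classes with no
    pixels in either mask, whose agreement is vacuously perfect.
    """
    inter, np_, nt = _per_class_counts(pred, truth, n_classes)
    vacuous = (np_ + nt) == 0
    denom = np.where(vacuous, 1.0, np_ + nt)
    dice = np.where(vacuous, 1.0, 2.0 * inter / denom)
    return dice, vacuous


def iou_per_class(pred, truth, n_classes: int = 14):
    """Per-class IoU (Jaccard); vacuous classes score 1 (flagged)."""
    inter, np_, nt = _per_class_counts(pred, truth, n_classes)
    union = np_ + nt - inter
    vacuous = (np_ + nt) == 0
    iou = np.where(vacuous, 1.0, inter / np.where(union == 0, 1.0, union))
    return iou, vacuous


def mdice(pred, truth, n_classes: int = 14) -> float:
    """Mean per-class Dice coefficient over the ``n_classes`` classes."""
    return float(dice_per_class(pred, truth, n_classes)[0].mean())


def miou(pred, truth, n_classes: int = 14) -> float:
    """Mean per-class intersection-over-union over the ``n_classes`` classes."""
    return float(iou_per_class(pred, truth, n_classes)[0].mean())


def macro_f1(table: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(precision, recall, macroF1) from a (true × predicted) count table.

    Per-class F1 is the harmonic mean of precision and recall (0 where
    undefined); macroF1 averages F1 over the classes with nonzero support
    in the truth, mirroring grade tables where an absent grade is left
    blank.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("confusion table must be square")
    if table.sum() <= 0:
        raise ValueError("empty confusion table")
    tp = np.diag(table)
    fp = table.sum(axis=0) - tp
    fn = table.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    support = (tp + fn) > 0
    return precision, recall, float(f1[support].mean())


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    n_raters: int


def icc_absolute_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way, absolute-agreement, single-measure ICC.

    ``ratings`` is an (n subjects × k raters) matrix with no missing cells.
    The estimate and its F-based confidence interval follow the standard
    two-way mean-squares decomposition (rows = subjects, columns = raters);
    the estimator is the same whether the interaction term is present or
    not.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing or non-finite cells")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # Satterthwaite df for the absolute-agreement interval
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1)
                + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_c = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f_l * mse) / (f_l * denom_c + n * msr)
        upper = n * (f_u * msr - mse) / (denom_c + n * f_u * msr)
    else:  # perfect agreement
        lower = upper = 1.0
    return ICCResult(float(icc), (float(lower), float(upper)), n, k)
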