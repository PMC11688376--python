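"""Segmentation losses, region-overlap metrics, consensus ground truth, and
clinician-vs-machine agreement statistics.

Losses accept soft probability maps (training use) or binary maps
(evaluation use); the overlap terms are soft intersections ``sum(p * y)``
so the losses are differentiable in ``p``.  Region metrics operate on
binary masks only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationScores",
    "AgreementStats",
    "region_scores",
    "dice_loss",
    "jaccard_loss",
    "bce_loss",
    "consensus_mask",
    "agreement",
    "BCE_EPS",
]

#: Probability clip applied before logarithms in the binary cross-entropy.
BCE_EPS = 1e-7


@dataclass(frozen=True)
class SegmentationScores:
    """Region-based overlap scores for one (ground truth, prediction) pair."""

    iou: float
    dice: float
    recall: float
    precision: float

    def to_dict(self) -> dict:
        return {"iou": self.iou, "dice": self.dice,
                "recall": self.recall, "precision": self.precision}


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between paired gestational-age estimates.

    Differences are ``test - reference``; ``loa_*`` are the 95% limits of
    agreement ``mean_diff +/- 1.96 * SD`` with the sample (n-1) standard
    deviation.  ``plot_x``/``plot_y`` are the Bland-Altman coordinates
    (per-pair mean on x, difference on y).
    """

    mean_diff: float
    loa_lower: float
    loa_upper: float
    mae: float
    n: int
    plot_x: np.ndarray = field(repr=False)
    plot_y: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"mean_diff": self.mean_diff, "loa_lower": self.loa_lower,
                "loa_upper": self.loa_upper, "mae": self.mae, "n": self.n}


def _pair(a, b, name_a="gt", name_b="pred") -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(
            f"{name_a} shape {a.shape} != {name_b} shape {b.shape}")
    return a, b


def region_scores(gt, pred) -> SegmentationScores:
    """IoU, Dice, Recall, Precision between binary masks.

    IoU = |I|/|U|, Dice = 2|I|/(|GT|+|PR|), Recall = |I|/|GT|,
    Precision = |I|/|PR| on pixel sets.  Empty-denominator convention:
    a metric is 1 when both operands it compares are empty and 0 when
    exactly one is.
    """
    gt, pred = _pair(gt, pred)
    g = gt.astype(bool)
    p = pred.astype(bool)
    inter = float(np.count_nonzero(g & p))
    ng = float(np.count_nonzero(g))
    npr = float(np.count_nonzero(p))
    union = ng + npr - inter

    def ratio(num, den, both_empty):
        if den == 0:
            return 1.0 if both_empty else 0.0
        return num / den

    both = ng == 0 and npr == 0
    return SegmentationScores(
        iou=ratio(inter, union, both),
        dice=ratio(2 * inter, ng + npr, both),
        recall=ratio(inter, ng, ng == 0),
        precision=ratio(inter, npr, npr == 0),
    )


def _soft_terms(pred, gt) -> tuple[float, float, float]:
    pred, gt = _pair(np.asarray(pred, dtype=float), np.asarray(gt, dtype=float),
                     "pred", "gt")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float((pred * gt).sum()), float(pred.sum()), float(gt.sum())


def dice_loss(pred, gt, smooth: float = 1.0) -> float:
    """Dice loss ``1 - (2*sum(p*y) + s) / (sum(p) + sum(y) + s)``.

    ``smooth`` stabilizes the empty-mask case; with ``smooth=0`` and binary
    ``pred`` this equals ``1 - Dice``.
    """
    sp_gt, sp, sg = _soft_terms(pred, gt)
    den = sp + sg + smooth
    if den == 0:
        return 0.0  # both empty, smooth=0: perfect agreement
    return 1.0 - (2.0 * sp_gt + smooth) / den


def jaccard_loss(pred, gt, smooth: float = 1.0) -> float:
    """Jaccard loss ``1 - (sum(p*y) + s) / (sum(p) + sum(y) - sum(p*y) + s)``.

    With ``smooth=0`` and binary ``pred`` this equals ``1 - IoU``.
    """
    sp_gt, sp, sg = _soft_terms(pred, gt)
    den = sp + sg - sp_gt + smooth
    if den == 0:
        return 0.0
    return 1.0 - (sp_gt + smooth) / den


def bce_loss(pred, gt, eps: float = BCE_EPS) -> float:
    """Pixel-mean binary cross-entropy.

    ``-(1/N) * sum(y*log(p) + (1-y)*log(1-p))`` with probabilities clipped
    to ``[eps, 1-eps]``.  Equals ``ln 2`` exactly for ``p == 0.5`` everywhere.
    """
    pred, gt = _pair(np.asarray(pred, dtype=float), np.asarray(gt, dtype=float),
                     "pred", "gt")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-(gt * np.log(p) + (1.0 - gt) * np.log1p(-p)).mean())


def consensus_mask(masks) -> np.ndarray:
    """Pixel-wise AND of >= 2 equally sized binary masks.

    Mirrors the consensus ground-truth protocol: the reference region is the
    intersection of all annotators' masks.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks for a consensus, got {len(masks)}")
    out = np.asarray(masks[0]).astype(bool)
    for m in masks[1:]:
        arr = np.asarray(m).astype(bool)
        if arr.shape != out.shape:
            raise ValueError("all masks must share the same dimensions")
        out = out & arr
    return out.astype(np.uint8)


def agreement(pairs, direction: str = "test-reference") -> AgreementStats:
    """Bland-Altman statistics over paired (reference, test) estimates.

    Parameters
    ----------
    pairs : iterable of (reference, test)
        Paired measurements in weeks, e.g. (clinician GW, automated GW).
    direction : {"test-reference", "reference-test"}
        Sign convention for the differences (default: automated minus
        clinician).

    Returns
    -------
    AgreementStats
        Mean difference, symmetric 95% limits of agreement
        (mean +/- 1.96 * sample SD), mean absolute error, and the
        Bland-Altman plot coordinates.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (reference, test) pairs")
    ref, test = arr[:, 0], arr[:, 1]
    if direction == "test-reference":
        d = test - ref
    elif direction == "reference-test":
        d = ref - test
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    return AgreementStats(
        mean_diff=mean_diff,
        loa_lower=mean_diff - half,
        loa_upper=mean_diff + half,
        mae=float(np.abs(d).mean()),
        n=int(arr.shape[0]),
        plot_x=(ref + test) / 2.0,
        plot_y=d,
    )
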