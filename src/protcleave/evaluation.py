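"""Binary-classification evaluation for cleavage-site scores.

Sensitivity, specificity, accuracy and Matthews correlation are computed
in two algebraically equivalent parameterizations — the textbook
TP/TN/FP/FN form and the intuitive miscount form written in terms of the
class totals N+ and N- and the miscounts N-+ (positives called negative)
and N+- (negatives called positive) — and cross-checked against each
other before being reported. ROC/AUC and specificity-level thresholding
round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

log = logging.getLogger("protcleave")

#: Smallest increment of the score grid, used to place a threshold just
#: above the largest negative score at the 100% specificity level.
SCORE_EPS = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    # The miscount parameterization.
    @property
    def n_pos(self) -> int:  # N+
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:  # N-
        return self.tn + self.fp

    @property
    def miss_pos(self) -> int:  # N-+: positives predicted negative
        return self.fn

    @property
    def miss_neg(self) -> int:  # N+-: negatives predicted positive
        return self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    threshold: float | None = None
    auc: float | None = None
    degenerate: tuple[str, ...] = ()


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Tally a confusion table; a site is called positive iff its score is
    >= the threshold (ties count as positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _metrics_confusion_form(c: ConfusionCounts) -> tuple[float, float, float, float]:
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else np.nan
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp else np.nan
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom) if denom else np.nan
    )
    return sn, sp, acc, mcc


def _metrics_miscount_form(c: ConfusionCounts) -> tuple[float, float, float, float]:
    n_pos, n_neg = c.n_pos, c.n_neg
    mp, mn = c.miss_pos, c.miss_neg
    sn = 1 - mp / n_pos if n_pos else np.nan
    sp = 1 - mn / n_neg if n_neg else np.nan
    acc = 1 - (mp + mn) / (n_pos + n_neg)
    if n_pos and n_neg:
        denom = (1 + (mn - mp) / n_pos) * (1 + (mp - mn) / n_neg)
        mcc = (1 - (mp / n_pos + mn / n_neg)) / np.sqrt(denom) if denom > 0 else np.nan
    else:
        mcc = np.nan
    return sn, sp, acc, mcc


def metrics(counts: ConfusionCounts, threshold: float | None = None) -> MetricsReport:
    """Sn, Sp, Acc, MCC computed in both parameterizations and asserted
    numerically equal. Undefined denominators are flagged and reported as
    0 (the MCC convention for vanishing marginals)."""
    a = _metrics_confusion_form(counts)
    b = _metrics_miscount_form(counts)
    for name, va, vb in zip(("Sn", "Sp", "Acc", "MCC"), a, b):
        if not (np.isnan(va) and np.isnan(vb)) and not np.isclose(
            va, vb, rtol=0, atol=1e-9, equal_nan=True
        ):
            raise AssertionError(
                f"metric formulations disagree for {name}: {va} vs {vb}"
            )
    degenerate = []
    sn, sp, acc, mcc = a
    if np.isnan(sn):
        degenerate.append("Sn")
        sn = 0.0
    if np.isnan(sp):
        degenerate.append("Sp")
        sp = 0.0
    if np.isnan(mcc):
        degenerate.append("MCC")
        mcc = 0.0
    return MetricsReport(
        sn=float(sn),
        sp=float(sp),
        acc=float(acc),
        mcc=float(mcc),
        threshold=threshold,
        degenerate=tuple(degenerate),
    )


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """AUC by trapezoidal integration over all distinct score thresholds,
    plus the ROC curve points (fpr, tpr, thresholds). Tied scores follow
    the rank/Mann-Whitney equivalence."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, np.asarray(scores, dtype=float))
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr, thresholds


def threshold_at_specificity(
    neg_scores: np.ndarray, target_specificity: float
) -> float:
    """Smallest threshold t with fraction(neg_scores < t) >= target.

    At target 1.0 the threshold sits one score-grid increment above the
    largest negative score, so no defining negative passes.
    """
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if neg.size == 0:
        raise ValueError("need at least one negative score")
    if not (0 < target_specificity <= 1):
        raise ValueError("target specificity must lie in (0, 1]")
    if target_specificity == 1.0:
        return float(neg[-1] + SCORE_EPS)
    candidates = np.unique(neg)
    for t in candidates:
        if np.mean(neg < t) >= target_specificity:
            return float(t)
    return float(neg[-1] + SCORE_EPS)


def metrics_report_tsv(reports: dict[str, MetricsReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tthreshold\tSn\tSp\tAcc\tMCC\tAUC\tdegenerate\n")
        for name, r in reports.items():
            thr = "" if r.threshold is None else f"{r.threshold:.6g}"
            aucv = "" if r.auc is None else f"{r.auc:.6g}"
            fh.write(
                f"{name}\t{thr}\t{r.sn:.6g}\t{r.sp:.6g}\t{r.acc:.6g}\t"
                f"{r.mcc:.6g}\t{aucv}\t{','.join(r.degenerate)}\n"
            )


def roc_points_tsv(fpr: np.ndarray, tpr: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(fpr, tpr):
            fh.write(f"{x:.6g}\t{y:.6g}\n")
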