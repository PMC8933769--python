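"""Between-tracer agreement tests and CL cutoff derivation.

Two analyses sit downstream of the regional positivity calls:

* Pearson chi-square on 2x2 tables of negative/positive calls, comparing
  an 18F tracer's calls with the paired 11C-PiB calls region by region.
  No continuity correction is applied — the plain Pearson statistic is
  what published agreement tables of this kind report.
* ROC analysis of the global Centiloid value against regional positivity,
  pooled over tracers, yielding the CL cutoff that detects regional
  amyloid positivity most accurately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Chi2Result",
    "ROCResult",
    "chi_square_2x2",
    "roc_analysis",
]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    degenerate: bool = False

    def __iter__(self):
        # allows `stat, p = chi_square_2x2(...)`
        return iter((self.statistic, self.p_value))


def chi_square_2x2(table) -> Chi2Result:
    """Pearson chi-square, 1 df, WITHOUT continuity correction.

    ``table`` is a 2x2 array of counts, rows = the two tracers, columns =
    negative/positive calls. If any row or column sum is zero the
    statistic is defined as 0 with ``degenerate=True`` rather than an
    error — empty margins mean there is nothing to compare.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("negative counts")
    if t.sum() < 1:
        raise ValueError("empty table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return Chi2Result(statistic=0.0, p_value=1.0, degenerate=True)
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return Chi2Result(statistic=stat, p_value=p)


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float  # percent, at cutoff
    specificity: float  # percent
    accuracy: float     # percent
    curve: list[tuple[float, float, float]]  # (threshold, tpr, fpr)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
        }


def roc_analysis(scores, labels, cutoff_rule: str = "max_accuracy") -> ROCResult:
    """ROC of a continuous score (CL) against binary truth.

    Thresholds sweep the midpoints between sorted unique scores plus
    +/- infinity; a case is called positive when score >= threshold. AUC
    is the trapezoidal area, identical to the Mann-Whitney rank
    statistic with ties counted 1/2. The operating cutoff maximizes
    accuracy = (TP + TN) / N by default (``cutoff_rule="youden"``
    maximizes sensitivity + specificity - 1 instead); ties break toward
    the lowest cutoff. Sensitivity, specificity and accuracy are
    reported as percentages at that cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(
        [1 if l in (1, True, "positive") else 0 for l in labels], dtype=int
    )
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if cutoff_rule not in ("max_accuracy", "youden"):
        raise ValueError(f"unknown cutoff_rule {cutoff_rule!r}")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    curve = []
    best = None
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        tpr = tp / n_pos
        fpr = fp / n_neg
        acc = (tp + (n_neg - fp)) / (n_pos + n_neg)
        youden = tpr - fpr
        key = acc if cutoff_rule == "max_accuracy" else youden
        curve.append((float(thr), tpr, fpr))
        # strict > keeps the earliest (lowest) threshold among ties
        if best is None or key > best[0] + 1e-12:
            best = (key, thr, tpr, fpr, acc)

    # trapezoid over the ROC polygon; thresholds descend left->right in FPR
    fprs = np.array([c[2] for c in curve])[::-1]
    tprs = np.array([c[1] for c in curve])[::-1]
    auc = float(np.trapezoid(tprs, fprs))

    _, cutoff, tpr, fpr, acc = best
    return ROCResult(
        auc=auc,
        cutoff=float(cutoff),
        sensitivity=100.0 * tpr,
        specificity=100.0 * (1.0 - fpr),
        accuracy=100.0 * acc,
        curve=curve,
    )
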