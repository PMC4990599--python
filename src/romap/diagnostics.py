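"""Diagnostic-test evaluation: confusion metrics, empirical ROC curves,
trapezoidal AUC, DeLong variance and paired AUC comparison, Youden cutoff.

Scores are treated as stimulants: higher values indicate malignancy.  Tied
scores contribute 1/2 to the AUC (Mann-Whitney convention), which makes the
trapezoidal area identical to the U-statistic estimator that DeLong's
placement-value variance theory assumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .model import Label

__all__ = [
    "ConfusionTable",
    "RocResult",
    "AucComparison",
    "confusion_at_cutoff",
    "metrics",
    "roc_curve",
    "auc",
    "delong_variance",
    "delong_compare",
    "roc_analysis",
    "select_cutoff",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC; DeLong SE/CI filled by roc_analysis."""

    points: tuple[tuple[float, float], ...]
    auc: float
    se_auc: Optional[float] = None
    ci_auc: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _positive_mask(labels: Sequence) -> np.ndarray:
    """Boolean mask of malignant subjects from Label enums, strings or bools."""
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, Label):
            out[i] = lab is Label.MALIGNANT
        elif isinstance(lab, str):
            out[i] = Label(lab) is Label.MALIGNANT
        else:
            out[i] = bool(lab)
    return out


def confusion_at_cutoff(
    scores: Sequence[float],
    labels: Sequence,
    cutoff: float,
    *,
    equal_is_high: bool = True,
) -> ConfusionTable:
    """Count TP/FP/TN/FN with malignant-and-score>=cutoff as TP."""
    if len(scores) != len(labels):
        raise ValueError(f"{len(scores)} scores vs {len(labels)} labels")
    if len(scores) == 0:
        raise ValueError("empty input")
    s = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    called = s >= cutoff if equal_is_high else s > cutoff
    return ConfusionTable(
        tp=int(np.sum(called & pos)),
        fp=int(np.sum(called & ~pos)),
        tn=int(np.sum(~called & ~pos)),
        fn=int(np.sum(~called & pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return math.nan
    return 100.0 * num / den


def metrics(table: ConfusionTable) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV as percentages.

    A metric whose denominator is zero is reported as NaN (undefined), never
    as zero, with a warning.
    """
    return {
        "sensitivity": _ratio(table.tp, table.tp + table.fn, "sensitivity"),
        "specificity": _ratio(table.tn, table.fp + table.tn, "specificity"),
        "ppv": _ratio(table.tp, table.tp + table.fp, "ppv"),
        "npv": _ratio(table.tn, table.fn + table.tn, "npv"),
    }


def _split(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(scores) != len(labels):
        raise ValueError(f"{len(scores)} scores vs {len(labels)} labels")
    s = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    x, y = s[pos], s[~pos]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ROC needs at least one subject of each class")
    return x, y


def roc_curve(scores: Sequence[float], labels: Sequence) -> RocResult:
    """Empirical ROC stepping through every distinct score threshold.

    Equal scores are grouped at a single threshold, so ties produce diagonal
    segments whose trapezoidal area is the tie-1/2 convention.
    """
    x, y = _split(scores, labels)
    m, n = len(x), len(y)
    thresholds = np.unique(np.concatenate([x, y]))[::-1]
    tps = np.array([np.sum(x >= t) for t in thresholds], dtype=float)
    fps = np.array([np.sum(y >= t) for t in thresholds], dtype=float)
    fpr = np.concatenate([[0.0], fps / n])
    tpr = np.concatenate([[0.0], tps / m])
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(points=points, auc=area)


def auc(roc: RocResult) -> float:
    """Trapezoidal area under an empirical ROC curve."""
    pts = np.asarray(roc.points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via midranks.

    V10[i] is the proportion of benign scores below positive i (ties 1/2);
    V01[j] the proportion of malignant scores above negative j.
    """
    m, n = len(x), len(y)
    rank_all = rankdata(np.concatenate([x, y]))
    rank_x = rankdata(x)
    rank_y = rankdata(y)
    v10 = (rank_all[:m] - rank_x) / n
    v01 = 1.0 - (rank_all[m:] - rank_y) / m
    area = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    return float(area), v10, v01


def delong_variance(
    scores: Sequence[float],
    labels: Sequence,
    *,
    alpha: float = 0.05,
    logit_ci: bool = False,
) -> dict[str, object]:
    """DeLong structural-component variance of the empirical AUC.

    Returns the AUC, its standard error and the (1-alpha) confidence
    interval — Wald on the AUC scale truncated to [0, 1] by default, or on
    the logit scale with ``logit_ci=True``.
    """
    x, y = _split(scores, labels)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("DeLong variance needs at least 2 subjects per class")
    area, v10, v01 = _placements(x, y)
    var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
    se = math.sqrt(max(var, 0.0))
    zcrit = norm.ppf(1 - alpha / 2)
    if logit_ci and 0 < area < 1 and se > 0:
        logit = math.log(area / (1 - area))
        se_logit = se / (area * (1 - area))
        lo = 1 / (1 + math.exp(-(logit - zcrit * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + zcrit * se_logit)))
    else:
        lo = max(0.0, area - zcrit * se)
        hi = min(1.0, area + zcrit * se)
    return {"auc": area, "se_auc": se, "ci_auc": (lo, hi)}


def roc_analysis(scores: Sequence[float], labels: Sequence, *, alpha: float = 0.05) -> RocResult:
    """Full single-marker ROC analysis: curve, AUC, DeLong SE and CI."""
    curve = roc_curve(scores, labels)
    d = delong_variance(scores, labels, alpha=alpha)
    return RocResult(points=curve.points, auc=d["auc"], se_auc=d["se_auc"], ci_auc=d["ci_auc"])


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
) -> AucComparison:
    """Paired DeLong z-test for two correlated AUCs on the same subjects.

    The variance of the AUC difference uses the covariance of the placement
    values, which is what makes the comparison paired.  Two-sided p from the
    standard normal.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError("score lists must be aligned to the same subjects")
    xa, ya = _split(scores_a, labels)
    xb, yb = _split(scores_b, labels)
    m, n = len(xa), len(ya)
    if m < 2 or n < 2:
        raise ValueError("DeLong comparison needs at least 2 subjects per class")
    auc_a, v10a, v01a = _placements(xa, ya)
    auc_b, v10b, v01b = _placements(xb, yb)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z))) if math.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return AucComparison(auc_a=auc_a, auc_b=auc_b, z=z, p=p)


def select_cutoff(scores: Sequence[float], labels: Sequence) -> float:
    """ROC-derived cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct scores plus
    sentinels below/above all scores, evaluated with the score>=cutoff
    calling convention.  Ties in J are broken toward higher specificity
    (the larger cutoff), so perfect separation returns the midpoint of the
    separating gap.
    """
    x, y = _split(scores, labels)
    s = np.unique(np.concatenate([x, y]))
    candidates = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    best_c, best_j = candidates[0], -math.inf
    for c in candidates:
        sens = np.mean(x >= c)
        spec = np.mean(y < c)
        j = sens + spec - 1
        if j > best_j or (j == best_j and c > best_c):
            best_c, best_j = c, j
    return float(best_c)
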