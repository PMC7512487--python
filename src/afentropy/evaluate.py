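"""ROC analysis and operating-point selection for entropy-based AF scores.

Scores for a set of labeled RR segments are swept over a 101-point
threshold grid spanning their range (steps of 1% of the range); at each
threshold the six standard classifier metrics are available, the area
under the ROC curve is computed by trapezoidal integration, and three
operating points are supported: the Youden-optimal cut-point
``c* = argmax_c {Se(c) + Sp(c) - 1}``, a rule-out point (Se > level),
and a rule-in point (Sp > level).  Paired AUCs are compared with the
DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "CutpointResult",
    "AucComparison",
    "confusion_at",
    "metrics",
    "roc",
    "mann_whitney_auc",
    "youden_optimal",
    "cutpoint_at",
    "compare_auc",
]

N_GRID = 101  # thresholds from min to max in steps of 1% of the range


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at one decision threshold; AF is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """Threshold grid with per-threshold Se/Sp and trapezoidal AUC."""

    thresholds: np.ndarray
    se_at: np.ndarray
    sp_at: np.ndarray
    auc: float
    orientation: str  # "high_is_AF" | "low_is_AF"
    n_pos: int
    n_neg: int
    n_dropped: int = 0


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    attainable: bool
    se: float
    sp: float


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool = False


def _binary_labels(labels, positive_label="AF") -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    return y == positive_label


def confusion_at(scores, labels, c: float, orientation: str = "high_is_AF",
                 positive_label="AF") -> ConfusionCounts:
    """Classify each score against threshold ``c`` and count outcomes.

    With ``high_is_AF``, a segment is called AF iff its score >= ``c``;
    with ``low_is_AF``, iff score <= ``c``.
    """
    s = np.asarray(scores, float)
    if s.size == 0:
        raise InvalidInputError("no scores to evaluate")
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("scores must be finite (drop non-finite upstream)")
    y = _binary_labels(labels, positive_label)
    if y.shape != s.shape:
        raise InvalidInputError("scores and labels must have the same length")
    if orientation == "high_is_AF":
        pred = s >= c
    elif orientation == "low_is_AF":
        pred = s <= c
    else:
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The six performance metrics, each as a fraction.

    ``Se = TP/(TP+FN)``, ``Sp = TN/(TN+FP)``, ``Acc = (TP+TN)/total``,
    ``PPV = TP/(TP+FP)``, ``NPV = TN/(TN+FN)``, ``Err = (FP+FN)/total``.
    A metric with a zero denominator is reported as NaN, never as 0.
    """
    if counts.total == 0:
        raise InvalidInputError("empty confusion table")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "Se": _ratio(counts.tp, counts.tp + counts.fn),
        "Sp": _ratio(counts.tn, counts.tn + counts.fp),
        "Acc": _ratio(counts.tp + counts.tn, counts.total),
        "PPV": _ratio(counts.tp, counts.tp + counts.fp),
        "NPV": _ratio(counts.tn, counts.tn + counts.fn),
        "Err": _ratio(counts.fp + counts.fn, counts.total),
    }


def _sweep(s: np.ndarray, y: np.ndarray, thresholds: np.ndarray, orientation: str):
    """Vectorised Se/Sp over the threshold grid."""
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if orientation == "high_is_AF":
        pred = s[None, :] >= thresholds[:, None]
    else:
        pred = s[None, :] <= thresholds[:, None]
    tp = (pred & y[None, :]).sum(axis=1)
    fp = (pred & ~y[None, :]).sum(axis=1)
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg
    return se, sp


def _trapezoid_auc(se: np.ndarray, sp: np.ndarray) -> float:
    fpr = np.concatenate([[0.0], 1.0 - sp, [1.0]])
    tpr = np.concatenate([[0.0], se, [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def roc(scores, labels, positive_label="AF", drop_nonfinite: bool = True) -> RocCurve:
    """ROC curve on the 101-point grid spanning the score range.

    Orientation (whether high or low scores indicate AF) is chosen so
    that AUC >= 0.5 and recorded on the curve.  Non-finite scores are
    dropped (count recorded) before the sweep.
    """
    s = np.asarray(scores, float)
    y = _binary_labels(labels, positive_label)
    if y.shape != s.shape:
        raise InvalidInputError("scores and labels must have the same length")
    n_dropped = 0
    if drop_nonfinite:
        keep = np.isfinite(s)
        n_dropped = int((~keep).sum())
        s, y = s[keep], y[keep]
    if s.size == 0 or y.all() or not y.any():
        raise InvalidInputError("both classes must be present among finite scores")
    lo, hi = float(s.min()), float(s.max())
    thresholds = np.linspace(lo, hi, N_GRID) if hi > lo else np.array([lo])
    se, sp = _sweep(s, y, thresholds, "high_is_AF")
    auc = _trapezoid_auc(se, sp)
    orientation = "high_is_AF"
    if auc < 0.5:
        orientation = "low_is_AF"
        se, sp = _sweep(s, y, thresholds, orientation)
        auc = _trapezoid_auc(se, sp)
    return RocCurve(
        thresholds=thresholds, se_at=se, sp_at=sp, auc=auc,
        orientation=orientation, n_pos=int(y.sum()), n_neg=int((~y).sum()),
        n_dropped=n_dropped,
    )


def mann_whitney_auc(scores, labels, positive_label="AF") -> float:
    """Exact AUC by pair counting (ties count 1/2); oracle for the grid AUC."""
    s = np.asarray(scores, float)
    y = _binary_labels(labels, positive_label)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both classes must be present")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def youden_optimal(curve: RocCurve) -> tuple[float, float]:
    """Grid threshold maximizing ``J = Se + Sp - 1``; ties -> smaller c."""
    j = curve.se_at + curve.sp_at - 1.0
    i = int(np.argmax(j))  # first occurrence = smallest threshold
    return float(curve.thresholds[i]), float(j[i])


def cutpoint_at(curve: RocCurve, constraint: str = "Se", level: float = 0.99) -> CutpointResult:
    """Threshold with ``constraint > level`` maximizing the other metric.

    If no grid threshold attains the constraint, the threshold that
    maximizes the constrained metric is returned flagged unattainable.
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    if constraint == "Se":
        primary, secondary = curve.se_at, curve.sp_at
    elif constraint == "Sp":
        primary, secondary = curve.sp_at, curve.se_at
    else:
        raise InvalidInputError(f"constraint must be 'Se' or 'Sp', got {constraint!r}")
    feasible = primary > level
    if feasible.any():
        masked = np.where(feasible, secondary, -np.inf)
        i = int(np.argmax(masked))
        attainable = True
    else:
        i = int(np.argmax(primary))
        attainable = False
    return CutpointResult(
        threshold=float(curve.thresholds[i]), attainable=attainable,
        se=float(curve.se_at[i]), sp=float(curve.sp_at[i]),
    )


# ---------------------------------------------------------------------------
# Paired AUC comparison (DeLong)
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n          # placement of each positive among negatives
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # placement of each negative among positives
    auc = v10.mean()
    return float(auc), v10, v01


def compare_auc(scores_a, scores_b, labels, positive_label="AF") -> AucComparison:
    """Two-sided DeLong test for a difference in paired AUCs.

    Both score vectors must be computed on the identical segments; the
    test accounts for their correlation.  A zero-variance difference
    (e.g. identical score vectors) is flagged degenerate with p = 1.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    y = _binary_labels(labels, positive_label)
    if not (sa.shape == sb.shape == y.shape):
        raise InvalidInputError("paired scores and labels must have equal length")
    keep = np.isfinite(sa) & np.isfinite(sb)
    sa, sb, y = sa[keep], sb[keep], y[keep]
    if y.all() or not y.any():
        raise InvalidInputError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_placements(sa[y], sa[~y])
    auc_b, v10_b, v01_b = _delong_placements(sb[y], sb[~y])
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        return AucComparison(auc_a, auc_b, z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(auc_a, auc_b, z=float(z), p_value=float(p))
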