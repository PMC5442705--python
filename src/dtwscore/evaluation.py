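"""ROC evaluation and confusion summaries against known labels.

Discrimination of a score (e.g. the DTWscore separating heterogeneous
from non-heterogeneous genes, or a mixture posterior separating cell
types) is summarized by the ROC curve and its trapezoidal AUC, which
equals the Mann–Whitney probability that a random positive outscores a
random negative (ties counted half).  Confidence intervals for the
sensitivity at chosen specificities come from a stratified percentile
bootstrap: positives and negatives are resampled independently, the
replicate ROC is re-read at each specificity by linear interpolation,
and percentile bounds are taken over replicates (default 2000
replicates, 95% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as _skm

from .exceptions import ValidationError

__all__ = ["RocCurve", "roc_curve", "sensitivity_ci", "confusion"]


@dataclass(frozen=True)
class RocCurve:
    """Operating points (descending thresholds) and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def sensitivity_at(self, specificity: float) -> float:
        """Sensitivity (TPR) at a given specificity, linearly interpolated
        between adjacent operating points."""
        if not 0.0 <= specificity <= 1.0:
            raise ValidationError(f"specificity must be in [0, 1], got {specificity}")
        spec = 1.0 - self.fpr  # decreasing along the curve
        # np.interp needs increasing x
        return float(np.interp(specificity, spec[::-1], self.tpr[::-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValidationError(
            f"labels must contain both classes 0 and 1, found {classes.tolist()}"
        )
    return labels


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve of a score against binary labels (higher = positive).

    One operating point per distinct score value plus the (0,0) and
    (1,1) endpoints; AUC by the trapezoid rule, which with half-credit
    for ties equals the Mann–Whitney pair statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if len(scores) != len(labels):
        raise ValidationError("scores and labels differ in length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr))
    )


def sensitivity_ci(
    scores,
    labels,
    specificities=(0.9, 0.95),
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stratified-bootstrap percentile CIs for sensitivity at fixed specificity.

    Positives and negatives are resampled with replacement independently
    (preserving class sizes); each replicate's ROC is read at the
    requested specificities; percentile bounds at (1-level)/2 and
    1-(1-level)/2 form the interval.  Deterministic given ``seed``.

    Returns a DataFrame with columns specificity, sensitivity (point
    estimate on the full data), lower, upper.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    specificities = np.asarray(specificities, dtype=float)
    if np.any((specificities < 0) | (specificities > 1)):
        raise ValidationError("specificities must lie in [0, 1]")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            "bootstrap needs at least 2 members per class "
            f"(got {len(pos)} positives, {len(neg)} negatives)"
        )
    point = roc_curve(scores, labels)
    est = np.array([point.sensitivity_at(s) for s in specificities])

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(specificities)))
    lbl = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    for b in range(n_boot):
        rp = pos[rng.integers(0, len(pos), len(pos))]
        rn = neg[rng.integers(0, len(neg), len(neg))]
        curve = roc_curve(np.concatenate([rp, rn]), lbl)
        boot[b] = [curve.sensitivity_at(s) for s in specificities]
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot, alpha, axis=0)
    upper = np.quantile(boot, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "specificity": specificities,
            "sensitivity": est,
            "lower": np.minimum(lower, est),
            "upper": np.maximum(upper, est),
        }
    )


def confusion(assignments, truth) -> tuple[pd.DataFrame, float]:
    """Contingency table and accuracy after optimal label matching.

    Cluster labels are arbitrary, so components are matched to truth
    labels by the maximum-agreement assignment (Hungarian algorithm —
    exact, and identical to exhaustive permutation search).  Returns the
    matched table (rows = truth, columns = matched assignment labels)
    and the matched accuracy.
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(truth)
    if len(assignments) != len(truth):
        raise ValidationError(
            f"length mismatch: {len(assignments)} assignments vs {len(truth)} truths"
        )
    if len(truth) == 0:
        raise ValidationError("empty label vectors")
    t_levels = np.unique(truth)
    a_levels = np.unique(assignments)
    table = np.zeros((len(t_levels), len(a_levels)), dtype=int)
    for i, t in enumerate(t_levels):
        for j, a in enumerate(a_levels):
            table[i, j] = int(np.sum((truth == t) & (assignments == a)))
    # pad to square so every truth level can receive a column
    size = max(table.shape)
    padded = np.zeros((size, size), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    order = [c for _, c in sorted(zip(rows, cols)) if c < table.shape[1]]
    order += [j for j in range(table.shape[1]) if j not in order]
    matched = table[:, order]
    acc = float(np.trace(padded[rows][:, cols]) / len(truth))
    df = pd.DataFrame(
        matched,
        index=pd.Index(t_levels, name="truth"),
        columns=pd.Index(a_levels[order], name="assignment"),
    )
    return df, acc
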