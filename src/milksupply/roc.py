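"""ROC analysis for low-milk-supply (LMS) diagnostic thresholds.

Conventions: LMS is the positive class. A predictor's ``direction`` states
which side of a threshold flags LMS — ``"lower"`` (e.g. milk production:
values *below* the cut-off are positive) or ``"higher"`` (e.g. formula
intake: values *above* are positive). Thresholds are evaluated at midpoints
between consecutive distinct scores plus infinite sentinels, and reported
on the original measurement scale. The optimal cut-off maximises Youden's
J = sensitivity + specificity - 1, with ties broken toward the more
sensitive threshold (missing a true LMS case is costlier than a false
alarm). +inf scores (e.g. formula-to-growth ratio with non-positive gain)
rank above all finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UndefinedRocError

log = logging.getLogger(__name__)

LOWER = "lower"
HIGHER = "higher"


@dataclass
class RocCurve:
    """A full ROC curve for one candidate predictor."""

    name: str
    direction: str                 # "lower" or "higher" is LMS-positive
    thresholds: np.ndarray         # strictly increasing, original scale
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    youden_at_optimum: float
    n_pos: int
    n_neg: int
    low_n: bool = False


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    """Scores transformed so that larger always means more LMS-like."""
    if direction == HIGHER:
        return scores
    if direction == LOWER:
        return -scores
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


def metrics_at(scores, labels, threshold: float, direction: str):
    """(sensitivity, specificity, J) at a given cut, by integer counting.

    ``direction='lower'`` predicts positive when score < threshold;
    ``'higher'`` predicts positive when score > threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pred = scores < threshold if direction == LOWER else scores > threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return sens, spec, sens + spec - 1.0


def _rank_auc(oriented_scores, labels):
    """Tie-corrected Mann-Whitney AUC (ties count one half)."""
    ranks = rankdata(oriented_scores)  # average ranks handle ties and +/-inf
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve(scores, labels, direction: str, name: str = "predictor") -> RocCurve:
    """Build the ROC curve of ``scores`` against boolean LMS ``labels``.

    Thresholds are midpoints of consecutive distinct score values plus
    -inf/+inf sentinels; the direction is handled by a sign convention
    internally and thresholds are reported on the original scale.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise UndefinedRocError(f"{name}: both LMS and NMS must be represented")
    if np.isnan(scores).any():
        raise ValueError(f"{name}: scores contain NaN; drop missing rows first")

    oriented = _oriented(scores, direction)
    distinct = np.unique(scores[np.isfinite(scores)])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # guard thresholds beyond the finite range give the operating points
    # where only infinite-score dyads fall on one side of the cut
    thresholds = np.concatenate(
        ([-np.inf, distinct[0] - 1.0], mids, [distinct[-1] + 1.0, np.inf])
    )

    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        sens[i], spec[i], _ = metrics_at(scores, labels, t, direction)

    auc_value = auc_trapezoid(sens, spec)
    rank_value = _rank_auc(oriented, labels)
    if not np.isclose(auc_value, rank_value, atol=1e-9):
        raise AssertionError(
            f"{name}: trapezoid AUC {auc_value} != rank AUC {rank_value}"
        )

    j = sens + spec - 1.0
    opt = _youden_index(j, sens, direction, thresholds)
    return RocCurve(
        name=name, direction=direction, thresholds=thresholds,
        sensitivity=sens, specificity=spec, auc=auc_value,
        optimal_threshold=float(thresholds[opt]),
        youden_at_optimum=float(j[opt]),
        n_pos=int(labels.sum()), n_neg=int((~labels).sum()),
    )


def auc_trapezoid(sensitivity, specificity) -> float:
    """Trapezoidal area under the (1-specificity, sensitivity) curve."""
    fpr = 1.0 - np.asarray(specificity, float)
    tpr = np.asarray(sensitivity, float)
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc(curve: RocCurve) -> float:
    """AUC of a built curve (trapezoid, already cross-checked against the
    tie-corrected rank statistic at construction)."""
    return curve.auc


def _youden_index(j, sens, direction, thresholds) -> int:
    """Index of the J-maximising threshold; ties favour sensitivity."""
    best_j = np.nanmax(j)
    candidates = np.where(np.isclose(j, best_j, atol=1e-12))[0]
    if len(candidates) > 1:
        log.info("Youden tie over %d thresholds; breaking toward sensitivity",
                 len(candidates))
    best_sens = sens[candidates].max()
    candidates = candidates[np.isclose(sens[candidates], best_sens, atol=1e-12)]
    # residual ties: the most permissive threshold in the LMS direction
    return int(candidates[-1] if direction == LOWER else candidates[0])


def youden_optimal(curve: RocCurve) -> float:
    """The Youden-optimal threshold of a built curve."""
    return curve.optimal_threshold


@dataclass
class ThresholdComparison:
    """Side-by-side metrics of two candidate thresholds for one predictor."""

    name: str
    threshold_a: float
    threshold_b: float
    metrics_a: tuple[float, float, float]   # sensitivity, specificity, J
    metrics_b: tuple[float, float, float]

    @property
    def deltas(self) -> tuple[float, float, float]:
        return tuple(b - a for a, b in zip(self.metrics_a, self.metrics_b))


def compare_thresholds(scores, labels, direction, t_a, t_b, name="predictor"):
    """Compare an existing and a proposed cut-off on the same data."""
    return ThresholdComparison(
        name=name, threshold_a=t_a, threshold_b=t_b,
        metrics_a=metrics_at(scores, labels, t_a, direction),
        metrics_b=metrics_at(scores, labels, t_b, direction),
    )


#: the standard predictor panel: (column, direction, partial-BF subset only)
PANEL_SPEC = [
    ("mp_24h", LOWER, False),
    ("breastmilk_intake_24h", LOWER, False),
    ("avg_daily_gain", LOWER, False),
    ("formula_intake_24h", HIGHER, True),
    ("formula_to_growth", HIGHER, True),
]


def predictor_panel(
    records: pd.DataFrame,
    lms_labels: pd.Series | np.ndarray,
    min_subgroup: int = 20,
) -> dict[str, RocCurve]:
    """ROC curves for the five candidate LMS predictors.

    Milk production, breast-milk intake and average daily weight gain are
    analysed on all dyads (lower values flag LMS); formula intake and the
    formula-to-growth ratio only among partially breastfeeding dyads
    (formula > 0; higher values flag LMS). Subgroup curves below
    ``min_subgroup`` dyads are flagged ``low_n``. Predictors absent or
    one-class are skipped with a log message.
    """
    labels = np.asarray(lms_labels, bool)
    partial = records["formula_intake_24h"].to_numpy(float) > 0
    curves: dict[str, RocCurve] = {}
    for col, direction, subset_only in PANEL_SPEC:
        if col not in records.columns:
            log.warning("panel: column %r missing, skipped", col)
            continue
        mask = partial.copy() if subset_only else np.ones(len(records), bool)
        mask &= ~np.isnan(records[col].to_numpy(float)) | np.isinf(
            records[col].to_numpy(float)
        )
        scores = records[col].to_numpy(float)[mask]
        sub_labels = labels[mask]
        if len(scores) == 0 or sub_labels.all() or not sub_labels.any():
            log.warning("panel: %r skipped (no dyads or one outcome class)", col)
            continue
        curve = roc_curve(scores, sub_labels, direction, name=col)
        if len(scores) < min_subgroup:
            curve.low_n = True
        curves[col] = curve
    return curves


def panel_report(curves: dict[str, RocCurve]) -> pd.DataFrame:
    """Flat per-predictor summary table (mirrors a published metrics panel)."""
    rows = []
    for name, c in curves.items():
        i = int(np.where(c.thresholds == c.optimal_threshold)[0][0])
        rows.append(
            {
                "predictor": name,
                "n": c.n_pos + c.n_neg,
                "direction": c.direction,
                "auc": c.auc,
                "optimal_threshold": c.optimal_threshold,
                "sensitivity": c.sensitivity[i],
                "specificity": c.specificity[i],
                "youden_j": c.youden_at_optimum,
                "low_n": c.low_n,
            }
        )
    return pd.DataFrame(rows)
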