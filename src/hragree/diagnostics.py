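"""Classification diagnostics with the reference device as gold standard.

A session is labelled positive at threshold fraction ``p`` when its
normalized intensity ratio HR_N = HRmean / (p * (220 - age)) is strictly
greater than 1. Sensitivity, specificity, PPV and NPV are computed from
the resulting confusion counts; a ROC curve is traced by sweeping ``p``
jointly for both devices (each ``p`` re-defines the gold-standard label
as well as the test label, mirroring how the operating points at 70% and
85% of maximum HR are constructed), with the trapezoid rule for AUC.

Metrics with a zero denominator are reported as NaN ("undefined"), never
coerced to 0 or 1; undefined points are skipped in the ROC sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import normalized_intensity

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "RocCurve",
    "tally",
    "confusion_metrics",
    "classify_summaries",
    "confusion_at_threshold",
    "roc_sweep",
    "auc_trapezoid",
    "default_p_grid",
]

OUTCOMES = ("TP", "FP", "TN", "FN")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Fractions in [0, 1]; NaN marks an undefined (zero-denominator) metric."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def tally(outcomes: Iterable[str]) -> ConfusionCounts:
    """Count TP/FP/TN/FN outcomes (all from one threshold)."""
    counts = {o: 0 for o in OUTCOMES}
    for o in outcomes:
        if o not in counts:
            raise ValueError(f"unknown outcome label {o!r}")
        counts[o] += 1
    return ConfusionCounts(counts["TP"], counts["FP"], counts["TN"], counts["FN"])


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV from confusion counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN); a metric whose denominator is zero is NaN.
    """
    return ConfusionMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def classify_summaries(summaries: pd.DataFrame, p: float) -> pd.Series:
    """Per-session confusion outcome at threshold fraction ``p``.

    Uses each session's peak-20-minute means (the quantity that defines a
    high-intensity session) on both devices; positivity is HR_N > 1.
    """
    from .features import classify_session  # session-level rule

    out = []
    for row in summaries.itertuples(index=False):
        rt = normalized_intensity(row.peak20_test, row.age, p)
        rr = normalized_intensity(row.peak20_ref, row.age, p)
        out.append(classify_session(rt, rr))
    return pd.Series(out, index=summaries.index, name=f"outcome_p{p:g}")


def confusion_at_threshold(
    summaries: pd.DataFrame, p: float
) -> tuple[ConfusionCounts, ConfusionMetrics]:
    counts = tally(classify_summaries(summaries, p))
    return counts, confusion_metrics(counts)


@dataclass(frozen=True)
class RocCurve:
    """ROC points (threshold p, FPR, TPR) with trapezoid AUC.

    ``points`` holds the raw swept operating points; ``fpr``/``tpr`` are
    the integration-ready curve: anchors (0,0) and (1,1) added, sorted by
    FPR with TPR averaged at duplicate FPR values.
    """

    points: pd.DataFrame  # columns: p, fpr, tpr
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def default_p_grid(start: float = 0.40, stop: float = 1.10, step: float = 0.01) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def roc_sweep(summaries: pd.DataFrame, p_grid: Sequence[float] | None = None) -> RocCurve:
    """Sweep the intensity threshold and trace the ROC curve.

    Both devices are classified at the same ``p`` for every grid value
    (the gold-standard labelling shifts with ``p``, exactly as at the
    fixed 70%/85% operating points); grid values where sensitivity or
    specificity is undefined are skipped.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0 or np.any(np.diff(p_grid) <= 0):
        raise ValueError("p_grid must be non-empty and strictly increasing")
    rows = []
    for p in p_grid:
        _, m = confusion_at_threshold(summaries, float(p))
        if np.isnan(m.sensitivity) or np.isnan(m.specificity):
            continue
        rows.append({"p": float(p), "fpr": 1.0 - m.specificity, "tpr": m.sensitivity})
    if not rows:
        raise ValueError("no threshold in the grid yields defined sensitivity "
                         "and specificity")
    points = pd.DataFrame(rows)
    fpr, tpr = _integration_curve(points["fpr"].to_numpy(), points["tpr"].to_numpy())
    return RocCurve(points=points, fpr=fpr, tpr=tpr, auc=auc_trapezoid(fpr, tpr))


def _integration_curve(fpr: np.ndarray, tpr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort swept points by FPR averaging TPR at duplicate FPR, then frame
    them with the (0,0) and (1,1) anchors (kept as endpoints even when a
    swept point shares their FPR, so a point at FPR 0 still anchors to 0)."""
    df = (
        pd.DataFrame({"fpr": fpr, "tpr": tpr})
        .groupby("fpr", sort=True)["tpr"]
        .mean()
        .reset_index()
    )
    out_f = np.concatenate([[0.0], df["fpr"].to_numpy(), [1.0]])
    out_t = np.concatenate([[0.0], df["tpr"].to_numpy(), [1.0]])
    return out_f, out_t


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal integral of TPR over FPR (curve must be FPR-sorted and
    include the (0,0) and (1,1) anchors)."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    if fpr.size < 2:
        raise ValueError("AUC needs at least the two anchor points")
    if np.any(np.diff(fpr) < 0):
        raise ValueError("ROC points must be sorted by FPR")
    if not (np.isclose(fpr[0], 0.0) and np.isclose(fpr[-1], 1.0)):
        raise ValueError("ROC curve must include the (0,0) and (1,1) anchors")
    return float(np.trapezoid(tpr, fpr))
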