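"""Exact ROC construction and the sensitivity-at-specificity evaluation metric.

A deployed detector runs at one operating point, so the holistic AUC can hide what
matters: how many positives survive a threshold chosen to keep the false-positive
rate tiny.  This module provides the operating-point metrics — the threshold that
realises a target specificity on a reference set, the sensitivity at that threshold,
and the confusion counts — alongside standard ROC/AUC computation.

Conventions (used consistently across the package):

* decision rule: predict positive iff ``score >= threshold``;
* ``specificity(theta)`` = fraction of negatives with ``score < theta``;
* the threshold returned for a level is the smallest observed score achieving
  specificity >= level (it therefore maximises sensitivity among qualifying
  thresholds), or ``+inf`` when no observed score qualifies;
* no interpolation: the reported sensitivity is the one realised at an achievable
  operating point with specificity at least the requested level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn.metrics

from .core_loss import PredictionBatch

__all__ = [
    "RocCurve",
    "ConfusionCounts",
    "MetricError",
    "roc_curve",
    "auc",
    "threshold_at_specificity",
    "sensitivity_at_specificity",
    "confusion_at_threshold",
    "read_scores",
    "write_roc_points",
    "write_metrics_json",
]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given batch."""


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC operating points.

    ``thresholds`` are strictly decreasing; ``fpr`` and ``tpr`` are non-decreasing.
    The first point (threshold above every score) has fpr = tpr = 0; the last
    (threshold at the minimum score) has fpr = tpr = 1.  Tied scores collapse to a
    single point.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _require_both_classes(batch: PredictionBatch) -> None:
    if batch.n_pos == 0 or batch.n_neg == 0:
        raise MetricError("ROC metrics require at least one sample of each class")


def roc_curve(batch: PredictionBatch) -> RocCurve:
    """Full ROC curve: one point per distinct score plus the (0, 0) boundary point."""
    _require_both_classes(batch)
    fpr, tpr, thr = sklearn.metrics.roc_curve(
        batch.labels, batch.scores, drop_intermediate=False
    )
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve; equals the tie-corrected Mann-Whitney
    statistic divided by ``n_pos * n_neg``."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def threshold_at_specificity(batch: PredictionBatch, level: float) -> float:
    """Smallest observed-score threshold achieving specificity >= ``level``.

    Specificity is non-decreasing in the threshold, so the smallest qualifying
    threshold also maximises sensitivity.  Returns ``+inf`` when no observed score
    reaches the level (every finite candidate leaves too many negatives at or above
    it).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("specificity level must lie in (0, 1)")
    if batch.n_neg == 0:
        raise MetricError("threshold_at_specificity requires at least one negative")
    neg = np.sort(batch.scores[batch.labels == 0])
    candidates = np.unique(batch.scores)
    # negatives strictly below each candidate threshold
    below = np.searchsorted(neg, candidates, side="left")
    ok = below / neg.size >= level
    if not ok.any():
        return float("inf")
    return float(candidates[np.argmax(ok)])


def sensitivity_at_specificity(batch: PredictionBatch, level: float) -> float:
    """True-positive rate at :func:`threshold_at_specificity`."""
    _require_both_classes(batch)
    theta = threshold_at_specificity(batch, level)
    pos = batch.scores[batch.labels == 1]
    return float((pos >= theta).mean())


def confusion_at_threshold(batch: PredictionBatch, threshold: float) -> ConfusionCounts:
    """Confusion counts under the rule "predict positive iff score >= threshold"."""
    pred = batch.scores >= threshold
    y = batch.labels == 1
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


# -- delimited-text / JSON plumbing for metric-only use ---------------------------


def read_scores(path: str | Path, score_col: str = "score", label_col: str = "label") -> PredictionBatch:
    """Read per-sample scores and binary labels from a delimited text file.

    The delimiter is sniffed by pandas; files may carry a header naming the two
    columns or be bare two-column (score, label) tables.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if score_col not in df.columns or label_col not in df.columns:
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        df.columns = [score_col, label_col][: len(df.columns)]
    return PredictionBatch(df[score_col].to_numpy(float), df[label_col].to_numpy(int))


def write_roc_points(curve: RocCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_metrics_json(batch: PredictionBatch, levels, path: str | Path) -> dict:
    """Compute AUC plus sensitivity/threshold/realised specificity at each level and
    write them as JSON; returns the written dict."""
    out = {"auc": auc(roc_curve(batch)), "n_pos": batch.n_pos, "n_neg": batch.n_neg}
    for level in levels:
        theta = threshold_at_specificity(batch, level)
        counts = confusion_at_threshold(batch, theta)
        key = f"{level:g}"
        out[f"sensitivity_at_{key}"] = counts.sensitivity
        out[f"realized_specificity_at_{key}"] = counts.specificity
        out[f"threshold_at_{key}"] = theta
    Path(path).write_text(json.dumps(out, indent=2))
    return out
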