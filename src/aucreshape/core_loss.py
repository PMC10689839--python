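"""Boosted cross-entropy loss for reshaping the ROC curve at high specificity.

The central idea: a binary classifier trained with plain cross-entropy optimises the
whole ROC curve, while a deployed detector operates at one high-specificity point.
Positives that are misclassified at that operating point (false negatives at the
high-specificity threshold) get an extra penalty: a scalar boost ``b`` is subtracted
from their predicted probability inside the log, so the per-sample loss becomes

    l_i = -[ y_i * log(p_i - b_i) + (1 - y_i) * log(1 - p_i + b_i) ]

with ``b_i > 0`` only when ``y_i == 1`` and ``p_i`` falls below the threshold of a
configured specificity level.  Subtracting ``b`` steepens the gradient
(``1/(p-b) > 1/p``), so the network concentrates on exactly the samples that block
sensitivity in the high-specificity region.

Boosts may be configured at several specificity levels at once (a
:class:`BoostSchedule`).  The thresholds realising those levels partition ``(0,
theta_max)`` into bands and a misclassified positive receives the boost of the single
band containing its score: the boost of level ``s_k`` applies on ``[theta_{k-1},
theta_k)`` with ``theta_0 = 0``.  Boosts never stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EPS",
    "PredictionBatch",
    "BoostSchedule",
    "BoostVector",
    "MulticlassBatch",
    "compute_boosts",
    "reshaped_binary_loss",
    "reshaped_multiclass_loss",
]

#: Floor for every log argument; keeps the loss finite and the gradient bounded when
#: p - b <= 0 (large boosts may otherwise push the argument negative).
EPS: float = 1e-7


class ConfigurationError(ValueError):
    """A schedule/threshold/parameter combination violates the contract."""


@dataclass(frozen=True)
class PredictionBatch:
    """Per-sample positive-class probabilities with binary labels.

    Label 1 is the positive (majority, low misclassification cost) class; label 0 is
    the negative (minority, high-cost) class.  Scores are clamped into the open
    interval ``(EPS, 1 - EPS)`` on construction.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1 or scores.shape != labels.shape:
            raise ValueError("scores and labels must be 1-D arrays of equal length")
        if scores.size < 1:
            raise ValueError("batch must contain at least one sample")
        if np.isnan(scores).any():
            raise ValueError("NaN score in prediction batch")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        scores = np.clip(scores, EPS, 1.0 - EPS)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int64))

    def __len__(self) -> int:
        return self.scores.size

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self) - self.labels.sum())


@dataclass(frozen=True)
class BoostSchedule:
    """Ordered (specificity level, boost value) pairs, e.g. ``[0.4, 0.2, 0.1, 0.1]``
    at ``[0.90, 0.92, 0.95, 0.98]``.

    Levels must be strictly increasing in ``(0, 1)``; every boost must lie in
    ``[0, 1)``.
    """

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Sequence[tuple[float, float]]) -> None:
        entries = tuple((float(s), float(b)) for s, b in entries)
        levels = [s for s, _ in entries]
        if any(not 0.0 < s < 1.0 for s in levels):
            raise ConfigurationError("specificity levels must lie in (0, 1)")
        if any(l2 <= l1 for l1, l2 in zip(levels, levels[1:])):
            raise ConfigurationError("specificity levels must be strictly increasing")
        if any(not 0.0 <= b < 1.0 for _, b in entries):
            raise ConfigurationError("every boost must satisfy 0 <= boost < 1")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def uniform(cls, boost: float, levels: Sequence[float]) -> "BoostSchedule":
        """One boost value applied at every level (the paper-style ``0.2 at
        [0.90, 0.92, 0.95, 0.98]`` notation)."""
        return cls([(s, boost) for s in levels])

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.entries)

    @property
    def boosts(self) -> tuple[float, ...]:
        return tuple(b for _, b in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class BoostVector:
    """Per-sample boost values; zero for negatives and for positives scored at or
    above the highest configured threshold."""

    boosts: np.ndarray

    def __post_init__(self) -> None:
        boosts = np.asarray(self.boosts, dtype=float)
        if (boosts < 0).any():
            raise ValueError("boosts must be non-negative")
        object.__setattr__(self, "boosts", boosts)

    @classmethod
    def zeros(cls, n: int) -> "BoostVector":
        return cls(np.zeros(n))

    def __len__(self) -> int:
        return self.boosts.size


@dataclass(frozen=True)
class MulticlassBatch:
    """Per-sample probability vectors over K >= 2 classes with integer labels."""

    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int64)
        if probs.ndim != 2 or probs.shape[1] < 2:
            raise ValueError("probabilities must be (n_samples, K>=2)")
        if labels.shape != (probs.shape[0],):
            raise ValueError("labels must align with probability rows")
        if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("each probability row must sum to 1 within 1e-6")
        if labels.min() < 0 or labels.max() >= probs.shape[1]:
            raise ValueError("labels must be class indices in [0, K)")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]


def compute_boosts(batch, thresholds, schedule: BoostSchedule | None) -> BoostVector:
    """Assign each sample its boost under the band rule.

    ``thresholds`` is a :class:`~aucreshape.threshold_tracker.ThresholdSet` aligned
    one-to-one with the schedule's specificity levels.  Thresholds must be
    non-decreasing with specificity level.  A positive with score in
    ``[theta_{k-1}, theta_k)`` (``theta_0 = 0``) receives the boost configured for
    level ``s_k``; negatives and positives at or above ``theta_max`` receive 0.

    An empty/absent schedule yields an all-zero vector.
    """
    n = len(batch)
    if schedule is None or len(schedule) == 0:
        return BoostVector.zeros(n)
    theta = np.asarray([thresholds[s] for s in schedule.levels], dtype=float)
    if theta.size != len(schedule):
        raise ConfigurationError("one threshold required per schedule entry")
    if not np.all(theta[1:] >= theta[:-1]):  # comparison, not diff: thresholds may be +inf
        raise ConfigurationError("thresholds must be non-decreasing with specificity")
    # band index: number of thresholds <= score; index len(theta) means "above all"
    band = np.searchsorted(theta, batch.scores, side="right")
    boost_by_band = np.append(np.asarray(schedule.boosts), 0.0)
    boosts = np.where(batch.labels == 1, boost_by_band[band], 0.0)
    return BoostVector(boosts)


def reshaped_binary_loss(
    batch: PredictionBatch,
    boosts: BoostVector,
    class_weights: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Evaluate the boosted cross-entropy.

    Parameters
    ----------
    batch
        Scores and binary labels.
    boosts
        Per-sample boost values (from :func:`compute_boosts`); all-zero reduces the
        loss to plain cross-entropy.
    class_weights
        Optional ``(w_neg, w_pos)`` multiplied into each sample's loss after
        boosting (inverse-class-frequency weighting in the training harness).

    Returns
    -------
    (total, per_sample)
        ``total`` is the (weighted) sum; ``per_sample`` the individual losses.
    """
    b = boosts.boosts
    if len(boosts) != len(batch):
        raise ConfigurationError("boost vector must align with the batch")
    if (b >= 1.0).any():
        raise ConfigurationError("boost values must be < 1")
    p, y = batch.scores, batch.labels
    pos_arg = np.clip(p - b, EPS, None)
    neg_arg = np.clip(1.0 - p + b, EPS, None)
    per_sample = -(y * np.log(pos_arg) + (1 - y) * np.log(neg_arg))
    if class_weights is not None:
        w_neg, w_pos = class_weights
        per_sample = per_sample * np.where(y == 1, w_pos, w_neg)
    return float(per_sample.sum()), per_sample


def reshaped_multiclass_loss(
    batch: MulticlassBatch,
    critical_class: int,
    threshold: float,
    boost: float,
) -> tuple[float, np.ndarray]:
    """One-vs-all reshaping for a single critical class in a K-class problem.

    For samples belonging to ``critical_class`` whose critical-class probability
    falls below ``threshold`` (the class's one-vs-all high-specificity threshold),
    the probability vector is modified mass-conservingly: ``boost`` is moved from the
    critical class onto the largest non-critical class (ties broken toward the lowest
    index).  The per-sample loss is ``-log(q_label)`` on the modified vector, with
    the same ``EPS`` floor as the binary case.
    """
    if not 0 <= critical_class < batch.n_classes:
        raise ConfigurationError("critical_class out of range")
    if not 0.0 <= boost < 1.0:
        raise ConfigurationError("boost must satisfy 0 <= boost < 1")
    probs = batch.probabilities.copy()
    labels = batch.labels
    hit = (labels == critical_class) & (probs[:, critical_class] < threshold)
    if boost > 0 and hit.any():
        rows = np.flatnonzero(hit)
        masked = probs[rows].copy()
        masked[:, critical_class] = -np.inf  # argmax over non-critical classes
        target = masked.argmax(axis=1)  # np.argmax takes the lowest index on ties
        # move at most p_critical so every entry stays in [0,1] and mass is conserved
        moved = np.minimum(boost, probs[rows, critical_class])
        probs[rows, critical_class] -= moved
        probs[rows, target] += moved
    q_label = probs[np.arange(len(labels)), labels]
    per_sample = -np.log(np.clip(q_label, EPS, None))
    return float(per_sample.sum()), per_sample
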