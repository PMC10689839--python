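"""Independent brute-force oracles for ROC quantities.

Everything here is written from the definitions by direct enumeration, deliberately
avoiding the package's own code paths and sklearn: specificity counted negative by
negative, AUC as pairwise wins over all (positive, negative) pairs.
"""

from __future__ import annotations

import math

import numpy as np


def mann_whitney_auc(scores, labels) -> float:
    """(wins + 0.5 * ties) / (n_pos * n_neg) by explicit pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def specificity_at(scores, labels, threshold) -> float:
    neg = [s for s, y in zip(scores, labels) if y == 0]
    return sum(s < threshold for s in neg) / len(neg)


def sensitivity_at(scores, labels, threshold) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    return sum(s >= threshold for s in pos) / len(pos)


def threshold_at_specificity(scores, labels, level) -> float:
    """Smallest candidate threshold (observed scores, then +inf) whose specificity
    reaches the level; ties resolved by the enumeration order itself."""
    candidates = sorted(set(scores)) + [math.inf]
    for theta in candidates:
        if specificity_at(scores, labels, theta) >= level:
            return theta
    raise AssertionError("unreachable: +inf always attains specificity 1")


def sensitivity_at_specificity(scores, labels, level) -> float:
    return sensitivity_at(scores, labels, threshold_at_specificity(scores, labels, level))


def confusion(scores, labels, threshold):
    tp = sum(s >= threshold and y == 1 for s, y in zip(scores, labels))
    fp = sum(s >= threshold and y == 0 for s, y in zip(scores, labels))
    fn = sum(s < threshold and y == 1 for s, y in zip(scores, labels))
    tn = sum(s < threshold and y == 0 for s, y in zip(scores, labels))
    return tp, fp, tn, fn


def random_tied_batch(rng: np.random.Generator, max_size: int = 200):
    """Random batch with both classes and deliberately coarse scores (many ties)."""
    n = int(rng.integers(2, max_size + 1))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    grid = int(rng.integers(2, 30))  # coarse grid forces tied scores
    scores = rng.integers(1, grid, size=n) / grid
    return scores.astype(float), labels
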