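"""Sensitivity at fixed specificity: the operating-point metric.

Two score distributions can share an AUC yet differ sharply in how many positives
survive a 98%-specificity threshold; this metric makes that difference visible.
"""

import numpy as np

from aucreshape import (
    PredictionBatch,
    auc,
    confusion_at_threshold,
    roc_curve,
    sensitivity_at_specificity,
    threshold_at_specificity,
)

rng = np.random.default_rng(0)
n_pos, n_neg = 2000, 400

# system A: all positives moderately separated
a_scores = np.r_[rng.normal(1.55, 1, n_pos), rng.normal(0, 1, n_neg)]
# system B: most positives far away, a third overlapping the negatives
b_scores = np.r_[
    rng.normal(3.0, 1, int(0.7 * n_pos)),
    rng.normal(0.3, 1, n_pos - int(0.7 * n_pos)),
    rng.normal(0, 1, n_neg),
]
labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]

for name, raw in [("A", a_scores), ("B", b_scores)]:
    batch = PredictionBatch(1 / (1 + np.exp(-raw)), labels)
    theta = threshold_at_specificity(batch, 0.98)
    counts = confusion_at_threshold(batch, theta)
    print(
        f"system {name}: AUC={auc(roc_curve(batch)):.3f}  "
        f"theta@0.98={theta:.3f}  sens@0.98={sensitivity_at_specificity(batch, 0.98):.3f}  "
        f"realized specificity={counts.specificity:.3f}"
    )

# Similar AUCs, very different sensitivity once only 2% of negatives may pass:
# system B's overlapping subpopulation is invisible to the AUC but dominates the
# high-specificity operating point.
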