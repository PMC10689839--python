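"""Boosted cross-entropy on a toy batch.

Shows how a misclassified positive's loss is amplified when its score falls below a
high-specificity threshold, while negatives and confident positives are untouched.
"""

import numpy as np

from aucreshape import (
    BoostSchedule,
    PredictionBatch,
    ThresholdSet,
    compute_boosts,
    reshaped_binary_loss,
)

# four samples: a confident positive, a borderline positive, a deep false negative,
# and a negative
batch = PredictionBatch(
    scores=np.array([0.95, 0.55, 0.30, 0.20]),
    labels=np.array([1, 1, 1, 0]),
)

# boost 0.4 below the 0.90-specificity threshold, 0.2 between it and the
# 0.98-specificity threshold (thresholds here are illustrative fixed values; during
# training they are re-estimated from the model's current predictions)
schedule = BoostSchedule([(0.90, 0.4), (0.98, 0.2)])
thresholds = ThresholdSet({0.90: 0.40, 0.98: 0.70})

boosts = compute_boosts(batch, thresholds, schedule)
total, per_sample = reshaped_binary_loss(batch, boosts)
_, plain = reshaped_binary_loss(batch, compute_boosts(batch, thresholds, None))

print("score  label  boost  plain_CE  boosted_CE")
for s, y, b, p, q in zip(batch.scores, batch.labels, boosts.boosts, plain, per_sample):
    print(f"{s:5.2f}  {y:5d}  {b:5.2f}  {p:8.4f}  {q:10.4f}")

# The borderline positive (0.55, below the 0.70 threshold) pays -ln(0.55-0.2)
# instead of -ln(0.55); the deep false negative (0.30, below 0.40) pays
# -ln(0.30-0.4 -> clamp) — a steeply amplified penalty. The negative and the
# confident positive keep their ordinary cross-entropy.
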