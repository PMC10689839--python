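"""One-vs-all reshaping for a critical class in a multi-class problem.

For samples of the critical class predicted below its high-specificity threshold,
probability mass is moved from the critical class onto the strongest competing
class — conserving total mass — which amplifies the gradient exactly as in the
binary case.
"""

import numpy as np

from aucreshape import MulticlassBatch, reshaped_multiclass_loss

probs = np.array(
    [
        [0.50, 0.30, 0.20],  # critical sample, under-confident -> boosted
        [0.10, 0.10, 0.80],  # critical sample, confident -> untouched
        [0.70, 0.20, 0.10],  # sample of another class -> untouched
    ]
)
labels = np.array([2, 2, 0])
batch = MulticlassBatch(probs, labels)

total, per_sample = reshaped_multiclass_loss(
    batch, critical_class=2, threshold=0.5, boost=0.1
)
plain = -np.log(probs[np.arange(3), labels])

print("label  p_label  plain_CE  boosted_CE")
for y, p, a, b in zip(labels, probs[np.arange(3), labels], plain, per_sample):
    print(f"{y:5d}  {p:7.2f}  {a:8.4f}  {b:10.4f}")

# The first sample's vector becomes [0.6, 0.3, 0.1]: 0.1 of mass moved from the
# critical class onto its strongest competitor, so the loss rises from -ln(0.2) to
# -ln(0.1) while the vector still sums to 1.
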