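# Methods

## Model and loss

The package targets binary screening problems with asymmetric misclassification
costs: a large positive ("normal") class, a small negative ("abnormal") class whose
false positives are expensive, and a deployment operating point in the
high-specificity region (false-positive rate of a few percent).  The training-time
modification is a boosted cross-entropy: for a positive sample whose predicted
probability `p` falls below the threshold realising a configured specificity level,
a constant boost `b` is subtracted from `p` inside the log, and symmetrically added
for the (never-triggered-in-practice) negative term:

    l_i = −[ y_i·log(p_i − b_i) + (1 − y_i)·log(1 − p_i + b_i) ]

The effect is purely a gradient amplification on the targeted samples:
`|dl/dp| = 1/(p − b) > 1/p` wherever the clamp is inactive.  Several design points
deserve explicit statement.

**Clamping.** `p − b` can reach zero or go negative for strongly misclassified
samples.  Both log arguments are floored at `ε = 1e−7`, which keeps the loss finite;
where the clamp is active the loss is flat, and the per-sample gradient is defined
as zero there.  Excessively large boosts therefore *silence* the deepest false
negatives rather than exploding the loss — one reason very large boosts degrade
rather than help.

**Band assignment for multi-level schedules.** With boosts `b_1..b_K` at strictly
increasing specificity levels `s_1..s_K` and realised thresholds `θ_1 ≤ … ≤ θ_K`,
the thresholds partition `(0, θ_K)` into bands and a misclassified positive receives
the boost of the single band containing its score: `b_k` applies on `[θ_{k−1}, θ_k)`
with `θ_0 = 0`.  Boosts never stack; the alternative (summing all triggered boosts)
was rejected because it can exceed `p` and saturate the clamp for the entire
overlap region.  Under this rule increasing and decreasing schedules are genuinely
different configurations.

**Where the boost enters.** The boost modifies the probability inside the loss,
exactly as written above.  Logit-space variants are a documented non-goal.

**Multi-class extension.** For a designated critical class `c` in a K-class
problem, samples of class `c` with `p_c` below the class's one-vs-all
high-specificity threshold have probability mass moved from `c` onto the strongest
competing class (argmax over non-critical classes, ties toward the lowest index):
`q_c = p_c − min(b, p_c)`, `q_m = p_m + min(b, p_c)`.  The `min` keeps every entry
in `[0, 1]` and conserves total mass exactly; the per-sample loss is `−log(q_label)`
with the same `ε` floor.  The direction of the transfer (diminish the critical
class, grow the competitor) is a documented convention: it amplifies the critical
class's gradient analogously to the binary case while keeping the vector on the
simplex.

## Operating-point metrics

All metrics share one decision rule — predict positive iff `score ≥ threshold` —
and one definition of specificity at a threshold: the fraction of negatives
*strictly below* it.  `threshold_at_specificity` returns the smallest observed
score whose specificity reaches the level (hence the sensitivity-maximising
qualifying threshold), or `+∞` when no observed score qualifies; no interpolation
is performed, and the realized specificity is reported alongside the sensitivity
because test-set levels rarely align exactly with validation levels.  ROC
construction delegates to scikit-learn with intermediate points retained, which
matches these conventions point-for-point; the trapezoidal AUC then equals the
tie-corrected Mann–Whitney statistic, a property the test suite checks exactly
against brute-force pair counting.

## Threshold tracking during training

The boost's conditional depends on thresholds that move as the model learns.  They
are re-estimated once per epoch from the model's current predictions on the full
training split (default; a per-batch mode and a validation-reference mode exist for
research use — per-batch quantile estimates of a 98th percentile from 100 samples
are far too noisy to be the default).  The first epoch always trains unboosted:
before a full forward pass there are no meaningful thresholds.  After training, the
thresholds realising each *evaluation* level are computed on the validation split
and carried to the test split as the actual classification thresholds.

## Training harness

The built-in model is a small dense network — linear layers with rectifier
activations and dropout 0.5 on hidden layers (default widths 32 and 16), sigmoid
output — with hand-derived gradients, since the boosted loss differentiates through
a per-sample-modified probability.  Defaults: Adam, learning rate 0.01, weight
decay 1e−5, batch size 100, 10 epochs, no class re-weighting (inverse-frequency and
fixed-positive-weight modes are available; for the synthetic conditions below,
inverse-frequency weighting suppresses the overlap region so strongly that the
hard subpopulation is never learned by either arm).  Model selection takes the
epoch with the lowest *plain* cross-entropy on validation, for baseline and
reshaped runs alike: selecting reshaped runs by their own boosted objective was
evaluated and favours late, heavily distorted epochs, performing clearly worse.
A loss or prediction that becomes non-finite marks the run failed; failed runs are
never averaged, and an experiment aborts if more than half its runs fail.

Repeated runs derive per-run seeds from one master seed.  Aggregation averages the
metrics of the top-k runs ranked by validation loss (metric averaging, not
parameter averaging), with bias-adjusted skewness and bias-adjusted excess
kurtosis computed over all runs' values — the adjusted excess convention is the
only common one consistent with kurtosis values below −2 at five runs.  Comparisons
report the percent change of full-precision means and a two-sided Mann–Whitney
rank test (robust at 5–10 runs; the flag is invariant to metric rescaling), with
α = 0.05 by default.

## Synthetic data

The generator emulates the screening structure the method targets, at desk scale:
5000 positives vs 200 negatives (≈4% minority prevalence standing in for the ~0.2%
of real fraud data) in 10 dimensions.  Negatives are a unit spherical Gaussian at
the origin.  Positives mix an *easy* component (70%, centred 6 pooled-sd away along
the first axis — essentially separable) with a *hard* component (30%) whose overall
centroid is the origin itself but whose samples concentrate on four compact patches
(radius 2 pooled-sd along each of two axes, within-patch spread 0.25) on the
diagonals of feature axes 1–2.

The patch structure is deliberate.  At ~2.8 pooled-sd from the origin the patches
lie *inside* the typical negative shell (radius √10 ≈ 3.16 in 10 dimensions), so
the hard positives genuinely overlap the negative density and no linear statistic
separates them — their component mean carries no signal.  Separation requires a
localized nonlinear feature, which a plain cross-entropy learner — dominated by the
easy majority — acquires slowly within a 10-epoch budget, leaving sensitivity at
98% specificity well below its ceiling.  That is the headroom the reshaped loss
exploits.  A single Gaussian overlap mode (centroid offset ≲0.5 sd, equal spread)
was analysed at the population level and discarded: its information ceiling at 98%
specificity sits within ~0.005 of what plain training already achieves, so no
training method could improve on the baseline there.

What the generator does *not* emulate: feature correlations, label noise,
covariate shift between splits, and the extreme prevalence of real screening data;
passing the efficacy check here demonstrates the mechanism (amplified gradients
accelerate learning of an under-served subpopulation at a fixed operating point),
not performance on any real modality.

## The efficacy experiment and its limits

The reference experiment pairs, over 10 derived seeds, a baseline and a reshaped
run (boost 0.2 at levels 0.90/0.92/0.95/0.98) on independently drawn
train/validation/test splits, comparing mean test sensitivity at 0.98 specificity
and mean AUC.  Problem sizes (5200 samples per split, 10 epochs, ~32k-parameter
network) keep the full paired experiment under ten seconds on one CPU.

Two caveats are part of the honest picture.  First, the mechanism is a
*training-dynamics* effect: at full convergence the boosted optimum shifts every
boosted score region up by approximately `+b`, which is ranking-neutral within a
region and mildly harmful across the threshold boundary — gains come from
accelerated feature acquisition in the under-trained regime, not from a better
asymptotic optimum.  Second, at this scale the effect is small relative to seed
noise: the dominant noise source is estimating a 98th-percentile threshold from
200 validation negatives, giving the 10-pair mean gain a standard error comparable
to the effect itself (both around 0.005–0.01).  The packaged test runs the
experiment at a fixed seed set; re-running it under other master seeds yields a
positive mean gain for most, but not all, seed sets, always with |ΔAUC| well under
0.02.  Larger paired-seed counts or validation sets would sharpen the comparison
but are deliberately kept at the stated study conditions.

## Degenerate inputs and numerical conventions

Scores are clamped to `(1e−7, 1 − 1e−7)` on batch construction; NaN scores are
rejected.  Tied scores collapse to single ROC points.  Constant metric vectors
report zero skewness/kurtosis with degeneracy implied; single-run reports carry a
zero, flagged standard deviation.  Identical constant samples on both sides of a
comparison receive p = 1 rather than a rank-test failure.  Logits are clipped at
±500 before the sigmoid, so extreme weights saturate probabilities instead of
overflowing.  All stochastic components (data generation, initialisation,
shuffling, dropout, oversampling) draw from per-run generators seeded
deterministically from the configured seed; derived seeds are produced by seed
sequences and kept below 2³¹.
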