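"""Paired baseline vs reshaped training on the synthetic screening data.

Generates the default imbalanced dataset (5000 positives, 200 negatives, 30% of
positives in a hard subpopulation embedded in the negative cloud), trains the MLP
once with plain cross-entropy and once with boost 0.2 at specificity levels
0.90/0.92/0.95/0.98, and compares the validation-threshold-carried-over test
metrics.  Runtime: a few seconds.
"""

from aucreshape import (
    BoostSchedule,
    MLPSpec,
    SyntheticSpec,
    TrainConfig,
    generate_splits,
    train_once,
)

seed = 11
splits = generate_splits(SyntheticSpec(seed=seed))
schedule = BoostSchedule.uniform(0.2, [0.90, 0.92, 0.95, 0.98])

baseline = train_once(splits, MLPSpec(), TrainConfig(seed=seed))
reshaped = train_once(splits, MLPSpec(), TrainConfig(seed=seed, schedule=schedule))

print(f"{'':12s} {'AUC':>7s} {'sens@0.95':>10s} {'sens@0.98':>10s} {'spec@0.98':>10s}")
for name, r in [("baseline", baseline), ("reshaped", reshaped)]:
    print(
        f"{name:12s} {r.auc_test:7.4f} {r.sens_test[0.95]:10.4f} "
        f"{r.sens_test[0.98]:10.4f} {r.realized_specificity_test[0.98]:10.4f}"
    )
print(
    f"\nbest epochs: baseline {baseline.best_epoch}, reshaped {reshaped.best_epoch}; "
    f"thresholds were refreshed {len(reshaped.threshold_history.records)} times"
)

# The reshaped run typically recovers a few extra percent of the hard positives at
# the 98%-specificity operating point while the AUC moves by well under 0.01; the
# realized test specificity shows how closely the carried-over validation threshold
# lands on the requested level.
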