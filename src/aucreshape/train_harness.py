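"""Fine-tuning loop wiring the boosted loss, threshold tracker and ROC metrics.

The protocol mirrors how a high-specificity detector is trained and evaluated:

1. train with (plain or reshaped) cross-entropy, refreshing the high-specificity
   thresholds from the model's current predictions (first epoch unboosted — no
   meaningful thresholds exist yet);
2. select the epoch with the lowest plain validation cross-entropy;
3. determine the thresholds realising each evaluation specificity level on the
   validation split and carry them over to the test split as the classification
   thresholds, reporting test sensitivity together with the realised test
   specificity (test specificity levels rarely align exactly with validation).

Repeated runs with derived seeds are aggregated by averaging the metrics of the
``top_k`` runs ranked by validation loss, with distribution-shape statistics over
all runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_loss import (
    EPS,
    BoostSchedule,
    BoostVector,
    PredictionBatch,
    compute_boosts,
    reshaped_binary_loss,
)
from .mlp import MLP, MLPSpec, make_optimizer
from .reporting import MetricsReport
from .roc_metrics import auc, confusion_at_threshold, roc_curve
from .threshold_tracker import RefreshPolicy, ThresholdHistory, ThresholdSet, refresh

__all__ = ["TrainConfig", "RunResult", "TrainingDiverged", "train_once", "run_repeated"]

DEFAULT_EVAL_LEVELS = (0.95, 0.98)


class TrainingDiverged(RuntimeError):
    """The loss became non-finite; the run is marked failed, never averaged."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run.

    ``class_weighting`` is ``"none"``, ``"inverse_frequency"`` (per-class weight
    proportional to the inverse class frequency in the training split) or
    ``("fixed", w_pos)``.  ``schedule=None`` is the baseline run (plain
    cross-entropy).
    """

    epochs: int = 10
    learning_rate: float = 0.01
    weight_decay: float = 1e-5
    batch_size: int = 100
    optimizer: str = "adam"
    class_weighting: object = "none"
    oversample_minority: bool = False
    schedule: BoostSchedule | None = None
    refresh: RefreshPolicy = field(default_factory=RefreshPolicy)
    eval_levels: tuple[float, ...] = DEFAULT_EVAL_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class RunResult:
    seed: int
    best_epoch: int
    best_val_loss: float
    auc_val: float
    auc_test: float
    sens_val: dict[float, float]
    sens_test: dict[float, float]
    realized_specificity_test: dict[float, float]
    threshold_history: ThresholdHistory
    failed: bool = False

    def metrics(self) -> dict[str, float]:
        out = {"auc": self.auc_test}
        for level, s in self.sens_test.items():
            out[f"sens_at_{level:g}"] = s
        return out


def _split_xy(df: pd.DataFrame, label_col: str):
    X = df.drop(columns=[label_col]).to_numpy(float)
    y = df[label_col].to_numpy(int)
    return X, y


def _class_weights(mode, y: np.ndarray) -> tuple[float, float]:
    if mode == "none" or mode is None:
        return (1.0, 1.0)
    if mode == "inverse_frequency":
        n = y.size
        n_pos = int(y.sum())
        n_neg = n - n_pos
        # normalised so the average sample keeps unit weight
        return (n / (2.0 * n_neg), n / (2.0 * n_pos))
    if isinstance(mode, tuple) and len(mode) == 2 and mode[0] == "fixed":
        return (1.0, float(mode[1]))
    raise ValueError(f"unknown class_weighting {mode!r}")


def _plain_ce(p: np.ndarray, y: np.ndarray) -> float:
    total, _ = reshaped_binary_loss(PredictionBatch(p, y), BoostVector.zeros(p.size))
    return total / p.size


def _dloss_dp(p: np.ndarray, y: np.ndarray, thresholds: ThresholdSet | None,
              schedule: BoostSchedule | None, weights: tuple[float, float]) -> np.ndarray:
    """Per-sample derivative of the mean reshaped loss with respect to p.

    Inactive wherever the EPS clamp binds (the loss is flat there by construction).
    """
    if not np.isfinite(p).all():
        raise TrainingDiverged("non-finite predictions during training")
    batch = PredictionBatch(p, y)
    p = batch.scores
    if thresholds is not None and schedule is not None:
        b = compute_boosts(batch, thresholds, schedule).boosts
    else:
        b = np.zeros(p.size)
    w_neg, w_pos = weights
    pos_arg = p - b
    neg_arg = 1.0 - p + b
    grad = np.where(
        y == 1,
        np.where(pos_arg > EPS, -w_pos / np.maximum(pos_arg, EPS), 0.0),
        np.where(neg_arg > EPS, w_neg / np.maximum(neg_arg, EPS), 0.0),
    )
    return grad / p.size


def train_once(
    splits: Mapping[str, pd.DataFrame],
    model_spec: MLPSpec,
    config: TrainConfig,
    label_col: str = "label",
) -> RunResult:
    """Train the MLP once and evaluate with the validation-to-test carry-over.

    ``splits`` maps ``train`` / ``validation`` / ``test`` to feature tables with a
    binary label column.  Deterministic for a fixed config.
    """
    for name in ("train", "validation", "test"):
        if splits[name][label_col].nunique() != 2:
            raise ValueError(f"{name} split must contain both classes")

    X_tr, y_tr = _split_xy(splits["train"], label_col)
    X_va, y_va = _split_xy(splits["validation"], label_col)
    X_te, y_te = _split_xy(splits["test"], label_col)

    # standardise features on training statistics
    mu = X_tr.mean(axis=0)
    sd = np.maximum(X_tr.std(axis=0), 1e-9)
    X_tr = (X_tr - mu) / sd
    X_va = (X_va - mu) / sd
    X_te = (X_te - mu) / sd

    rng = np.random.default_rng(config.seed)
    model = MLP(X_tr.shape[1], model_spec, rng)
    optimizer = make_optimizer(config.optimizer, config.learning_rate, config.weight_decay)
    weights = _class_weights(config.class_weighting, y_tr)
    schedule = config.schedule
    if schedule is not None and len(schedule) == 0:
        schedule = None

    n = y_tr.size
    if config.oversample_minority:
        class_p = np.where(y_tr == 1, 1.0 / max(y_tr.sum(), 1), 1.0 / max(n - y_tr.sum(), 1))
        class_p = class_p / class_p.sum()

    def reference_batch() -> PredictionBatch:
        if config.refresh.reference == "validation":
            return PredictionBatch(model.forward(X_va), y_va)
        return PredictionBatch(model.forward(X_tr), y_tr)

    history = ThresholdHistory()
    thresholds: ThresholdSet | None = None
    best_val_loss = np.inf
    best_epoch = -1
    best_state = model.get_state()

    for epoch in range(config.epochs):
        # warm-up: the first epoch trains unboosted
        if schedule is not None and epoch > 0 and config.refresh.mode == "per_epoch":
            thresholds = refresh(reference_batch(), schedule)
            history.append(epoch, thresholds)
        idx = (
            rng.choice(n, size=n, p=class_p)
            if config.oversample_minority
            else rng.permutation(n)
        )
        for start in range(0, n, config.batch_size):
            take = idx[start : start + config.batch_size]
            if schedule is not None and epoch > 0 and config.refresh.mode == "per_batch":
                thresholds = refresh(reference_batch(), schedule)
            Xb, yb = X_tr[take], y_tr[take]
            _, gW, gb = model.backward(
                Xb,
                lambda p: _dloss_dp(p, yb, thresholds, schedule, weights),
                train=True,
            )
            if any(not np.isfinite(g).all() for g in gW + gb):
                raise TrainingDiverged(f"non-finite gradient at epoch {epoch}")
            optimizer.step(model, gW, gb)

        p_va = model.forward(X_va)
        val_loss = _plain_ce(p_va, y_va)
        if not np.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_epoch = epoch
            best_state = model.get_state()

    model.set_state(best_state)
    val_batch = PredictionBatch(model.forward(X_va), y_va)
    test_batch = PredictionBatch(model.forward(X_te), y_te)

    sens_val, sens_test, realized_spec = {}, {}, {}
    eval_set = refresh(val_batch, BoostSchedule([(s, 0.0) for s in config.eval_levels]))
    for level in config.eval_levels:
        theta = eval_set[level]
        sens_val[level] = confusion_at_threshold(val_batch, theta).sensitivity
        test_counts = confusion_at_threshold(test_batch, theta)
        sens_test[level] = test_counts.sensitivity
        realized_spec[level] = test_counts.specificity

    return RunResult(
        seed=config.seed,
        best_epoch=best_epoch,
        best_val_loss=float(best_val_loss),
        auc_val=auc(roc_curve(val_batch)),
        auc_test=auc(roc_curve(test_batch)),
        sens_val=sens_val,
        sens_test=sens_test,
        realized_specificity_test=realized_spec,
        threshold_history=history,
    )


def run_repeated(
    splits: Mapping[str, pd.DataFrame],
    model_spec: MLPSpec,
    config: TrainConfig,
    n_runs: int,
    top_k: int,
    label_col: str = "label",
) -> MetricsReport:
    """Execute ``n_runs`` seeded runs and aggregate the ``top_k`` by validation loss.

    Per-run seeds are derived deterministically from ``config.seed``.  Runs whose
    loss diverges are recorded as failed and excluded; more than half failing aborts
    with diagnostics.
    """
    if not 1 <= top_k <= n_runs:
        raise ValueError("need 1 <= top_k <= n_runs")
    run_seeds = np.random.SeedSequence(config.seed).generate_state(n_runs) % (2**31)
    results: list[RunResult] = []
    failures: list[str] = []
    for i, s in enumerate(run_seeds):
        cfg = replace(config, seed=int(s))
        try:
            results.append(train_once(splits, model_spec, cfg, label_col))
        except TrainingDiverged as err:
            failures.append(f"run {i} (seed {int(s)}): {err}")
    if len(failures) > n_runs / 2:
        raise RuntimeError(
            "more than half of the runs diverged:\n" + "\n".join(failures)
        )
    return MetricsReport.from_runs(results, top_k=min(top_k, len(results)), failures=failures)
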