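"""Tracking of high-specificity thresholds during training.

The boost is conditional on the *current* model: a positive is boosted when its score
falls below the threshold realising a configured specificity level on a reference
set of predictions.  Those thresholds move as the model learns, so they are
re-estimated ("refreshed") during training — by default once per epoch on the full
training set's predictions, since per-batch quantile estimates of a 98th percentile
from 64-100 samples are far too noisy.  The first epoch trains without boosting:
no meaningful thresholds exist before the first full forward pass.

After training, thresholds are determined on the validation split and carried over
to the test split as the actual classification thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .core_loss import BoostSchedule, PredictionBatch
from .roc_metrics import threshold_at_specificity

__all__ = ["ThresholdSet", "RefreshPolicy", "TrackerError", "refresh", "ThresholdHistory"]


class TrackerError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Mapping specificity level -> score threshold, aligned with a schedule."""

    entries: dict[float, float]

    def __getitem__(self, level: float) -> float:
        return self.entries[level]

    def __iter__(self) -> Iterator[float]:
        return iter(self.entries)

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(self.entries)

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(self.entries.values())


@dataclass(frozen=True)
class RefreshPolicy:
    """When and on which split thresholds are re-estimated during training.

    mode: 'per_epoch' (default) or 'per_batch'; reference: 'train' (default) or
    'validation'.
    """

    mode: str = "per_epoch"
    reference: str = "train"

    def __post_init__(self) -> None:
        if self.mode not in ("per_epoch", "per_batch"):
            raise ValueError("mode must be 'per_epoch' or 'per_batch'")
        if self.reference not in ("train", "validation"):
            raise ValueError("reference must be 'train' or 'validation'")


def refresh(reference_batch: PredictionBatch, schedule: BoostSchedule) -> ThresholdSet:
    """Compute the threshold realising each schedule level on the reference batch.

    Deterministic: a fixed batch always yields the identical ThresholdSet.
    """
    if reference_batch.n_pos == 0 or reference_batch.n_neg == 0:
        raise TrackerError(
            "threshold refresh needs both classes in the reference batch; "
            f"got {reference_batch.n_pos} positives and {reference_batch.n_neg} "
            "negatives — check the split or the refresh policy's reference"
        )
    return ThresholdSet(
        {s: threshold_at_specificity(reference_batch, s) for s in schedule.levels}
    )


@dataclass
class ThresholdHistory:
    """Per-epoch threshold log, serialisable to JSON for auditability."""

    records: list[dict] = field(default_factory=list)

    def append(self, epoch: int, thresholds: ThresholdSet) -> None:
        self.records.append(
            {"epoch": epoch, "thresholds": {f"{s:g}": t for s, t in thresholds.entries.items()}}
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.records, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
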