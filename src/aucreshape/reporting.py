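"""Aggregation and comparison of repeated-run metrics.

Reports follow the convention of the reshaping literature's result tables: each
configuration is summarised as mean ± sd of AUC and sensitivity-at-specificity over
the top-k runs (ranked by validation loss), with bias-adjusted skewness and excess
kurtosis over all measured values, and a treated-vs-baseline comparison giving the
percent change per metric and a rank-based significance flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricsReport", "shape_stats", "compare", "percent_change"]


def shape_stats(values) -> tuple[float, float]:
    """Bias-adjusted Fisher-Pearson skewness and bias-adjusted excess kurtosis.

    The adjusted (sample-size corrected) excess form is the convention here: it is
    the only common kurtosis definition that can print values below -2 on as few as
    five runs.  Constant input is degenerate — both statistics are reported as 0
    (callers may check :func:`is_degenerate`).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.allclose(values, values[0]):
        return (0.0, 0.0)
    skew = float(stats.skew(values, bias=False))
    if values.size < 4:
        return (skew, 0.0)
    return (skew, float(stats.kurtosis(values, fisher=True, bias=False)))


def percent_change(treated_mean: float, baseline_mean: float) -> float:
    """100 * (treated - baseline) / baseline."""
    return 100.0 * (treated_mean - baseline_mean) / baseline_mean


@dataclass
class MetricsReport:
    """Aggregated metrics of a repeated-run experiment.

    ``values`` maps each metric name (``auc``, ``sens_at_0.95`` ...) to the per-run
    values of the top-k selected runs; ``all_values`` to every successful run's
    values (used for the shape statistics, which describe the whole distribution of
    measured sensitivities, not just the selected runs).
    """

    values: dict[str, np.ndarray]
    all_values: dict[str, np.ndarray]
    n_runs: int
    top_k: int
    failures: list[str] = field(default_factory=list)
    per_run: list = field(default_factory=list)

    @classmethod
    def from_runs(cls, results, top_k: int, failures=()) -> "MetricsReport":
        order = np.argsort([r.best_val_loss for r in results], kind="stable")
        selected = [results[i] for i in order[:top_k]]
        metric_names = list(results[0].metrics()) if results else []
        values = {
            m: np.array([r.metrics()[m] for r in selected]) for m in metric_names
        }
        all_values = {
            m: np.array([r.metrics()[m] for r in results]) for m in metric_names
        }
        return cls(
            values=values,
            all_values=all_values,
            n_runs=len(results),
            top_k=top_k,
            failures=list(failures),
            per_run=list(results),
        )

    @property
    def metric_names(self) -> list[str]:
        return list(self.values)

    def mean(self, metric: str) -> float:
        return float(self.values[metric].mean())

    def sd(self, metric: str) -> float:
        v = self.values[metric]
        # a single run has no spread; reported as 0 and flagged via sd_defined
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def sd_defined(self) -> bool:
        return self.top_k > 1

    def shape(self, metric: str) -> tuple[float, float]:
        v = self.all_values[metric]
        if v.size < 3:
            return (0.0, 0.0)
        return shape_stats(v)

    def summary(self) -> dict:
        out = {
            "n_runs": self.n_runs,
            "top_k": self.top_k,
            "sd_defined": self.sd_defined,
            "failures": self.failures,
            "metrics": {},
        }
        for m in self.metric_names:
            skew, kurt = self.shape(m)
            out["metrics"][m] = {
                "mean": self.mean(m),
                "sd": self.sd(m),
                "skewness": skew,
                "excess_kurtosis": kurt,
                "values": self.values[m].tolist(),
                "all_values": self.all_values[m].tolist(),
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.summary(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricsReport":
        data = json.loads(Path(path).read_text())
        values = {m: np.array(d["values"]) for m, d in data["metrics"].items()}
        all_values = {
            m: np.array(d.get("all_values", d["values"]))
            for m, d in data["metrics"].items()
        }
        return cls(
            values=values,
            all_values=all_values,
            n_runs=data["n_runs"],
            top_k=data["top_k"],
            failures=list(data.get("failures", [])),
        )


def compare(treated: MetricsReport, baseline: MetricsReport, alpha: float = 0.05) -> pd.DataFrame:
    """Treated-vs-baseline comparison table.

    Per shared metric: both means, the percent change of the treated mean relative
    to the baseline mean, a two-sided Mann-Whitney rank-test p-value over the
    selected runs (omitted, with a flag, when either side has fewer than 2 runs),
    and a significance asterisk iff p < alpha.
    """
    rows = []
    metrics = [m for m in treated.metric_names if m in baseline.metric_names]
    if not metrics:
        raise ValueError("no shared metrics to compare")
    for m in metrics:
        t, b = treated.values[m], baseline.values[m]
        row = {
            "metric": m,
            "baseline_mean": baseline.mean(m),
            "treated_mean": treated.mean(m),
            "percent_change": percent_change(treated.mean(m), baseline.mean(m)),
        }
        if t.size >= 2 and b.size >= 2:
            if np.allclose(t, t[0]) and np.allclose(b, b[0]) and np.isclose(t[0], b[0]):
                row["p_value"] = 1.0  # identical constant samples: no evidence
            else:
                row["p_value"] = float(
                    stats.mannwhitneyu(t, b, alternative="two-sided").pvalue
                )
            row["significant"] = bool(row["p_value"] < alpha)
            row["p_value_defined"] = True
        else:
            row["p_value"] = float("nan")
            row["significant"] = False
            row["p_value_defined"] = False
        rows.append(row)
    return pd.DataFrame(rows)
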