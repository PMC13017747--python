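"""Evaluation metrics for probabilistic binary mortality prediction.

Five metrics are reported per model: ROC-AUC, PR-AUC (average precision),
R-squared on probabilities, Efron's pseudo R-squared, and the Inter-Model
Vigorish (IMV). PR-AUC is the primary metric for imbalanced outcomes; its
no-skill baseline equals the outcome prevalence, which is therefore carried
alongside every report as the "IP" (in-sample prevalence) row.

IMV
---
For a vector of Bernoulli predictions the mean log-likelihood
``L = mean(y log p + (1-y) log(1-p))`` maps to an *entropy-equivalent
bet-winning probability* ``w in [0.5, 1)`` solving

    w ln w + (1 - w) ln(1 - w) = L.

A model with w = 0.72 is as informative as a weighted coin landing heads
72% of the time. The IMV of an enhanced model over a baseline is the
relative gain ``(w1 - w0) / w0``: the fraction by which the enhanced model
raises the equivalent bet-winning probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "METRIC_NAMES",
    "roc_auc",
    "pr_auc",
    "r2_binary",
    "pseudo_r2",
    "entropy_equivalent_w",
    "imv",
    "compute_all_metrics",
    "MetricReport",
    "aggregate_report",
]

METRIC_NAMES = ("roc_auc", "pr_auc", "r2", "pseudo_r2", "imv")

PROB_CLIP = 1e-12  # probabilities are clipped to [PROB_CLIP, 1-PROB_CLIP] before logs


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary 0/1")
    return y


def roc_auc(y: Sequence[int], p: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count half)."""
    y = _check_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both outcome classes")
    return float(roc_auc_score(y, p))


def pr_auc(y: Sequence[int], p: Sequence[float]) -> float:
    """Area under the precision-recall curve in average-precision (step) form.

    A constant predictor scores exactly the prevalence, which is the
    interpretation baseline (probability of random guessing).
    """
    y = _check_binary(y)
    if y.sum() == 0:
        raise ValueError("pr_auc requires at least one positive")
    return float(average_precision_score(y, p))


def r2_binary(y: Sequence[int], p: Sequence[float]) -> float:
    """R-squared of predicted probabilities against the 0/1 outcome."""
    y = _check_binary(y).astype(float)
    p = np.asarray(p, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant outcome: R^2 undefined")
    return 1.0 - float(np.sum((y - p) ** 2)) / ss_tot


def pseudo_r2(y: Sequence[int], p: Sequence[float]) -> float:
    """Efron's pseudo R-squared; identical to :func:`r2_binary` on
    probabilities, which is why the two columns of a model-comparison table
    agree to the printed precision."""
    return r2_binary(y, p)


def _mean_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(np.asarray(p, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y, dtype=float)
    return float(np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def entropy_equivalent_w(mean_loglik: float, tol: float = 1e-12) -> float:
    """Invert the Bernoulli entropy to the bet-winning probability w.

    Solves ``w ln w + (1-w) ln(1-w) = mean_loglik`` for ``w in [0.5, 1)``
    by bracketed root finding to |dw| < 1e-10. Mean log-likelihoods below
    ln(1/2) (worse than a fair coin) are clipped to ln(1/2), mapping to
    w = 0.5.
    """
    if mean_loglik >= 0.0:
        raise ValueError("mean log-likelihood must be negative")
    ln_half = float(np.log(0.5))
    if mean_loglik <= ln_half:
        return 0.5

    def h(w: float) -> float:
        return w * np.log(w) + (1.0 - w) * np.log(1.0 - w) - mean_loglik

    return float(brentq(h, 0.5, 1.0 - 1e-15, xtol=tol))


def imv(y: Sequence[int], p_baseline: Sequence[float], p_enhanced: Sequence[float]) -> float:
    """Inter-Model Vigorish: relative gain (w1 - w0)/w0 in entropy-equivalent
    bet-winning probability of the enhanced over the baseline predictions."""
    y = _check_binary(y)
    w0 = entropy_equivalent_w(_mean_loglik(y, np.asarray(p_baseline)))
    w1 = entropy_equivalent_w(_mean_loglik(y, np.asarray(p_enhanced)))
    return (w1 - w0) / w0


def compute_all_metrics(
    y: Sequence[int],
    p: Sequence[float],
    p_baseline: Sequence[float] | None = None,
) -> dict[str, float]:
    """All five metrics for one prediction vector.

    ``p_baseline`` anchors the IMV; by default the prevalence-constant
    predictor on the evaluation set (the canonical no-information null).
    """
    y = _check_binary(y)
    if p_baseline is None:
        p_baseline = np.full(len(y), float(np.mean(y)))
    return {
        "roc_auc": roc_auc(y, p),
        "pr_auc": pr_auc(y, p),
        "r2": r2_binary(y, p),
        "pseudo_r2": pseudo_r2(y, p),
        "imv": imv(y, p_baseline, p),
    }


# ---------------------------------------------------------------------------
# Seed-replication report


@dataclass
class MetricReport:
    """Per-model, per-metric mean and standard error across seeds.

    ``table`` is long-format with columns (model, metric, mean, se, n_seeds);
    ``per_seed`` keeps the raw values; ``in_sample_prevalence`` is the mean
    test-set prevalence across seeds (the IP row of a results table).
    """

    table: pd.DataFrame
    per_seed: dict = field(default_factory=dict)
    in_sample_prevalence: float = float("nan")

    def value(self, model: str, metric: str) -> float:
        row = self.table[(self.table["model"] == model) & (self.table["metric"] == metric)]
        if row.empty:
            raise KeyError((model, metric))
        return float(row["mean"].iloc[0])

    def se(self, model: str, metric: str) -> float:
        row = self.table[(self.table["model"] == model) & (self.table["metric"] == metric)]
        if row.empty:
            raise KeyError((model, metric))
        return float(row["se"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "in_sample_prevalence": self.in_sample_prevalence,
            "rows": self.table.to_dict(orient="records"),
            "per_seed": {f"{m}/{k}": list(v) for (m, k), v in self.per_seed.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def aggregate_report(
    per_seed_metrics: Mapping[tuple[str, str], Sequence[float]],
    in_sample_prevalence: Sequence[float] | float = float("nan"),
) -> MetricReport:
    """Aggregate per-seed metric values into mean +- SE rows.

    SE is the sample standard deviation across seeds divided by sqrt(#seeds);
    with a single seed it is reported as 0.
    """
    rows = []
    for (model, metric), values in per_seed_metrics.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"no values for ({model}, {metric})")
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append(
            {"model": model, "metric": metric, "mean": float(v.mean()), "se": se, "n_seeds": int(v.size)}
        )
    ip = float(np.mean(np.atleast_1d(in_sample_prevalence)))
    return MetricReport(
        table=pd.DataFrame(rows),
        per_seed={k: list(map(float, v)) for k, v in per_seed_metrics.items()},
        in_sample_prevalence=ip,
    )
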