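"""Reporting statistics over run distributions.

Accuracy, per-class miss rate and recall come from the pooled confusion
matrix of a run's leave-out predictions; distributions over runs are
summarised with five-number boxplot statistics where the whisker endpoints
("adjacent values") are the most extreme observations within 1.5 x IQR of
the quartiles, and quartiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix


def confusion_and_metrics(y_true, y_pred, labels=None):
    """Confusion matrix plus accuracy, per-class miss rate and recall.

    Miss rate is 1 - recall per class exactly; accuracy is trace / total.
    Classes absent from ``y_true`` get NaN recall/miss rate.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label sequences must be non-empty and equal length")
    labels = list(labels) if labels is not None else sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    recalls, miss_rates = {}, {}
    for i, lab in enumerate(labels):
        row = cm[i].sum()
        recalls[lab] = float(cm[i, i] / row) if row else float("nan")
        miss_rates[lab] = 1.0 - recalls[lab] if row else float("nan")
    return cm, accuracy, miss_rates, recalls


@dataclass
class EvalSummary:
    """Five-number boxplot summary of one metric's run distribution."""

    median: float
    q1: float
    q3: float
    lower_adjacent: float
    upper_adjacent: float
    n: int
    metric: str = ""
    regime: str = ""

    def __post_init__(self):
        if not (
            self.lower_adjacent <= self.q1 <= self.median
            <= self.q3 <= self.upper_adjacent
        ):
            raise ValueError("boxplot statistics out of order")


def boxplot_stats(values, metric: str = "", regime: str = "") -> EvalSummary:
    """Median, quartiles (linear interpolation) and Tukey 1.5xIQR adjacents."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("boxplot statistics need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    inside = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return EvalSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        lower_adjacent=float(inside.min()), upper_adjacent=float(inside.max()),
        n=int(values.size), metric=metric, regime=regime,
    )


def chance_level(n_classes: int) -> float:
    """Expected accuracy of uninformed guessing: 1 / number of classes."""
    if n_classes < 2:
        raise ValueError("chance level needs at least two classes")
    return 1.0 / n_classes


def summarize_runs(results, metric: str = "accuracy") -> EvalSummary:
    """Boxplot summary of a per-run metric over a list of run results."""
    if metric == "accuracy":
        values = [r.accuracy for r in results]
    elif metric == "miss_rate":
        values = [m for r in results for m in r.miss_rates.values()]
    elif metric == "recall":
        values = [m for r in results for m in r.recalls.values()]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    regime = results[0].regime if results else ""
    return boxplot_stats(values, metric=metric, regime=regime)
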