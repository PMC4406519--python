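"""Cut-off based classification metrics for probabilistic risk predictions.

Continuous complication probabilities are dichotomised at a percentage
cut-off (prediction >= cutoff/100 counts as "yes") and tallied against the
observed outcomes. Sensitivity, specificity, positive predictive value
(precision) and accuracy follow from the confusion counts; metrics whose
denominator is zero are reported as missing (NaN), never as zero. The
default cut-off sweep is 60/70/80/90/100 percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricRow",
    "confusion_at_cutoff",
    "classification_metrics",
    "sweep_cutoffs",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (60.0, 70.0, 80.0, 90.0, 100.0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRow:
    cutoff_percent: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float


def _normalize_outcomes(outcomes: Sequence) -> list[bool]:
    out = []
    for o in outcomes:
        if isinstance(o, str):
            s = o.strip().lower()
            if s not in ("yes", "no"):
                raise ValueError(f"outcome must be 'yes' or 'no', got {o!r}")
            out.append(s == "yes")
        else:
            out.append(bool(o))
    return out


def confusion_at_cutoff(
    predicted: Sequence[float], outcomes: Sequence, cutoff_percent: float
) -> ConfusionCounts:
    """Tally confusion counts at one percentage cut-off (inclusive >=)."""
    if len(predicted) != len(outcomes):
        raise ValueError(
            f"{len(predicted)} predictions vs {len(outcomes)} outcomes"
        )
    if not (0.0 <= cutoff_percent <= 100.0):
        raise ValueError("cutoff must be in [0, 100] percent")
    thresh = cutoff_percent / 100.0
    tp = fp = tn = fn = 0
    for p, truth in zip(predicted, _normalize_outcomes(outcomes)):
        pred_yes = p >= thresh
        if pred_yes and truth:
            tp += 1
        elif pred_yes and not truth:
            fp += 1
        elif not pred_yes and not truth:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(
    c: ConfusionCounts, cutoff_percent: float = math.nan
) -> MetricRow:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), precision tp/(tp+fp),
    accuracy (tp+tn)/total; undefined ratios are NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated patients")
    return MetricRow(
        cutoff_percent=cutoff_percent,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


def sweep_cutoffs(
    predicted: Sequence[float],
    outcomes: Sequence,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[MetricRow]:
    """One MetricRow per cut-off, in input order."""
    if not cutoffs:
        raise ValueError("cutoff list must be non-empty")
    return [
        classification_metrics(
            confusion_at_cutoff(predicted, outcomes, c), cutoff_percent=c
        )
        for c in cutoffs
    ]


def metrics_frame(rows: Sequence[MetricRow], complication: str = "") -> pd.DataFrame:
    """Tabular report (one row per cut-off) ready for CSV export."""
    df = pd.DataFrame(
        {
            "cutoff_percent": [r.cutoff_percent for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
            "specificity": [r.specificity for r in rows],
            "precision": [r.precision for r in rows],
            "accuracy": [r.accuracy for r in rows],
        }
    )
    if complication:
        df.insert(0, "complication", complication)
    return df
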