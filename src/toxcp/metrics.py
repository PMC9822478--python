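"""Evaluation measures for conformal toxicity classifiers.

Validity (per class): fraction of true-class-c evaluation compounds
whose prediction set contains c — a both-label set is always correct,
an empty set always an error.  A model is flagged valid at significance
epsilon when its error rate exceeds epsilon by at most 2.5 percentage
points.

Efficiency (per class): fraction of true-class-c compounds receiving
exactly one label, right or wrong — the informative predictions.

Sensitivity / specificity / balanced accuracy are computed over the
single-label predictions only (both and empty sets carry no committed
class call), with class 1 — the minority/toxic class under the
standard coding — as positive.  Undefined ratios (zero denominator)
are reported as missing, never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .conformal import Outcome, PredictionSetRecord

#: Tolerance by which the error rate may exceed the significance level
#: and the model still count as valid.
VALIDITY_TOLERANCE = 0.025

_OUTCOMES = [o.value for o in Outcome]


def _labels_for(
    sets: Sequence[PredictionSetRecord], true_labels
) -> np.ndarray:
    """Align true labels to the prediction-set records (hard error on
    any id mismatch)."""
    if isinstance(true_labels, Mapping):
        missing = [r.id for r in sets if r.id not in true_labels]
        if missing:
            raise ValueError(f"no true label for ids {missing[:10]}")
        return np.asarray([int(true_labels[r.id]) for r in sets])
    arr = np.asarray(true_labels, dtype=int)
    if arr.shape[0] != len(sets):
        raise ValueError("true_labels length does not match prediction sets")
    return arr


def outcome_contingency(
    sets: Sequence[PredictionSetRecord], true_labels
) -> pd.DataFrame:
    """2 (true class) x 4 (outcome) count table.

    Rows are true classes 0 and 1; columns the four conformal outcomes.
    Row sums equal the per-class evaluation sizes.
    """
    y = _labels_for(sets, true_labels)
    table = pd.DataFrame(0, index=[0, 1], columns=_OUTCOMES, dtype=int)
    for rec, label in zip(sets, y):
        table.loc[int(label), rec.outcome.value] += 1
    table.index.name = "true_class"
    return table


def validity(sets: Sequence[PredictionSetRecord], true_labels, c: int) -> float:
    """Fraction of true-class-c compounds whose set contains c."""
    y = _labels_for(sets, true_labels)
    mask = y == c
    if not mask.any():
        raise ValueError(f"no true class-{c} compounds in evaluation set")
    hits = sum(1 for rec, m in zip(sets, mask) if m and c in rec.set)
    return hits / int(mask.sum())


def efficiency(sets: Sequence[PredictionSetRecord], true_labels, c: int) -> float:
    """Fraction of true-class-c compounds with a single-label set."""
    y = _labels_for(sets, true_labels)
    mask = y == c
    if not mask.any():
        raise ValueError(f"no true class-{c} compounds in evaluation set")
    singles = sum(1 for rec, m in zip(sets, mask) if m and rec.is_single)
    return singles / int(mask.sum())


def validity_flag(validity_fraction: float, epsilon: float) -> bool:
    """True iff the error rate stays within epsilon + 2.5 points."""
    return (1.0 - validity_fraction) <= epsilon + VALIDITY_TOLERANCE


def confusion_metrics(
    sets: Sequence[PredictionSetRecord], true_labels, positive_class: int = 1
):
    """SE, SP, BA over single-label predictions, plus the full 2x4
    contingency.

    Returns ``(se, sp, ba, contingency)``; any ratio with a zero
    denominator comes back as ``None``.
    """
    y = _labels_for(sets, true_labels)
    neg = 1 - positive_class
    tp = fn = tn = fp = 0
    for rec, label in zip(sets, y):
        if not rec.is_single:
            continue
        (pred,) = rec.set
        if label == positive_class:
            tp, fn = (tp + 1, fn) if pred == positive_class else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == neg else (tn, fp + 1)
    se = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    ba = (se + sp) / 2 if se is not None and sp is not None else None
    return se, sp, ba, outcome_contingency(sets, y)


@dataclass
class CPMetricsReport:
    """One benchmark-table row: per-class validity/efficiency with
    validity flags, SE/SP/BA, and the outcome contingency."""

    dataset: str
    method: str
    epsilon: float
    validity: dict[int, float]
    efficiency: dict[int, float]
    is_valid: dict[int, bool]
    se: Optional[float]
    sp: Optional[float]
    ba: Optional[float]
    contingency: pd.DataFrame = field(repr=False, default=None)


def evaluate_sets(
    sets: Sequence[PredictionSetRecord],
    true_labels,
    epsilon: float,
    dataset: str = "eval",
    method: str = "rf",
    positive_class: int = 1,
) -> CPMetricsReport:
    """Compute the full report for one (dataset, method, epsilon)."""
    y = _labels_for(sets, true_labels)
    val = {c: validity(sets, y, c) for c in (0, 1)}
    eff = {c: efficiency(sets, y, c) for c in (0, 1)}
    flags = {c: validity_flag(val[c], epsilon) for c in (0, 1)}
    se, sp, ba, cont = confusion_metrics(sets, y, positive_class=positive_class)
    return CPMetricsReport(
        dataset=dataset,
        method=method,
        epsilon=float(epsilon),
        validity=val,
        efficiency=eff,
        is_valid=flags,
        se=se,
        sp=sp,
        ba=ba,
        contingency=cont,
    )


REPORT_COLUMNS = [
    "dataset",
    "method",
    "significance",
    "validity_1",
    "validity_0",
    "efficiency_1",
    "efficiency_0",
    "SE",
    "SP",
    "BA",
]


def report_table(
    reports: Sequence[CPMetricsReport], blank_invalid: bool = True
) -> pd.DataFrame:
    """Render reports as a benchmark-style table, one row per
    (dataset, method, epsilon).

    With ``blank_invalid`` (the default), rows where either class fails
    its validity flag get blank efficiency/SE/SP/BA cells — an invalid
    model's efficiency is not meaningful.  Undefined metrics are always
    blank.
    """
    rows = []
    for r in reports:
        blank = blank_invalid and not (r.is_valid[0] and r.is_valid[1])
        rows.append(
            {
                "dataset": r.dataset,
                "method": r.method,
                "significance": r.epsilon,
                "validity_1": r.validity[1],
                "validity_0": r.validity[0],
                "efficiency_1": np.nan if blank else r.efficiency[1],
                "efficiency_0": np.nan if blank else r.efficiency[0],
                "SE": np.nan if blank or r.se is None else r.se,
                "SP": np.nan if blank or r.sp is None else r.sp,
                "BA": np.nan if blank or r.ba is None else r.ba,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report_csv(
    reports: Sequence[CPMetricsReport], path: str | Path, blank_invalid: bool = True
) -> None:
    report_table(reports, blank_invalid=blank_invalid).to_csv(path, index=False)


def render_report_text(
    reports: Sequence[CPMetricsReport], blank_invalid: bool = True
) -> str:
    df = report_table(reports, blank_invalid=blank_invalid)
    return df.to_string(
        index=False, na_rep="", float_format=lambda v: f"{v:.3f}"
    )
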