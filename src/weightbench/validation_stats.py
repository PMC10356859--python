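"""Observed-vs-expected validation statistics.

Per-person accuracy is the percent relative weight difference
``100 * (O - E) / E``; cohort-level error is the mean squared error
``sum((O - E)^2) / n`` over people at a week.  Weekly distributions are
summarized with Tukey-plot statistics (median, quartiles, 1.5 * IQR
whiskers) plus mean, SD and 5th/95th percentiles.  Quantiles use linear
interpolation between order statistics throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ObservedExpectedPair


def relative_weight_difference(observed, expected):
    """Percent relative weight difference, ``100 * (O - E) / E``.

    Negative values mean the observed weight fell below the model's
    expectation, i.e. the model underestimated the observed loss.
    Vectorized over array inputs; scale-invariant in the common unit.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected weight must be strictly positive")
    out = 100.0 * (observed - expected) / expected
    return float(out) if out.ndim == 0 else out


def pair_relative_difference(pair: ObservedExpectedPair) -> float:
    return relative_weight_difference(pair.observed, pair.expected)


def mean_squared_error(pairs: Sequence[ObservedExpectedPair]) -> float:
    """MSE over people at one week, in squared units of the pairs."""
    if not pairs:
        raise ValueError("no observed/expected pairs")
    units = {p.unit for p in pairs}
    if len(units) > 1:
        raise ValueError(f"mixed units in MSE input: {sorted(units)}")
    diffs = np.array([p.observed - p.expected for p in pairs])
    return float(np.mean(diffs**2))


@dataclass(frozen=True)
class ValidationSummary:
    """Weekly distributional summary of one statistic (Tukey-plot numbers)."""

    week: int
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")
        if self.p5 > self.q1 or self.q3 > self.p95:
            raise ValueError("outer percentiles inside the box")


def summarize_week(week: int, values: Sequence[float]) -> ValidationSummary:
    """Tukey-plot summary of one week's values.

    Whiskers are the most extreme data points within 1.5 * IQR of the box
    (the classical Tukey adjacent values).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty week")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    p5, p95 = np.percentile(x, [5, 95])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return ValidationSummary(
        week=int(week),
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p5=float(p5),
        p95=float(p95),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def weekly_summaries(
    values_by_week: Mapping[int, Sequence[float]] | pd.DataFrame,
    value_column: str = "value",
) -> list[ValidationSummary]:
    """Available-case weekly summaries.

    Accepts either ``{week: values}`` or a long DataFrame with ``week`` and
    ``value_column``.  Weeks that end up empty are omitted with a warning.
    """
    if isinstance(values_by_week, pd.DataFrame):
        grouped = {
            int(w): g[value_column].dropna().to_numpy()
            for w, g in values_by_week.groupby("week")
        }
    else:
        grouped = {int(w): np.asarray(v, dtype=float) for w, v in values_by_week.items()}
    out = []
    for week in sorted(grouped):
        vals = grouped[week]
        if len(vals) == 0:
            warnings.warn(f"week {week}: no available cases; omitted", stacklevel=2)
            continue
        out.append(summarize_week(week, vals))
    return out


def summaries_to_frame(
    summaries: Sequence[ValidationSummary], **labels: str
) -> pd.DataFrame:
    """Tidy table of summaries; ``labels`` adds constant columns (model, statistic)."""
    rows = []
    for s in summaries:
        row = dict(labels)
        row.update(
            week=s.week, n=s.n, mean=s.mean, sd=s.sd, median=s.median,
            q1=s.q1, q3=s.q3, p5=s.p5, p95=s.p95,
            whisker_low=s.whisker_low, whisker_high=s.whisker_high,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AccuracyContrast:
    """Patient-specific model-accuracy contrast at one week."""

    deltas: dict[str, float]  # subject -> rd_A - rd_B
    summary: ValidationSummary
    n_unmatched: int


def model_accuracy_contrast(
    rd_a: Mapping[str, float], rd_b: Mapping[str, float], week: int
) -> AccuracyContrast:
    """Per-subject difference in relative weight difference, model A minus B.

    Subjects present for only one model are excluded and counted in
    ``n_unmatched``.
    """
    common = sorted(set(rd_a) & set(rd_b))
    if not common:
        raise ValueError("no subjects matched across models")
    deltas = {s: rd_a[s] - rd_b[s] for s in common}
    n_unmatched = (len(rd_a) - len(common)) + (len(rd_b) - len(common))
    return AccuracyContrast(
        deltas=deltas,
        summary=summarize_week(week, list(deltas.values())),
        n_unmatched=n_unmatched,
    )


def pairs_to_frame(pairs: Sequence[ObservedExpectedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pairs],
            "week": [p.week for p in pairs],
            "observed": [p.observed for p in pairs],
            "expected": [p.expected for p in pairs],
            "unit": [p.unit for p in pairs],
        }
    )
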