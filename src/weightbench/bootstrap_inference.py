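"""Percentile-bootstrap inference for model comparison.

The comparison rule: 1000 bootstrap resamples of participants (with
replacement), percentile confidence intervals at the 83% level around each
model's MSE, and a significance verdict at p < 0.05 when the two 83%
intervals do not overlap.  Resampling is paired: one subject resample is
scored under both models, preserving within-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class BootstrapResult:
    statistic: str
    point_estimate: float
    ci_low: float
    ci_high: float
    level: float  # percent
    n_resamples: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if self.n_resamples < 1:
            raise ValueError("need at least one resample")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "point_estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level_percent": self.level,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def quantile_targets(level: float) -> tuple[float, float]:
    """Percentile-method quantiles for a ``level``% interval (83 -> 8.5, 91.5)."""
    alpha = 1.0 - level / 100.0
    return (100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0))


def percentile_bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    *,
    level: float = 83.0,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
    label: str = "statistic",
) -> BootstrapResult:
    """Percentile bootstrap CI for ``statistic`` over per-subject values.

    The resampling unit is the participant: each resample redraws ``n``
    subjects with replacement and recomputes the statistic.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    resampled = x[idx]
    if statistic is np.mean:  # fast path for the common case
        boot = resampled.mean(axis=1)
    else:
        boot = np.array([statistic(row) for row in resampled])
    lo_q, hi_q = quantile_targets(level)
    lo, hi = np.percentile(boot, [lo_q, hi_q])
    return BootstrapResult(
        statistic=label,
        point_estimate=float(statistic(x)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_resamples=n_resamples,
        seed=seed,
    )


def intervals_overlap(a: BootstrapResult, b: BootstrapResult) -> bool:
    """Closed-interval overlap; touching endpoints count as overlapping."""
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high


@dataclass(frozen=True)
class ComparisonVerdict:
    model_a: BootstrapResult
    model_b: BootstrapResult
    intervals_overlap: bool
    significant_at_0_05: bool

    def __post_init__(self) -> None:
        if self.significant_at_0_05 != (not self.intervals_overlap):
            raise ValueError("verdict inconsistent with the overlap rule")

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a.to_dict(),
            "model_b": self.model_b.to_dict(),
            "intervals_overlap": self.intervals_overlap,
            "significant_at_0_05": self.significant_at_0_05,
        }


def compare_models_mse(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    *,
    label_a: str = "model_A",
    label_b: str = "model_B",
    level: float = 83.0,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> ComparisonVerdict:
    """Compare two models' MSE at one week with paired percentile bootstrap.

    ``errors_a`` and ``errors_b`` are the per-subject observed-minus-expected
    errors for the same subjects in the same order; one subject resample is
    evaluated under both models.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size != b.size:
        raise ValueError("subject mismatch between the two models")
    if a.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_resamples, a.size))
    boot_a = (a[idx] ** 2).mean(axis=1)
    boot_b = (b[idx] ** 2).mean(axis=1)
    lo_q, hi_q = quantile_targets(level)

    def _result(boot: np.ndarray, point: float, label: str) -> BootstrapResult:
        lo, hi = np.percentile(boot, [lo_q, hi_q])
        return BootstrapResult(
            statistic=f"MSE[{label}]",
            point_estimate=point,
            ci_low=float(lo),
            ci_high=float(hi),
            level=level,
            n_resamples=n_resamples,
            seed=seed,
        )

    res_a = _result(boot_a, float(np.mean(a**2)), label_a)
    res_b = _result(boot_b, float(np.mean(b**2)), label_b)
    overlap = intervals_overlap(res_a, res_b)
    return ComparisonVerdict(
        model_a=res_a,
        model_b=res_b,
        intervals_overlap=overlap,
        significant_at_0_05=not overlap,
    )
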