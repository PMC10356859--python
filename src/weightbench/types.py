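"""Shared domain types and unit conversions.

All quantities are stored in SI-flavoured model units: kilograms, metres,
years, days, kcal/day.  Pounds and inches are accepted only at I/O
boundaries through the conversion constants below.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

KG_PER_LB = 0.45359237
M_PER_IN = 0.0254


def lb_to_kg(pounds: float) -> float:
    return pounds * KG_PER_LB


def kg_to_lb(kg: float) -> float:
    return kg / KG_PER_LB


def in_to_m(inches: float) -> float:
    return inches * M_PER_IN


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class ModelId(str, enum.Enum):
    NIH_BWP = "NIH_BWP"
    PBRC_WLP = "PBRC_WLP"


# Model-eligibility envelope of the validation cohort: adults no taller than
# the models accept, at most 450 lb, at least 55 in tall.
MIN_AGE_YEARS = 18.0
MIN_HEIGHT_M = 1.397  # 55 in
MAX_WEIGHT_KG = 204.5  # 450 lb as conventionally rounded


def eligibility_violation(
    age: Optional[float], height: Optional[float], weight: Optional[float]
) -> Optional[str]:
    """First eligibility violation among the known fields, or None.

    Fields that are ``None`` (unknown) are not tested here; missingness is a
    separate screening reason.
    """
    if age is not None and age < MIN_AGE_YEARS:
        return f"age {age:g} y below {MIN_AGE_YEARS:g}"
    if weight is not None and not (0.0 < weight <= MAX_WEIGHT_KG):
        return f"weight {weight:g} kg outside (0, {MAX_WEIGHT_KG:g}]"
    if height is not None and height < MIN_HEIGHT_M:
        return f"height {height:g} m below {MIN_HEIGHT_M:g}"
    return None


class EligibilityError(ValueError):
    """Profile falls outside the model-eligibility envelope."""


@dataclass(frozen=True)
class SubjectProfile:
    """One person's model inputs: the covariates both models consume."""

    subject_id: str
    age: float  # years
    sex: Sex
    height: float  # metres
    baseline_weight: float  # kg

    def validate(self) -> None:
        """Raise :class:`EligibilityError` if outside the eligibility envelope."""
        reason = eligibility_violation(self.age, self.height, self.baseline_weight)
        if reason is not None:
            raise EligibilityError(f"subject {self.subject_id}: {reason}")

    @property
    def is_eligible(self) -> bool:
        return eligibility_violation(self.age, self.height, self.baseline_weight) is None

    @property
    def bmi(self) -> float:
        return self.baseline_weight / self.height**2


@dataclass(frozen=True)
class IntakeSchedule:
    """Daily energy intake as a step function over program days.

    ``segments`` is an ordered tuple of ``(start_day, kcal_per_day)``; the
    intake on day ``d`` is that of the last segment with ``start_day <= d``.
    """

    segments: tuple[tuple[int, float], ...]
    horizon_days: int

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        starts = [s for s, _ in self.segments]
        if starts[0] != 0:
            raise ValueError("first segment must start at day 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start days must be strictly increasing")
        if any(k <= 0 for _, k in self.segments):
            raise ValueError("intake must be positive")
        if self.horizon_days < 1:
            raise ValueError("horizon must cover at least one day")

    @classmethod
    def standard_program(cls, horizon_days: int = 56) -> "IntakeSchedule":
        """The clinic prescription: 1200 kcal/day in week 0, 900 kcal/day after."""
        return cls(segments=((0, 1200.0), (7, 900.0)), horizon_days=horizon_days)

    @classmethod
    def constant(cls, kcal_per_day: float, horizon_days: int = 56) -> "IntakeSchedule":
        return cls(segments=((0, float(kcal_per_day)),), horizon_days=horizon_days)

    def kcal_on_day(self, day: int) -> float:
        if not (0 <= day < self.horizon_days):
            raise ValueError(f"day {day} outside [0, {self.horizon_days})")
        kcal = self.segments[0][1]
        for start, value in self.segments:
            if start <= day:
                kcal = value
        return kcal

    def daily_intake(self) -> np.ndarray:
        """Vector of intake for each day in ``[0, horizon_days)``."""
        out = np.empty(self.horizon_days)
        for (start, value), nxt in zip(
            self.segments, [s for s, _ in self.segments[1:]] + [self.horizon_days]
        ):
            out[start:nxt] = value
        return out

    def shifted(self, delta_kcal: float, floor: float = 50.0) -> "IntakeSchedule":
        """Schedule with every segment shifted by ``delta_kcal`` (floored)."""
        return IntakeSchedule(
            segments=tuple((s, max(k + delta_kcal, floor)) for s, k in self.segments),
            horizon_days=self.horizon_days,
        )


@dataclass(frozen=True)
class ActivityConfig:
    """Physical activity level: multiplier of resting expenditure (>= 1)."""

    pal: float = 1.4

    def __post_init__(self) -> None:
        if self.pal < 1.0:
            raise ValueError("physical activity level must be >= 1.0")


@dataclass(frozen=True)
class PredictionSeries:
    """Expected weights from one model on the weekly measurement grid.

    ``times`` are program weeks 0..7 where week ``w`` labels the measurement
    after program week ``w`` (model day ``7 * (w + 1)``).
    """

    model_id: ModelId
    subject_id: str
    times: tuple[int, ...]
    expected_weights: tuple[float, ...]  # kg

    def __post_init__(self) -> None:
        if len(self.times) != len(self.expected_weights):
            raise ValueError("times and expected_weights must align")
        if any(w <= 0 for w in self.expected_weights):
            raise ValueError("expected weights must be strictly positive")

    def weight_at(self, week: int) -> float:
        return self.expected_weights[self.times.index(week)]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.times, self.expected_weights))


# Follow-up measurement weeks: the weekly clinic weights after program weeks
# 1..7.  Keys -1 and 0 are the pre-diet intake and initiation weights.
FOLLOWUP_WEEKS: tuple[int, ...] = tuple(range(1, 8))
ALL_WEEKS: tuple[int, ...] = tuple(range(-1, 8))


@dataclass
class ParticipantRecord:
    """Raw enrollment record as captured by the clinic database."""

    subject_id: str
    age: Optional[float]
    sex: Optional[Sex]
    height: Optional[float]  # m
    consented: bool
    weights_by_week: dict[int, float] = field(default_factory=dict)  # kg
    mr_usage_percent: Optional[float] = None
    attendance_fraction: Optional[float] = None

    def followup_weeks(self) -> list[int]:
        return [w for w in FOLLOWUP_WEEKS if w in self.weights_by_week]


@dataclass(frozen=True)
class ObservedExpectedPair:
    """One observed/expected weight pair for a subject at a week."""

    subject_id: str
    week: int
    observed: float
    expected: float
    unit: str = "kg"

    def __post_init__(self) -> None:
        if self.expected <= 0:
            raise ValueError("expected weight must be positive")


def pairs_in_lb(pairs: Sequence[ObservedExpectedPair]) -> list[ObservedExpectedPair]:
    """Convert kg pairs to pounds (pairs already in lb pass through)."""
    out = []
    for p in pairs:
        if p.unit == "lb":
            out.append(p)
        else:
            out.append(
                ObservedExpectedPair(
                    p.subject_id, p.week, kg_to_lb(p.observed), kg_to_lb(p.expected), "lb"
                )
            )
    return out
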