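"""Analysis-cohort construction.

Raw enrollment records pass through the study's screening rules in listed
order — consent, model eligibility, variable completeness, presence of
follow-up weights, diet adherence — with the first failing rule recorded as
the exclusion reason.  Baseline weight is the mean of the intake (week -1)
and program-initiation (week 0) clinic weights.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import (
    ParticipantRecord,
    Sex,
    SubjectProfile,
    eligibility_violation,
)

# Adherence: consuming 80-100% of the prescribed meal replacement and
# attending at least two thirds of the weekly meetings.  The exclusion
# conditions are strict inequalities, so the boundaries are adherent.
USAGE_MIN_PERCENT = 80.0
USAGE_MAX_PERCENT = 100.0
ATTENDANCE_MIN_FRACTION = 2.0 / 3.0


class ExclusionReason(str, enum.Enum):
    NO_CONSENT = "no_consent"
    MODEL_INELIGIBLE = "model_ineligible"
    MISSING_VARIABLES = "missing_variables"
    NO_FOLLOWUP_WEIGHTS = "no_followup_weights"
    NON_ADHERENT = "non_adherent"


class MissingBaselineError(ValueError):
    """Neither the week -1 nor the week 0 weight is available."""


@dataclass(frozen=True)
class BaselineWeight:
    """Computed baseline weight; ``partial`` marks a single-visit fallback."""

    value: float  # kg
    partial: bool


def baseline_weight(w_minus1: Optional[float], w0: Optional[float]) -> BaselineWeight:
    """Mean of the two pre-diet weights; either one alone if the other is absent."""
    if w_minus1 is None and w0 is None:
        raise MissingBaselineError("no pre-diet weight available")
    if w_minus1 is None:
        return BaselineWeight(float(w0), partial=True)
    if w0 is None:
        return BaselineWeight(float(w_minus1), partial=True)
    return BaselineWeight((float(w_minus1) + float(w0)) / 2.0, partial=False)


def is_adherent(record: ParticipantRecord, *, on_missing: str = "non_adherent") -> bool:
    """Whether meal-replacement usage and attendance meet the program rules.

    ``on_missing`` controls records lacking usage or attendance data:
    ``"non_adherent"`` (default) treats them as non-adherent, ``"raise"``
    raises ``ValueError``.
    """
    if record.mr_usage_percent is None or record.attendance_fraction is None:
        if on_missing == "raise":
            raise ValueError(f"subject {record.subject_id}: adherence data missing")
        return False
    return (
        USAGE_MIN_PERCENT <= record.mr_usage_percent <= USAGE_MAX_PERCENT
        and record.attendance_fraction >= ATTENDANCE_MIN_FRACTION
    )


def _baseline_or_none(record: ParticipantRecord) -> Optional[BaselineWeight]:
    try:
        return baseline_weight(
            record.weights_by_week.get(-1), record.weights_by_week.get(0)
        )
    except MissingBaselineError:
        return None


def screen_record(record: ParticipantRecord) -> Optional[ExclusionReason]:
    """First-matching exclusion reason, or None if the record is included.

    Reasons are evaluated in the study's listed order.  Model eligibility is
    tested on whichever required fields are present (the 450 lb cutoff uses
    the computed baseline weight); wholly missing fields fall through to the
    missing-variables reason.
    """
    if not record.consented:
        return ExclusionReason.NO_CONSENT
    bl = _baseline_or_none(record)
    if eligibility_violation(
        record.age, record.height, None if bl is None else bl.value
    ) is not None:
        return ExclusionReason.MODEL_INELIGIBLE
    if record.age is None or record.sex is None or record.height is None or bl is None:
        return ExclusionReason.MISSING_VARIABLES
    if not record.followup_weeks():
        return ExclusionReason.NO_FOLLOWUP_WEIGHTS
    if not is_adherent(record):
        return ExclusionReason.NON_ADHERENT
    return None


@dataclass
class ExclusionTally:
    """Enrollment-flow accounting; mass-conserving by construction."""

    n_screened: int
    counts: dict[ExclusionReason, int] = field(
        default_factory=lambda: {r: 0 for r in ExclusionReason}
    )

    @classmethod
    def from_counts(cls, *, n_screened: Optional[int] = None, **reason_counts: int) -> "ExclusionTally":
        """Build a tally from externally reported counts.

        ``reason_counts`` keys are :class:`ExclusionReason` values.  If
        ``n_screened`` is omitted it must be supplied as
        ``n_included + sum of exclusions`` via the ``n_included`` key.
        """
        n_included = reason_counts.pop("n_included", None)
        counts = {r: 0 for r in ExclusionReason}
        for key, value in reason_counts.items():
            counts[ExclusionReason(key)] = int(value)
        total_excluded = sum(counts.values())
        if n_screened is None:
            if n_included is None:
                raise ValueError("need n_screened or n_included")
            n_screened = int(n_included) + total_excluded
        tally = cls(n_screened=int(n_screened), counts=counts)
        if n_included is not None and tally.n_included != int(n_included):
            raise ValueError("inconsistent counts: n_screened != n_included + exclusions")
        return tally

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def n_included(self) -> int:
        return self.n_screened - self.n_excluded

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_screened

    def exclusion_shares_percent(self) -> dict[str, float]:
        """Each reason's share of all exclusions, in percent."""
        total = self.n_excluded
        return {
            r.value: (100.0 * self.counts[r] / total if total else 0.0)
            for r in ExclusionReason
        }

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "percent_excluded": round(self.percent_excluded, 4),
            "counts": {r.value: self.counts[r] for r in ExclusionReason},
            "shares_percent": {
                k: round(v, 4) for k, v in self.exclusion_shares_percent().items()
            },
        }


@dataclass(frozen=True)
class IncludedParticipant:
    record: ParticipantRecord
    baseline: BaselineWeight
    profile: SubjectProfile


def build_cohort(
    records: Sequence[ParticipantRecord],
) -> tuple[list[IncludedParticipant], ExclusionTally]:
    """Screen every record; return included participants and the flow tally."""
    if not records:
        raise ValueError("no records to screen")
    tally = ExclusionTally(n_screened=len(records))
    included: list[IncludedParticipant] = []
    for record in records:
        reason = screen_record(record)
        if reason is not None:
            tally.counts[reason] += 1
            continue
        bl = baseline_weight(record.weights_by_week.get(-1), record.weights_by_week.get(0))
        profile = SubjectProfile(
            subject_id=record.subject_id,
            age=float(record.age),
            sex=Sex(record.sex),
            height=float(record.height),
            baseline_weight=bl.value,
        )
        included.append(IncludedParticipant(record, bl, profile))
    return included, tally


@dataclass
class CohortComposition:
    """Descriptive composition of an analysis cohort."""

    n: int
    n_female: int
    weights_count: dict[int, int]  # number of follow-up weights -> people

    @classmethod
    def from_cohort(cls, cohort: Iterable[IncludedParticipant]) -> "CohortComposition":
        cohort = list(cohort)
        counts: dict[int, int] = {}
        n_female = 0
        for part in cohort:
            k = len(part.record.followup_weeks())
            counts[k] = counts.get(k, 0) + 1
            if part.profile.sex is Sex.FEMALE:
                n_female += 1
        return cls(n=len(cohort), n_female=n_female, weights_count=counts)

    @classmethod
    def from_counts(cls, *, n_female: int, n_male: int, weights_count: dict[int, int]) -> "CohortComposition":
        return cls(n=n_female + n_male, n_female=n_female, weights_count=dict(weights_count))

    @property
    def percent_female(self) -> float:
        return 100.0 * self.n_female / self.n

    def percent_with_exactly(self, k: int) -> float:
        return 100.0 * self.weights_count.get(k, 0) / self.n

    def percent_with_at_least(self, k: int) -> float:
        n_ge = sum(v for kk, v in self.weights_count.items() if kk >= k)
        return 100.0 * n_ge / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_female": self.n_female,
            "percent_female": round(self.percent_female, 4),
            "weights_count": {int(k): v for k, v in sorted(self.weights_count.items())},
        }
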