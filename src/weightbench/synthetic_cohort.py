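"""Synthetic enrollment cohort with the statistical structure the analysis assumes.

The generator emulates a real weight-management clinic intake stream:

* demographics drawn from sex-conditional truncated normals whose defaults
  match the validation cohort's published means and SDs (73.5% female;
  female weight 247.2 +/- 47.0 lb, male 299.5 +/- 47.0 lb, etc.);
* an enrollment flow whose default stage probabilities reproduce, in
  expectation, the published screening losses (26.8% excluded overall,
  split 30.2 / 4.8 / 0.2 / 0.7 / 64.2% across consent refusal, model
  ineligibility, missing variables, no follow-up weights, non-adherence);
* observed weekly weights generated from a ground-truth energy-balance
  model (the dynamic NIH-BWP model by default) driven by the prescribed
  diet plus a person-specific intake deviation, with additive scale noise
  and independently missing weeks.

With the discrepancy configuration zeroed, observed weights coincide with
the generating model's predictions exactly, which makes downstream
relative differences identically zero — the end-to-end null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from . import constants as c
from .types import (
    MAX_WEIGHT_KG,
    MIN_AGE_YEARS,
    MIN_HEIGHT_M,
    ActivityConfig,
    IntakeSchedule,
    KG_PER_LB,
    M_PER_IN,
    ModelId,
    ParticipantRecord,
    Sex,
    SubjectProfile,
)
from .weight_models import predict, simulate_hall_batch, simulate_thomas_batch


@dataclass(frozen=True)
class SexStats:
    """Marginal anthropometric distribution for one sex (SI units)."""

    age_mean: float
    age_sd: float
    height_mean: float  # m
    height_sd: float
    weight_mean: float  # kg
    weight_sd: float


# Published cohort demographics (pounds/inches rows converted to SI).
FEMALE_DEFAULTS = SexStats(
    age_mean=46.1,
    age_sd=11.1,
    height_mean=64.4 * M_PER_IN,
    height_sd=2.5 * M_PER_IN,
    weight_mean=247.2 * KG_PER_LB,
    weight_sd=47.0 * KG_PER_LB,
)
MALE_DEFAULTS = SexStats(
    age_mean=48.9,
    age_sd=11.1,
    height_mean=69.7 * M_PER_IN,
    height_sd=2.7 * M_PER_IN,
    weight_mean=299.5 * KG_PER_LB,
    weight_sd=47.0 * KG_PER_LB,
)


@dataclass(frozen=True)
class PopulationConfig:
    n: int = 1000
    p_female: float = 0.735
    female: SexStats = FEMALE_DEFAULTS
    male: SexStats = MALE_DEFAULTS
    age_bounds: tuple[float, float] = (MIN_AGE_YEARS, 90.0)
    height_bounds: tuple[float, float] = (MIN_HEIGHT_M, 2.20)
    weight_bounds: tuple[float, float] = (40.0, MAX_WEIGHT_KG)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must be a probability")
        for lo, hi in (self.age_bounds, self.height_bounds, self.weight_bounds):
            if lo >= hi:
                raise ValueError("infeasible truncation bounds")


@dataclass(frozen=True)
class FlowConfig:
    """Stage-conditional exclusion probabilities of the enrollment flow.

    Defaults are the stage-wise hazards implied by the published screening
    counts (409/5057 consent refusals among screened, 66/4648 ineligible
    among consenters, and so on), so expected flow fractions match the
    published enrollment figure.
    """

    p_no_consent: float = 409 / 5057
    p_model_ineligible: float = 66 / 4648
    p_missing_variables: float = 3 / 4582
    p_no_followup: float = 9 / 4579
    p_non_adherent: float = 869 / 4570

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")

    @classmethod
    def none(cls) -> "FlowConfig":
        """No screening losses: every generated record passes the filter."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DiscrepancyConfig:
    """Mechanisms separating observed weights from model expectations.

    ``intake_bias_mean/sd`` is a person-level deviation (kcal/day) from the
    prescribed intake, constant over the program — unreported eating or
    incomplete supplement ingestion.  ``measurement_noise_sd`` is additive
    scale noise per clinic weighing.  Each follow-up week is missing
    independently with ``missing_week_probability``.
    """

    intake_bias_mean: float = -250.0  # kcal/day
    intake_bias_sd: float = 450.0
    measurement_noise_sd: float = 0.5  # kg
    missing_week_probability: float = 0.05

    def __post_init__(self) -> None:
        if self.intake_bias_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.missing_week_probability <= 1.0:
            raise ValueError("missing_week_probability must be a probability")

    @classmethod
    def null(cls) -> "DiscrepancyConfig":
        """Zero discrepancy: observed weights equal the generating model's."""
        return cls(0.0, 0.0, 0.0, 0.0)


def _truncnorm(rng, mean, sd, bounds, size) -> np.ndarray:
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_population(
    config: PopulationConfig, rng: Optional[np.random.Generator] = None
) -> list[SubjectProfile]:
    """Draw ``config.n`` eligible subject profiles, reproducibly under the seed."""
    if config.n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    female = rng.random(config.n) < config.p_female
    age = np.empty(config.n)
    height = np.empty(config.n)
    weight = np.empty(config.n)
    for is_f, st in ((True, config.female), (False, config.male)):
        mask = female == is_f
        m = int(mask.sum())
        if m == 0:
            continue
        age[mask] = _truncnorm(rng, st.age_mean, st.age_sd, config.age_bounds, m)
        height[mask] = _truncnorm(rng, st.height_mean, st.height_sd, config.height_bounds, m)
        weight[mask] = _truncnorm(rng, st.weight_mean, st.weight_sd, config.weight_bounds, m)
    return [
        SubjectProfile(
            subject_id=f"S{i:05d}",
            age=float(age[i]),
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            height=float(height[i]),
            baseline_weight=float(weight[i]),
        )
        for i in range(config.n)
    ]


def simulate_observed_trajectory(
    profile: SubjectProfile,
    schedule: IntakeSchedule,
    disc: DiscrepancyConfig,
    rng: np.random.Generator | int,
    *,
    pal: float = c.PAL_DEFAULT,
    truth_model: ModelId = ModelId.NIH_BWP,
) -> dict[int, float]:
    """Observed weekly clinic weights for one person.

    Ground truth follows ``truth_model`` under the prescribed schedule
    shifted by the person's intake bias; weeks -1 and 0 scatter around the
    true baseline with measurement noise only; each follow-up week is
    dropped independently with the configured probability.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    bias = rng.normal(disc.intake_bias_mean, disc.intake_bias_sd) if (
        disc.intake_bias_mean or disc.intake_bias_sd
    ) else 0.0
    actual = schedule.shifted(bias) if bias else schedule
    series = predict(
        truth_model, profile, actual, ActivityConfig(pal), enforce_eligibility=False
    )
    noise = rng.normal(0.0, disc.measurement_noise_sd, size=9) if disc.measurement_noise_sd else np.zeros(9)
    out = {
        -1: profile.baseline_weight + noise[0],
        0: profile.baseline_weight + noise[1],
    }
    drop = rng.random(7) < disc.missing_week_probability
    for w in range(1, 8):
        if not drop[w - 1]:
            out[w] = series.weight_at(w) + noise[w + 1]
    return out


def generate_enrollment(
    pop_config: PopulationConfig,
    flow_config: FlowConfig | None = None,
    disc_config: DiscrepancyConfig | None = None,
    *,
    schedule: IntakeSchedule | None = None,
    pal: float = c.PAL_DEFAULT,
    truth_model: ModelId = ModelId.NIH_BWP,
    seed: Optional[int] = None,
) -> list[ParticipantRecord]:
    """Generate raw enrollment records for the full screening pipeline.

    Consent refusal, injected model-ineligibility, missing variables,
    absent follow-up and non-adherence are assigned independently with the
    stage probabilities in ``flow_config``; observed trajectories follow
    :func:`simulate_observed_trajectory` semantics, computed in one
    vectorized pass over the cohort.
    """
    flow = flow_config if flow_config is not None else FlowConfig()
    disc = disc_config if disc_config is not None else DiscrepancyConfig()
    schedule = schedule if schedule is not None else IntakeSchedule.standard_program()
    rng = np.random.default_rng(pop_config.seed if seed is None else seed)

    profiles = generate_population(pop_config, rng)
    n = len(profiles)

    no_consent = rng.random(n) < flow.p_no_consent
    inelig = rng.random(n) < flow.p_model_ineligible
    inelig_kind = rng.integers(0, 3, n)
    inelig_age = rng.uniform(16.0, 17.9, n)
    inelig_weight = rng.uniform(MAX_WEIGHT_KG + 1.0, MAX_WEIGHT_KG + 30.0, n)
    inelig_height = rng.uniform(1.30, MIN_HEIGHT_M - 0.005, n)
    missing = rng.random(n) < flow.p_missing_variables
    missing_kind = rng.integers(0, 2, n)
    no_follow = rng.random(n) < flow.p_no_followup
    nonadh = rng.random(n) < flow.p_non_adherent
    nonadh_kind = rng.integers(0, 3, n)
    usage_low = rng.uniform(40.0, 79.5, n)
    usage_high = rng.uniform(100.5, 120.0, n)
    attend_low = rng.uniform(0.20, 0.66, n)
    usage_ok = rng.uniform(82.0, 100.0, n)
    attend_ok = rng.uniform(0.70, 1.00, n)
    bias = rng.normal(disc.intake_bias_mean, disc.intake_bias_sd, n)
    noise = (
        rng.normal(0.0, disc.measurement_noise_sd, (n, 9))
        if disc.measurement_noise_sd
        else np.zeros((n, 9))
    )
    drop_week = rng.random((n, 7)) < disc.missing_week_probability

    # Demographics possibly perturbed out of the eligibility envelope.
    age = np.array([p.age for p in profiles])
    is_male = np.array([p.sex is Sex.MALE for p in profiles])
    height = np.array([p.height for p in profiles])
    weight0 = np.array([p.baseline_weight for p in profiles])
    age = np.where(inelig & (inelig_kind == 0), inelig_age, age)
    weight0 = np.where(inelig & (inelig_kind == 1), inelig_weight, weight0)
    height = np.where(inelig & (inelig_kind == 2), inelig_height, height)

    base_intake = schedule.daily_intake()
    intake = np.clip(base_intake[None, :] + bias[:, None], 50.0, None)
    if truth_model is ModelId.NIH_BWP:
        daily = simulate_hall_batch(age, is_male, height, weight0, intake, pal=pal).weights
    else:
        daily = simulate_thomas_batch(age, is_male, height, weight0, intake)

    records: list[ParticipantRecord] = []
    for i, profile in enumerate(profiles):
        weights: dict[int, float] = {
            -1: float(weight0[i] + noise[i, 0]),
            0: float(weight0[i] + noise[i, 1]),
        }
        if not no_follow[i]:
            for w in range(1, 8):
                if not drop_week[i, w - 1]:
                    weights[w] = float(daily[i, 7 * (w + 1)] + noise[i, w + 1])
        rec_height: Optional[float] = float(height[i])
        if missing[i]:
            if missing_kind[i] == 0:
                rec_height = None
            else:
                weights.pop(-1, None)
                weights.pop(0, None)
        if nonadh[i]:
            usage = usage_low[i] if nonadh_kind[i] == 0 else (
                usage_high[i] if nonadh_kind[i] == 1 else usage_ok[i]
            )
            attendance = attend_low[i] if nonadh_kind[i] == 2 else attend_ok[i]
        else:
            usage, attendance = usage_ok[i], attend_ok[i]
        records.append(
            ParticipantRecord(
                subject_id=profile.subject_id,
                age=float(age[i]),
                sex=profile.sex,
                height=rec_height,
                consented=not bool(no_consent[i]),
                weights_by_week=weights,
                mr_usage_percent=float(usage),
                attendance_fraction=float(attendance),
            )
        )
    return records
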