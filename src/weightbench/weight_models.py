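"""Individualized body-weight prediction models.

Two published models are implemented behind one interface mapping
``(profile, intake schedule, activity)`` to expected weekly weights:

``NIH_BWP``
    The dynamic energy-balance model of Hall et al. behind the NIH Body
    Weight Planner.  Four state variables — fat mass F, lean mass L,
    glycogen G and extracellular fluid ECF — evolve under the energy
    balance

        rho_F dF/dt + rho_L dL/dt + rho_G dG/dt = I - E,

    with the imbalance partitioned between lean and fat tissue along the
    Forbes curve, p = C / (C + F).  Expenditure E comprises a constant
    term calibrated to baseline balance, tissue-specific resting costs
    (gamma_F F + gamma_L L), physical activity proportional to body
    weight, the thermic effect of food (beta_TEF * I), adaptive
    thermogenesis (first-order response to the intake change), and the
    biochemical cost of tissue turnover (eta_F dF/dt + eta_L dL/dt).
    Glycogen relaxes toward a level set by carbohydrate intake and drags
    2.7 kg of water per kg; extracellular fluid responds to sodium and
    carbohydrate intake changes.

``PBRC_WLP``
    The one-dimensional model of Thomas et al. behind the Pennington
    Weight Loss Predictor.  A single state, body weight W, obeys

        rho_W dW/dt = I - E(W, I),

    where expenditure is affine in weight: resting metabolic rate
    (Mifflin-St Jeor, a linear function of weight with a sex-, age- and
    height-dependent intercept) plus dietary-induced thermogenesis
    (0.075 * I), inflated by the spontaneous-activity share (32.6%) of
    total expenditure.

Both models are integrated with a fixed-step classical Runge-Kutta scheme
(default one step per day); intake is piecewise constant on days, so steps
never straddle an intake discontinuity.  Every parameter is recorded with
its unit and source in ``data/model_constants.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import constants as c
from .types import (
    ActivityConfig,
    EligibilityError,
    IntakeSchedule,
    ModelId,
    PredictionSeries,
    Sex,
    SubjectProfile,
    kg_to_lb,
)

WEEKLY_TIMES: tuple[int, ...] = tuple(range(8))
MIN_HORIZON_DAYS = 7 * (WEEKLY_TIMES[-1] + 1)  # 56: eight weekly measurements


class IntegrationError(RuntimeError):
    """The fixed-step integration produced a non-physical state."""


@dataclass(frozen=True)
class BodyCompositionState:
    """Hall-model body composition; all components in kg.

    Body weight closes exactly:
    ``fat + lean + glycogen + glycogen-bound water + ECF = weight``.
    """

    fat_mass: float
    lean_mass: float
    glycogen: float
    extracellular_fluid: float

    def __post_init__(self) -> None:
        for name in ("fat_mass", "lean_mass", "glycogen", "extracellular_fluid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def glycogen_bound_water(self) -> float:
        return c.H_G * self.glycogen

    @property
    def weight(self) -> float:
        return (
            self.fat_mass
            + self.lean_mass
            + self.glycogen
            + self.glycogen_bound_water
            + self.extracellular_fluid
        )


# ---------------------------------------------------------------------------
# Baseline physiology
# ---------------------------------------------------------------------------


def mifflin_st_jeor_rmr(weight_kg, height_m, age_years, is_male) -> np.ndarray:
    """Resting metabolic rate (kcal/day), vectorized over numpy inputs."""
    offset = np.where(is_male, c.MSJ_MALE, c.MSJ_FEMALE)
    return (
        c.MSJ_WEIGHT * np.asarray(weight_kg)
        + c.MSJ_HEIGHT * np.asarray(height_m) * 100.0
        - c.MSJ_AGE * np.asarray(age_years)
        + offset
    )


def body_fat_percent(age_years, bmi, is_male) -> np.ndarray:
    """Initial body-fat percentage from the sex-specific BMI regression.

    Clipped to [5, 60]% so extreme BMIs still yield a physiological state.
    """
    lnbmi = np.log(np.asarray(bmi, dtype=float))
    female = c.BF_FEMALE_AGE * np.asarray(age_years) + c.BF_FEMALE_LNBMI * lnbmi + c.BF_FEMALE_INTERCEPT
    male = c.BF_MALE_AGE * np.asarray(age_years) + c.BF_MALE_LNBMI * lnbmi + c.BF_MALE_INTERCEPT
    return np.clip(np.where(is_male, male, female), 5.0, 60.0)


def maintenance_intake_nih(profile: SubjectProfile, activity: ActivityConfig) -> float:
    """Baseline weight-maintaining intake for the dynamic model: PAL * RMR."""
    rmr = float(
        mifflin_st_jeor_rmr(profile.baseline_weight, profile.height, profile.age, profile.sex is Sex.MALE)
    )
    return activity.pal * rmr


def maintenance_intake_pbrc(profile: SubjectProfile) -> float:
    """Weight-maintaining intake under the one-dimensional model.

    Solves I = E(W0, I) with E = (RMR + dit * I) / (1 - spa).
    """
    rmr = float(
        mifflin_st_jeor_rmr(profile.baseline_weight, profile.height, profile.age, profile.sex is Sex.MALE)
    )
    return rmr / (1.0 - c.SPA_FRACTION - c.DIT_FRACTION)


def initial_body_composition(
    profile: SubjectProfile, *, enforce_eligibility: bool = True
) -> BodyCompositionState:
    """Baseline body composition for the dynamic model.

    Fat mass comes from the sex-specific BMI/age regression; glycogen starts
    at its reference store; extracellular fluid is a fixed fraction of
    fat-free mass; lean mass absorbs the remainder so the components sum to
    the baseline weight exactly.
    """
    if enforce_eligibility:
        profile.validate()
    bf = float(body_fat_percent(profile.age, profile.bmi, profile.sex is Sex.MALE))
    fat = bf / 100.0 * profile.baseline_weight
    ffm = profile.baseline_weight - fat
    ecf = c.ECF_FRACTION_FFM * ffm
    glyc = c.G_INIT
    lean = profile.baseline_weight - fat - (1.0 + c.H_G) * glyc - ecf
    if lean <= 0:
        raise EligibilityError(
            f"subject {profile.subject_id}: non-physical composition (lean {lean:.2f} kg)"
        )
    return BodyCompositionState(fat, lean, glyc, ecf)


# ---------------------------------------------------------------------------
# Vectorized integrators (shared by single-subject prediction and the
# synthetic-cohort generator)
# ---------------------------------------------------------------------------


def _rk4_day(deriv: Callable, state: tuple, intake: np.ndarray, substeps: int) -> tuple:
    """Advance one day with ``substeps`` classical Runge-Kutta steps.

    ``intake`` is constant over the day, so no step straddles an intake
    discontinuity.
    """
    h = 1.0 / substeps
    for _ in range(substeps):
        k1 = deriv(state, intake)
        k2 = deriv(tuple(s + 0.5 * h * d for s, d in zip(state, k1)), intake)
        k3 = deriv(tuple(s + 0.5 * h * d for s, d in zip(state, k2)), intake)
        k4 = deriv(tuple(s + h * d for s, d in zip(state, k3)), intake)
        state = tuple(
            s + (h / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            for s, d1, d2, d3, d4 in zip(state, k1, k2, k3, k4)
        )
    return state


@dataclass
class HallTrajectory:
    """Daily output of the dynamic model for a batch of subjects."""

    weights: np.ndarray  # (n, n_days + 1), weight at the end of each day
    fat: np.ndarray
    lean: np.ndarray
    glycogen: np.ndarray
    ecf: np.ndarray
    energy_imbalance: np.ndarray  # (n,), cumulative integral of I - E (kcal)


def simulate_hall_batch(
    age: np.ndarray,
    is_male: np.ndarray,
    height: np.ndarray,
    weight0: np.ndarray,
    intake: np.ndarray,
    pal: float = c.PAL_DEFAULT,
    carb_fraction: float = c.CARB_FRACTION_DEFAULT,
    dt: float = 1.0,
) -> HallTrajectory:
    """Integrate the Hall model for ``n`` subjects over ``intake.shape[1]`` days.

    ``intake`` has shape ``(n, n_days)`` in kcal/day.  ``dt`` must divide one
    day evenly.  Raises :class:`IntegrationError` on non-physical states.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    is_male = np.atleast_1d(np.asarray(is_male, dtype=bool))
    height = np.atleast_1d(np.asarray(height, dtype=float))
    weight0 = np.atleast_1d(np.asarray(weight0, dtype=float))
    intake = np.atleast_2d(np.asarray(intake, dtype=float))
    n, n_days = intake.shape
    substeps = int(round(1.0 / dt))
    if not np.isclose(substeps * dt, 1.0):
        raise ValueError("dt must divide one day evenly")

    bmi = weight0 / height**2
    bf = body_fat_percent(age, bmi, is_male)
    fat0 = bf / 100.0 * weight0
    ffm = weight0 - fat0
    ecf0 = c.ECF_FRACTION_FFM * ffm
    g0 = np.full(n, c.G_INIT)
    lean0 = weight0 - fat0 - (1.0 + c.H_G) * g0 - ecf0
    if np.any(lean0 <= 0):
        raise IntegrationError("non-physical baseline composition (lean mass <= 0)")

    rmr0 = mifflin_st_jeor_rmr(weight0, height, age, is_male)
    intake_b = pal * rmr0  # baseline maintenance intake
    ci_b = carb_fraction * intake_b
    k_g = ci_b / c.G_INIT**2
    delta = ((1.0 - c.BETA_TEF) * pal - 1.0) * rmr0 / weight0  # activity, kcal/kg/d
    k_const = (1.0 - c.BETA_TEF) * intake_b - c.GAMMA_F * fat0 - c.GAMMA_L * lean0 - delta * weight0

    def deriv(state: tuple, kcal: np.ndarray) -> tuple:
        f, lean, g, ecf, at, _cum = state
        ci = carb_fraction * kcal
        d_g = (ci - k_g * g**2) / c.RHO_G
        d_na = c.NA_BASELINE * (kcal / intake_b - 1.0)
        d_ecf = (d_na - c.XI_NA * (ecf - ecf0) - c.XI_CI * (1.0 - ci / ci_b)) / c.NA_CONC
        d_at = (c.BETA_AT * (kcal - intake_b) - at) / c.TAU_AT
        bw = f + lean + (1.0 + c.H_G) * g + ecf
        e0 = k_const + c.GAMMA_F * f + c.GAMMA_L * lean + delta * bw + c.BETA_TEF * kcal + at
        p = c.FORBES_C / (c.FORBES_C + f)
        denom = 1.0 + c.ETA_F * (1.0 - p) / c.RHO_F + c.ETA_L * p / c.RHO_L
        imbalance = (kcal - e0 - c.RHO_G * d_g) / denom
        d_f = (1.0 - p) * imbalance / c.RHO_F
        d_l = p * imbalance / c.RHO_L
        expenditure = e0 + c.ETA_F * d_f + c.ETA_L * d_l
        return (d_f, d_l, d_g, d_ecf, d_at, kcal - expenditure)

    state = (fat0, lean0, g0, ecf0, np.zeros(n), np.zeros(n))
    weights = np.empty((n, n_days + 1))
    fat_t = np.empty((n, n_days + 1))
    lean_t = np.empty((n, n_days + 1))
    g_t = np.empty((n, n_days + 1))
    ecf_t = np.empty((n, n_days + 1))

    def record(day: int, st: tuple) -> None:
        f, lean, g, ecf, _, _ = st
        weights[:, day] = f + lean + (1.0 + c.H_G) * g + ecf
        fat_t[:, day], lean_t[:, day], g_t[:, day], ecf_t[:, day] = f, lean, g, ecf

    record(0, state)
    for day in range(n_days):
        state = _rk4_day(deriv, state, intake[:, day], substeps)
        f, lean, g, ecf, _, _ = state
        bad = ~np.isfinite(f) | (f < 0) | (lean < 0) | (f + lean + (1 + c.H_G) * g + ecf <= 0)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise IntegrationError(
                f"unstable integration at day {day + 1} with step {dt:g} d: "
                f"state F={f[i]:.3f}, L={lean[i]:.3f}, G={g[i]:.4f}, ECF={ecf[i]:.3f} kg"
            )
        record(day + 1, state)

    return HallTrajectory(weights, fat_t, lean_t, g_t, ecf_t, state[5].copy())


def simulate_thomas_batch(
    age: np.ndarray,
    is_male: np.ndarray,
    height: np.ndarray,
    weight0: np.ndarray,
    intake: np.ndarray,
    dt: float = 1.0,
) -> np.ndarray:
    """Integrate the one-dimensional model; returns daily weights (n, n_days+1)."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    is_male = np.atleast_1d(np.asarray(is_male, dtype=bool))
    height = np.atleast_1d(np.asarray(height, dtype=float))
    weight0 = np.atleast_1d(np.asarray(weight0, dtype=float))
    intake = np.atleast_2d(np.asarray(intake, dtype=float))
    n, n_days = intake.shape
    substeps = int(round(1.0 / dt))
    if not np.isclose(substeps * dt, 1.0):
        raise ValueError("dt must divide one day evenly")

    # RMR(W) = a W + b: affine in weight with sex/age/height intercept.
    a_w = c.MSJ_WEIGHT
    b0 = (
        c.MSJ_HEIGHT * height * 100.0
        - c.MSJ_AGE * age
        + np.where(is_male, c.MSJ_MALE, c.MSJ_FEMALE)
    )

    def deriv(state: tuple, kcal: np.ndarray) -> tuple:
        (w,) = state
        expenditure = (a_w * w + b0 + c.DIT_FRACTION * kcal) / (1.0 - c.SPA_FRACTION)
        return ((kcal - expenditure) / c.RHO_BW,)

    state = (weight0.copy(),)
    weights = np.empty((n, n_days + 1))
    weights[:, 0] = weight0
    for day in range(n_days):
        state = _rk4_day(deriv, state, intake[:, day], substeps)
        (w,) = state
        if np.any(~np.isfinite(w) | (w <= 0)):
            i = int(np.argmax(~np.isfinite(w) | (w <= 0)))
            raise IntegrationError(
                f"unstable integration at day {day + 1} with step {dt:g} d: W={w[i]:.3f} kg"
            )
        weights[:, day + 1] = w
    return weights


# ---------------------------------------------------------------------------
# Public per-subject prediction API
# ---------------------------------------------------------------------------


def _weekly_from_daily(daily: np.ndarray) -> tuple[float, ...]:
    """Weights at days 7, 14, ..., 56 -> measurement weeks 0..7."""
    return tuple(float(daily[7 * (w + 1)]) for w in WEEKLY_TIMES)


def _check_inputs(profile: SubjectProfile, schedule: IntakeSchedule, enforce: bool) -> None:
    if enforce:
        profile.validate()
    if schedule.horizon_days < MIN_HORIZON_DAYS:
        raise ValueError(
            f"schedule must cover >= {MIN_HORIZON_DAYS} days for 8 weekly measurements"
        )


def predict_nih_bwp(
    profile: SubjectProfile,
    schedule: IntakeSchedule,
    activity: ActivityConfig | None = None,
    *,
    carb_fraction: float = c.CARB_FRACTION_DEFAULT,
    dt: float = 1.0,
    enforce_eligibility: bool = True,
) -> PredictionSeries:
    """Expected weekly weights under the dynamic energy-balance model."""
    activity = activity or ActivityConfig()
    _check_inputs(profile, schedule, enforce_eligibility)
    traj = simulate_hall_batch(
        np.array([profile.age]),
        np.array([profile.sex is Sex.MALE]),
        np.array([profile.height]),
        np.array([profile.baseline_weight]),
        schedule.daily_intake()[None, :],
        pal=activity.pal,
        carb_fraction=carb_fraction,
        dt=dt,
    )
    return PredictionSeries(
        ModelId.NIH_BWP, profile.subject_id, WEEKLY_TIMES, _weekly_from_daily(traj.weights[0])
    )


def predict_pbrc_wlp(
    profile: SubjectProfile,
    schedule: IntakeSchedule,
    *,
    dt: float = 1.0,
    enforce_eligibility: bool = True,
) -> PredictionSeries:
    """Expected weekly weights under the one-dimensional model."""
    _check_inputs(profile, schedule, enforce_eligibility)
    daily = simulate_thomas_batch(
        np.array([profile.age]),
        np.array([profile.sex is Sex.MALE]),
        np.array([profile.height]),
        np.array([profile.baseline_weight]),
        schedule.daily_intake()[None, :],
        dt=dt,
    )
    return PredictionSeries(
        ModelId.PBRC_WLP, profile.subject_id, WEEKLY_TIMES, _weekly_from_daily(daily[0])
    )


def predict(
    model_id: ModelId | str,
    profile: SubjectProfile,
    schedule: IntakeSchedule,
    activity: ActivityConfig | None = None,
    **kwargs,
) -> PredictionSeries:
    """Dispatch to one of the two models; both receive identical covariates."""
    model_id = ModelId(model_id)
    if model_id is ModelId.NIH_BWP:
        return predict_nih_bwp(profile, schedule, activity, **kwargs)
    if model_id is ModelId.PBRC_WLP:
        return predict_pbrc_wlp(profile, schedule, **kwargs)
    raise ValueError(f"unknown model {model_id!r}")  # pragma: no cover


def predict_cohort(
    model_id: ModelId | str,
    profiles: Sequence[SubjectProfile],
    schedule: IntakeSchedule,
    activity: ActivityConfig | None = None,
    *,
    dt: float = 1.0,
) -> list[PredictionSeries]:
    """Batch prediction for many subjects on a shared schedule.

    Numerically identical to calling :func:`predict` per subject (the same
    element-wise integrator runs underneath), but one vectorized pass.
    """
    model_id = ModelId(model_id)
    activity = activity or ActivityConfig()
    if not profiles:
        return []
    if schedule.horizon_days < MIN_HORIZON_DAYS:
        raise ValueError(f"schedule must cover >= {MIN_HORIZON_DAYS} days")
    age = np.array([p.age for p in profiles])
    male = np.array([p.sex is Sex.MALE for p in profiles])
    height = np.array([p.height for p in profiles])
    w0 = np.array([p.baseline_weight for p in profiles])
    intake = np.tile(schedule.daily_intake(), (len(profiles), 1))
    if model_id is ModelId.NIH_BWP:
        daily = simulate_hall_batch(age, male, height, w0, intake, pal=activity.pal, dt=dt).weights
    else:
        daily = simulate_thomas_batch(age, male, height, w0, intake, dt=dt)
    return [
        PredictionSeries(model_id, p.subject_id, WEEKLY_TIMES, _weekly_from_daily(daily[i]))
        for i, p in enumerate(profiles)
    ]


def predictions_to_frame(series: Sequence[PredictionSeries]):
    """Tidy table: subject_id, model_id, week, expected_weight_kg / _lb."""
    import pandas as pd

    rows = [
        {
            "subject_id": s.subject_id,
            "model_id": s.model_id.value,
            "week": w,
            "expected_weight_kg": round(e, 6),
            "expected_weight_lb": round(kg_to_lb(e), 6),
        }
        for s in series
        for w, e in zip(s.times, s.expected_weights)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "model_id", "week", "expected_weight_kg", "expected_weight_lb"])
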