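"""Unit and property tests for the two weight-prediction models."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from weightbench import (
    ActivityConfig,
    IntakeSchedule,
    ModelId,
    Sex,
    SubjectProfile,
    initial_body_composition,
    predict,
    predict_nih_bwp,
    predict_pbrc_wlp,
)
from weightbench import constants as c
from weightbench.types import EligibilityError
from weightbench.weight_models import (
    IntegrationError,
    maintenance_intake_nih,
    maintenance_intake_pbrc,
    predict_cohort,
    simulate_hall_batch,
    simulate_thomas_batch,
)

# Week-7 weights for the reference female (46 y, 1.64 m, 112.1 kg, PAL 1.4)
# on the 1200/900 kcal program, frozen from a 0.1-day-step integration.
NIH_REF_WEEK7_KG = 99.277315
PBRC_REF_WEEK7_KG = 99.855269

eligible_profiles = st.builds(
    SubjectProfile,
    subject_id=st.just("h"),
    age=st.floats(18.0, 80.0),
    sex=st.sampled_from([Sex.FEMALE, Sex.MALE]),
    height=st.floats(1.45, 2.0),
    baseline_weight=st.floats(60.0, 200.0),
)


class TestInitialComposition:
    def test_mass_closure(self, ref_female):
        state = initial_body_composition(ref_female)
        assert state.weight == pytest.approx(ref_female.baseline_weight, abs=1e-9)

    def test_component_sum_named_parts(self, ref_female):
        state = initial_body_composition(ref_female)
        total = (
            state.fat_mass
            + state.lean_mass
            + state.glycogen
            + state.glycogen_bound_water
            + state.extracellular_fluid
        )
        assert total == pytest.approx(112.1, abs=1e-9)

    def test_female_fatter_than_male_at_same_covariates(self):
        f = SubjectProfile("f", 45.0, Sex.FEMALE, 1.70, 110.0)
        m = SubjectProfile("m", 45.0, Sex.MALE, 1.70, 110.0)
        assert initial_body_composition(f).fat_mass > initial_body_composition(m).fat_mass

    def test_fat_mass_matches_regression_arithmetic(self, ref_male):
        # Independent recomputation of the sex-specific body-fat regression.
        bmi = 136.0 / 1.77**2
        bf = 0.14 * 48.0 + 37.31 * math.log(bmi) - 103.94
        assert initial_body_composition(ref_male).fat_mass == pytest.approx(
            bf / 100.0 * 136.0, rel=1e-12
        )
        assert initial_body_composition(ref_male).fat_mass == pytest.approx(
            59.111938, abs=1e-5
        )

    @pytest.mark.parametrize(
        "age,height,weight",
        [(17.0, 1.70, 90.0), (40.0, 1.30, 90.0), (40.0, 1.70, 210.0)],
    )
    def test_rejects_outside_eligibility_envelope(self, age, height, weight):
        profile = SubjectProfile("x", age, Sex.FEMALE, height, weight)
        with pytest.raises(EligibilityError):
            initial_body_composition(profile)

    @given(eligible_profiles)
    def test_mass_closure_property(self, profile):
        state = initial_body_composition(profile)
        assert state.weight == pytest.approx(profile.baseline_weight, abs=1e-8)
        assert min(state.fat_mass, state.lean_mass, state.extracellular_fluid) > 0


class TestSteadyStateAndMonotonicity:
    def test_nih_maintenance_steady_state(self, ref_female, sedentary):
        kcal = maintenance_intake_nih(ref_female, sedentary)
        series = predict_nih_bwp(ref_female, IntakeSchedule.constant(kcal), sedentary)
        assert max(abs(w - 112.1) for w in series.expected_weights) < 0.1

    def test_pbrc_maintenance_steady_state(self, ref_female):
        kcal = maintenance_intake_pbrc(ref_female)
        series = predict_pbrc_wlp(ref_female, IntakeSchedule.constant(kcal))
        assert max(abs(w - 112.1) for w in series.expected_weights) < 0.1

    @pytest.mark.parametrize("model", [ModelId.NIH_BWP, ModelId.PBRC_WLP])
    def test_sustained_deficit_strictly_monotone(self, model, ref_female, sedentary):
        series = predict(model, ref_female, IntakeSchedule.constant(900.0), sedentary)
        w = series.expected_weights
        assert all(b < a for a, b in zip(w, w[1:]))
        assert w[0] < ref_female.baseline_weight

    @pytest.mark.parametrize("model", [ModelId.NIH_BWP, ModelId.PBRC_WLP])
    def test_program_schedule_monotone(self, model, ref_female, program_schedule, sedentary):
        w = predict(model, ref_female, program_schedule, sedentary).expected_weights
        assert all(b < a for a, b in zip(w, w[1:]))

    def test_deeper_deficit_means_more_loss(self, ref_female, sedentary):
        w7_900 = predict_pbrc_wlp(ref_female, IntakeSchedule.constant(900.0)).weight_at(7)
        w7_450 = predict_pbrc_wlp(ref_female, IntakeSchedule.constant(450.0)).weight_at(7)
        assert w7_450 < w7_900
        n7_900 = predict_nih_bwp(ref_female, IntakeSchedule.constant(900.0), sedentary).weight_at(7)
        n7_450 = predict_nih_bwp(ref_female, IntakeSchedule.constant(450.0), sedentary).weight_at(7)
        assert n7_450 < n7_900

    @pytest.mark.parametrize("model", [ModelId.NIH_BWP, ModelId.PBRC_WLP])
    def test_heavier_baseline_larger_absolute_loss(self, model, program_schedule, sedentary):
        light = SubjectProfile("l", 46.0, Sex.FEMALE, 1.64, 90.0)
        heavy = SubjectProfile("h", 46.0, Sex.FEMALE, 1.64, 150.0)
        loss_light = 90.0 - predict(model, light, program_schedule, sedentary).weight_at(7)
        loss_heavy = 150.0 - predict(model, heavy, program_schedule, sedentary).weight_at(7)
        assert loss_heavy > loss_light

    @given(eligible_profiles)
    def test_maintenance_steady_state_property(self, profile):
        kcal = maintenance_intake_nih(profile, ActivityConfig(1.4))
        series = predict_nih_bwp(profile, IntakeSchedule.constant(kcal))
        dev = max(abs(w - profile.baseline_weight) for w in series.expected_weights)
        assert dev < 0.1


class TestNumerics:
    def test_week7_regression_values(self, ref_female, program_schedule, sedentary):
        nih = predict_nih_bwp(ref_female, program_schedule, sedentary).weight_at(7)
        pbrc = predict_pbrc_wlp(ref_female, program_schedule).weight_at(7)
        assert nih == pytest.approx(NIH_REF_WEEK7_KG, abs=1e-4)
        assert pbrc == pytest.approx(PBRC_REF_WEEK7_KG, abs=1e-4)

    def test_daily_step_matches_fine_step(self, ref_female, program_schedule, sedentary):
        coarse = predict_nih_bwp(ref_female, program_schedule, sedentary).weight_at(7)
        fine = predict_nih_bwp(ref_female, program_schedule, sedentary, dt=0.1).weight_at(7)
        assert abs(coarse - fine) < 0.01

    @pytest.mark.parametrize("model", [ModelId.NIH_BWP, ModelId.PBRC_WLP])
    def test_step_halving_stability(self, model, ref_female, program_schedule, sedentary):
        full = predict(model, ref_female, program_schedule, sedentary, dt=1.0).weight_at(7)
        half = predict(model, ref_female, program_schedule, sedentary, dt=0.5).weight_at(7)
        assert abs(full - half) < 0.01

    def test_energy_closure(self, ref_female, program_schedule):
        traj = simulate_hall_batch(
            np.array([46.0]),
            np.array([False]),
            np.array([1.64]),
            np.array([112.1]),
            program_schedule.daily_intake()[None, :],
        )
        tissue_energy = (
            c.RHO_F * (traj.fat[0, -1] - traj.fat[0, 0])
            + c.RHO_L * (traj.lean[0, -1] - traj.lean[0, 0])
            + c.RHO_G * (traj.glycogen[0, -1] - traj.glycogen[0, 0])
        )
        assert tissue_energy == pytest.approx(traj.energy_imbalance[0], abs=1e-6)

    def test_unstable_integration_reports_step_and_state(self):
        with pytest.raises(IntegrationError, match="step"):
            simulate_thomas_batch(
                np.array([40.0]),
                np.array([False]),
                np.array([1.64]),
                np.array([3.0]),
                np.full((1, 200), 50.0),
            )


class TestDispatchAndContracts:
    def test_dispatch_identity(self, ref_female, program_schedule, sedentary):
        via_dispatch = predict(ModelId.NIH_BWP, ref_female, program_schedule, sedentary)
        direct = predict_nih_bwp(ref_female, program_schedule, sedentary)
        assert via_dispatch == direct
        assert predict(ModelId.PBRC_WLP, ref_female, program_schedule) == predict_pbrc_wlp(
            ref_female, program_schedule
        )

    def test_both_models_cover_weeks_0_to_7(self, ref_female, program_schedule, sedentary):
        for model in ModelId:
            series = predict(model, ref_female, program_schedule, sedentary)
            assert series.times == tuple(range(8))
            assert all(w > 0 for w in series.expected_weights)

    def test_unknown_model_rejected(self, ref_female, program_schedule):
        with pytest.raises(ValueError):
            predict("NOT_A_MODEL", ref_female, program_schedule)

    def test_short_horizon_rejected(self, ref_female):
        short = IntakeSchedule.constant(900.0, horizon_days=30)
        with pytest.raises(ValueError, match="56"):
            predict_nih_bwp(ref_female, short)

    def test_batch_prediction_matches_per_subject(self, ref_female, ref_male, program_schedule, sedentary):
        batch = predict_cohort(ModelId.NIH_BWP, [ref_female, ref_male], program_schedule, sedentary)
        singles = [
            predict_nih_bwp(ref_female, program_schedule, sedentary),
            predict_nih_bwp(ref_male, program_schedule, sedentary),
        ]
        for b, s in zip(batch, singles):
            assert b.expected_weights == s.expected_weights
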