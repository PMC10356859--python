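"""Screening rules, baseline computation and cohort-flow accounting."""

import random

import pytest

from weightbench import ParticipantRecord, Sex
from weightbench.cohort_filter import (
    CohortComposition,
    ExclusionReason,
    ExclusionTally,
    MissingBaselineError,
    baseline_weight,
    build_cohort,
    is_adherent,
    screen_record,
)


def make_record(**overrides) -> ParticipantRecord:
    """A fully adherent, eligible record; keyword overrides mutate it."""
    weights = {-1: 113.0, 0: 112.0, **{w: 112.0 - 1.5 * w for w in range(1, 8)}}
    base = dict(
        subject_id="r1",
        age=46.0,
        sex=Sex.FEMALE,
        height=1.64,
        consented=True,
        weights_by_week=weights,
        mr_usage_percent=95.0,
        attendance_fraction=0.9,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestBaselineWeight:
    def test_mean_of_both_visits(self):
        bl = baseline_weight(114.0, 112.0)
        assert bl.value == 113.0 and not bl.partial

    def test_identical_visits(self):
        assert baseline_weight(113.0, 113.0).value == 113.0

    @pytest.mark.parametrize("w_m1,w0,expected", [(None, 112.0, 112.0), (114.0, None, 114.0)])
    def test_single_visit_fallback_flags_partial(self, w_m1, w0, expected):
        bl = baseline_weight(w_m1, w0)
        assert bl.value == expected and bl.partial

    def test_both_absent_raises(self):
        with pytest.raises(MissingBaselineError):
            baseline_weight(None, None)


class TestAdherence:
    @pytest.mark.parametrize(
        "usage,attendance,expected",
        [
            (80.0, 2.0 / 3.0, True),  # boundaries are adherent (strict exclusions)
            (100.0, 1.0, True),
            (95.0, 0.9, True),
            (79.9, 0.9, False),
            (101.0, 0.9, False),
            (90.0, 0.5, False),
        ],
    )
    def test_usage_and_attendance_rules(self, usage, attendance, expected):
        rec = make_record(mr_usage_percent=usage, attendance_fraction=attendance)
        assert is_adherent(rec) is expected

    def test_missing_adherence_data_defaults_to_non_adherent(self):
        rec = make_record(mr_usage_percent=None)
        assert is_adherent(rec) is False
        with pytest.raises(ValueError):
            is_adherent(rec, on_missing="raise")


class TestScreening:
    def test_fully_eligible_record_included(self):
        assert screen_record(make_record()) is None

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"consented": False}, ExclusionReason.NO_CONSENT),
            ({"age": 17.5}, ExclusionReason.MODEL_INELIGIBLE),
            ({"weights_by_week": {-1: 206.0, 0: 205.0, 3: 200.0}}, ExclusionReason.MODEL_INELIGIBLE),
            ({"height": 1.30}, ExclusionReason.MODEL_INELIGIBLE),
            ({"height": None}, ExclusionReason.MISSING_VARIABLES),
            ({"sex": None}, ExclusionReason.MISSING_VARIABLES),
            ({"weights_by_week": {3: 110.0}}, ExclusionReason.MISSING_VARIABLES),
            ({"weights_by_week": {-1: 113.0, 0: 112.0}}, ExclusionReason.NO_FOLLOWUP_WEIGHTS),
            ({"mr_usage_percent": 70.0}, ExclusionReason.NON_ADHERENT),
            ({"attendance_fraction": 0.5}, ExclusionReason.NON_ADHERENT),
        ],
    )
    def test_first_matching_reason(self, overrides, reason):
        assert screen_record(make_record(**overrides)) is reason

    def test_precedence_consent_before_eligibility(self):
        rec = make_record(consented=False, age=17.0, mr_usage_percent=10.0)
        assert screen_record(rec) is ExclusionReason.NO_CONSENT

    def test_precedence_eligibility_before_adherence(self):
        rec = make_record(age=17.0, mr_usage_percent=10.0)
        assert screen_record(rec) is ExclusionReason.MODEL_INELIGIBLE


class TestBuildCohort:
    def test_all_passing(self):
        records = [make_record(subject_id=f"r{i}") for i in range(10)]
        cohort, tally = build_cohort(records)
        assert tally.n_included == len(cohort) == 10
        assert all(v == 0 for v in tally.counts.values())

    def test_one_record_per_reason(self):
        records = [
            make_record(subject_id="inc"),
            make_record(subject_id="nc", consented=False),
            make_record(subject_id="mi", age=16.0),
            make_record(subject_id="mv", height=None),
            make_record(subject_id="nf", weights_by_week={-1: 113.0, 0: 112.0}),
            make_record(subject_id="na", mr_usage_percent=60.0),
        ]
        cohort, tally = build_cohort(records)
        assert [p.record.subject_id for p in cohort] == ["inc"]
        assert all(v == 1 for v in tally.counts.values())
        assert tally.n_screened == tally.n_included + tally.n_excluded

    def test_included_participant_carries_baseline_and_profile(self):
        cohort, _ = build_cohort([make_record()])
        part = cohort[0]
        assert part.baseline.value == pytest.approx(112.5)
        assert part.profile.baseline_weight == pytest.approx(112.5)
        assert part.profile.sex is Sex.FEMALE

    def test_order_independence(self):
        records = [
            make_record(subject_id=f"r{i}", consented=(i % 3 != 0), mr_usage_percent=60.0 if i % 5 == 0 else 95.0)
            for i in range(40)
        ]
        cohort_a, tally_a = build_cohort(records)
        shuffled = records[:]
        random.Random(1).shuffle(shuffled)
        cohort_b, tally_b = build_cohort(shuffled)
        assert tally_a.counts == tally_b.counts
        assert {p.record.subject_id for p in cohort_a} == {p.record.subject_id for p in cohort_b}

    def test_idempotence_on_included_cohort(self):
        records = [make_record(subject_id=f"r{i}") for i in range(8)]
        cohort, _ = build_cohort(records)
        again, tally = build_cohort([p.record for p in cohort])
        assert tally.n_excluded == 0 and len(again) == len(cohort)


class TestTallyArithmetic:
    def test_conservation_invariant(self):
        tally = ExclusionTally.from_counts(
            n_screened=100, no_consent=5, non_adherent=10
        )
        assert tally.n_included == 85
        assert tally.n_screened == tally.n_included + tally.n_excluded

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ExclusionTally.from_counts(n_screened=100, n_included=90, no_consent=5)

    def test_shares_sum_to_100(self):
        tally = ExclusionTally.from_counts(
            n_included=50, no_consent=3, model_ineligible=2, non_adherent=5
        )
        assert sum(tally.exclusion_shares_percent().values()) == pytest.approx(100.0)


class TestComposition:
    def test_from_cohort_counts_sexes_and_weights(self):
        records = [make_record(subject_id=f"f{i}") for i in range(3)]
        records.append(
            make_record(
                subject_id="m0",
                sex=Sex.MALE,
                weights_by_week={-1: 140.0, 0: 139.0, 1: 138.0, 2: 137.0},
            )
        )
        cohort, _ = build_cohort(records)
        comp = CohortComposition.from_cohort(cohort)
        assert comp.n == 4 and comp.n_female == 3
        assert comp.percent_female == pytest.approx(75.0)
        assert comp.weights_count == {7: 3, 2: 1}
        assert comp.percent_with_at_least(5) == pytest.approx(75.0)
        assert comp.percent_with_exactly(2) == pytest.approx(25.0)
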