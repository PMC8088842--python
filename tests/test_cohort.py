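"""Eligibility filters, BMI derivations, and outcome categorisation."""

import pytest
from hypothesis import given, settings, strategies as st

from retainwl.cohort import (
    ExclusionReport,
    OUTCOME_CATEGORIES,
    compute_bmi,
    filter_eligible,
    obesity_class,
    outcome_category,
)
from retainwl.records import N_WEEKS, UserProfile, WeeklyLog


def make_profile(uid="u0", gender="female", age=43.2, height=166.4,
                 initial=93.4, target=85.0):
    return UserProfile(user_id=uid, gender=gender, age=age, height=height,
                       initial_weight=initial, target_weight=target)


def make_logs(uid="u0", weeks=range(1, N_WEEKS + 1), weight_freq=5.0,
              adherence=70.0, weight=93.4):
    return [
        WeeklyLog(user_id=uid, week=w, weight_input_freq=weight_freq,
                  meal_input_adherence=adherence, exercise_input_freq=3,
                  calorie_intake=1600, steps_k=6, alcohol_drinks=1,
                  over_calorie_events=1, weight=weight)
        for w in weeks
    ]


@pytest.mark.parametrize(
    "weight, height, expected, decimals",
    [
        (93.4, 166.4, 33.7, 1),  # cohort-mean worked example
        (100.0, 200.0, 25.0, 6),
        (88.8, 166.4, 32.07, 2),
    ],
)
def test_bmi_worked_examples(weight, height, expected, decimals):
    assert round(compute_bmi(weight, height), decimals) == pytest.approx(expected)


@pytest.mark.parametrize("weight, height", [(0, 170), (-5, 170), (70, 0)])
def test_bmi_rejects_nonpositive_inputs(weight, height):
    with pytest.raises(ValueError):
        compute_bmi(weight, height)


@pytest.mark.parametrize(
    "bmi, expected",
    [
        (24.99, None),
        (25.0, "overweight"),
        (29.99, "overweight"),
        (30.0, "obese class I"),
        (33.7, "obese class I"),
        (35.0, "obese class II"),
        (40.0, "obese class III"),
        (55.0, "obese class III"),
    ],
)
def test_obesity_class_bands(bmi, expected):
    assert obesity_class(bmi) == expected


@pytest.mark.parametrize(
    "initial, final, expected",
    [
        (93.4, 88.8, "loss 2-5%"),  # p = 4.92%
        (100.0, 100.0, "stable"),
        (100.0, 84.0, "loss >15%"),  # p = 16%
        (100.0, 103.0, "gained >2%"),
        (100.0, 102.0, "stable"),  # gain of exactly 2% is stable
        (100.0, 98.0, "loss 2-5%"),  # loss of exactly 2% enters the loss band
        (100.0, 91.0, "loss 5-10%"),
        (100.0, 90.0, "loss 10-15%"),  # exactly 10% enters the higher band
        (100.0, 87.0, "loss 10-15%"),
        (100.0, 85.0, "loss >15%"),
    ],
)
def test_outcome_category_bands(initial, final, expected):
    assert outcome_category(initial, final) == expected


@given(
    initial=st.floats(40, 250, allow_nan=False),
    final=st.floats(40, 250, allow_nan=False),
)
@settings(derandomize=True, max_examples=200)
def test_outcome_categories_partition_all_weight_pairs(initial, final):
    assert outcome_category(initial, final) in OUTCOME_CATEGORIES


def _cohort_with_one_bad_user(bad_profile, bad_logs):
    good = make_profile(uid="good")
    profiles = [good, bad_profile]
    logs = {"good": make_logs("good"), bad_profile.user_id: bad_logs}
    return profiles, logs


@pytest.mark.parametrize(
    "profile_kwargs, filter_name",
    [
        (dict(height=124.0), "height_out_of_range"),
        (dict(height=231.0), "height_out_of_range"),
        (dict(age=66.0), "age_out_of_range"),
        (dict(age=17.0), "age_out_of_range"),
        (dict(initial=60.0, target=55.0), "bmi_below_25"),
        (dict(target=93.4), "target_not_below_initial"),
    ],
)
def test_profile_filters_exclude_and_report(profile_kwargs, filter_name):
    bad = make_profile(uid="bad", **profile_kwargs)
    profiles, logs = _cohort_with_one_bad_user(bad, make_logs("bad"))
    eligible, report = filter_eligible(profiles, logs)
    assert [p.user_id for p in eligible] == ["good"]
    assert report.exclusions[filter_name] == 1
    assert report.n_out + sum(report.exclusions.values()) == report.n_in == 2


def test_incomplete_program_and_records_filters():
    short = make_profile(uid="short")
    gappy = make_profile(uid="gappy")
    profiles = [make_profile("good"), short, gappy]
    gap_logs = make_logs("gappy")
    gap_logs[7] = WeeklyLog(user_id="gappy", week=8, weight_input_freq=0.0,
                            meal_input_adherence=70, exercise_input_freq=3,
                            calorie_intake=1600, steps_k=6, alcohol_drinks=1,
                            over_calorie_events=1, weight=93.0)
    logs = {
        "good": make_logs("good"),
        "short": make_logs("short", weeks=range(1, 13)),
        "gappy": gap_logs,
    }
    eligible, report = filter_eligible(profiles, logs)
    assert [p.user_id for p in eligible] == ["good"]
    assert report.exclusions["incomplete_program"] == 1
    assert report.exclusions["incomplete_records"] == 1


def test_filtering_is_idempotent_and_monotone(small_cohort):
    eligible, report1 = filter_eligible(small_cohort.profiles, small_cohort.logs)
    again, report2 = filter_eligible(eligible, small_cohort.logs)
    assert [p.user_id for p in again] == [p.user_id for p in eligible]
    assert report2.n_out == report2.n_in
    assert len(eligible) <= len(small_cohort.profiles)


def test_duplicate_user_id_rejected():
    profiles = [make_profile("dup"), make_profile("dup")]
    with pytest.raises(ValueError, match="duplicate"):
        filter_eligible(profiles, {"dup": make_logs("dup")})


def test_exclusion_report_must_reconcile():
    from collections import OrderedDict
    with pytest.raises(ValueError, match="reconcile"):
        ExclusionReport(n_in=5, n_out=3, exclusions=OrderedDict(height_out_of_range=1))
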