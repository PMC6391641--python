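"""Weekly criteria, payout arithmetic, and the week runner."""

import datetime as dt
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from adherepay import (
    DietDayRecord,
    IncentiveSchedule,
    Participant,
    QCStatus,
    Scenario,
    Sex,
    compute_incentive,
    evaluate_diet_criterion,
    evaluate_weight_criterion,
    run_study,
    run_week,
    scenario_for,
)
from adherepay.models import ErrorCode
from conftest import MONDAY, make_event

SAT, SUN = 5, 6


def diet_days(day_indices, kcal, pid="P001", anchor=MONDAY):
    return [
        DietDayRecord(pid, anchor + dt.timedelta(days=d), kcal)
        for d in day_indices
    ]


# ------------------------------------------------------- diet criterion ----

def test_five_threshold_days_with_saturday_meets(criteria):
    # female at exactly 1000 kcal on 5 days, one of them Saturday
    records = diet_days([0, 1, 2, 3, SAT], 1000)
    assert evaluate_diet_criterion(records, Sex.FEMALE, criteria)


def test_male_below_1200_fails_even_with_weekend(criteria):
    records = diet_days([0, 1, 2, 3, SUN], 1150)
    assert not evaluate_diet_criterion(records, Sex.MALE, criteria)


def test_five_weekdays_without_weekend_fails(criteria):
    records = diet_days([0, 1, 2, 3, 4], 2000)
    assert not evaluate_diet_criterion(records, Sex.FEMALE, criteria)


def test_unnormalized_records_rejected(criteria):
    records = diet_days([0, 0], 1000)
    with pytest.raises(ValueError, match="one per date"):
        evaluate_diet_criterion(records, Sex.FEMALE, criteria)


def brute_force_diet(qualifying_days: frozenset) -> bool:
    """Literal restatement of the printed rule for the oracle."""
    return len(qualifying_days) >= 5 and bool(qualifying_days & {SAT, SUN})


def test_exactly_28_of_128_day_subsets_qualify(criteria):
    """Enumerating all 2^7 subsets of qualifying days reproduces the
    printed rule: 5+ days including a weekend day -> 28 subsets."""
    n_true = 0
    for r in range(8):
        for subset in itertools.combinations(range(7), r):
            records = diet_days(subset, 1000) + diet_days(
                sorted(set(range(7)) - set(subset)), 999
            )
            got = evaluate_diet_criterion(records, Sex.FEMALE, criteria)
            assert got == brute_force_diet(frozenset(subset))
            n_true += got
    assert n_true == 28


@pytest.mark.parametrize("sex,threshold", [(Sex.FEMALE, 1000), (Sex.MALE, 1200)])
def test_threshold_recovered_by_calorie_grid(sex, threshold, criteria):
    """The smallest uniform 5-day (incl. Saturday) calorie total that
    meets the criterion is exactly the sex-specific threshold."""
    passing = [
        kcal
        for kcal in range(threshold - 25, threshold + 26)
        if evaluate_diet_criterion(
            diet_days([0, 1, 2, 3, SAT], kcal), sex, criteria
        )
    ]
    assert min(passing) == threshold


@settings(deadline=None, max_examples=100)
@given(
    days=st.sets(st.integers(0, 6), min_size=0, max_size=6),
    extra=st.integers(0, 6),
)
def test_adding_qualifying_day_is_monotone(days, extra, criteria):
    """Adding one more qualifying logging day never flips met -> unmet."""
    before = evaluate_diet_criterion(
        diet_days(sorted(days), 1500), Sex.FEMALE, criteria
    )
    after = evaluate_diet_criterion(
        diet_days(sorted(days | {extra}), 1500), Sex.FEMALE, criteria
    )
    assert after >= before


# ----------------------------------------------------- weight criterion ----

def test_net_loss_meets(tz, criteria):
    events = [
        make_event(tz, day=0, weight=100.0, status=QCStatus.RETAINED),
        make_event(tz, day=6, weight=99.5, status=QCStatus.RETAINED),
    ]
    assert evaluate_weight_criterion(events, criteria) == (True, pytest.approx(0.5))


def test_zero_change_is_not_loss(tz, criteria):
    events = [
        make_event(tz, day=0, weight=100.0, status=QCStatus.RETAINED),
        make_event(tz, day=6, weight=100.0, status=QCStatus.RETAINED),
    ]
    assert evaluate_weight_criterion(events, criteria) == (False, 0.0)


def test_single_weighin_not_evaluable(tz, criteria):
    events = [make_event(tz, status=QCStatus.RETAINED)]
    assert evaluate_weight_criterion(events, criteria) == (False, None)


def test_arrival_order_does_not_matter(tz, criteria):
    events = [
        make_event(tz, day=d, hour=h, weight=w, status=QCStatus.RETAINED)
        for d, h, w in [(3, 9, 101.2), (0, 7, 102.0), (6, 20, 100.4), (1, 8, 101.9)]
    ]
    expected = evaluate_weight_criterion(
        sorted(events, key=lambda e: e.timestamp), criteria
    )
    for perm_seed in range(5):
        shuffled = events[:]
        random.Random(perm_seed).shuffle(shuffled)
        assert evaluate_weight_criterion(shuffled, criteria) == expected


# ------------------------------------------------------------- payouts ----

def test_control_group_earns_nothing(study_config):
    earned, foregone = compute_incentive(
        4, 1, 5, True, True, study_config.schedule
    )
    assert (earned, foregone) == (0, 0)


def test_single_arm_full_payout():
    sched = IncentiveSchedule(
        diet_cents=[1000] * 23 + [7000], weight_cents=[1000] * 23 + [7000],
        weekly_cap=7000,
    )
    assert compute_incentive(2, 1, 1, True, False, sched) == (1000, 0)
    assert compute_incentive(2, 1, 1, False, True, sched) == (0, 1000)


def test_combined_arm_halves_each_component():
    sched = IncentiveSchedule(
        diet_cents=[1000] * 23 + [7000], weight_cents=[1000] * 23 + [7000],
        weekly_cap=7000,
    )
    # only diet met: half of the 1000-cent week, half foregone
    assert compute_incentive(1, 1, 1, True, False, sched) == (500, 500)
    assert compute_incentive(1, 1, 1, True, True, sched) == (1000, 0)
    assert compute_incentive(1, 1, 1, False, False, sched) == (0, 1000)


def test_odd_cent_goes_to_diet_half():
    sched = IncentiveSchedule(
        diet_cents=[1001] * 10 + [19990], weight_cents=[1001] * 10 + [19990],
        weekly_cap=19990,
    )
    assert compute_incentive(1, 1, 1, True, False, sched) == (501, 500)
    assert compute_incentive(1, 1, 1, False, True, sched) == (500, 501)


def test_total_cap_truncates_earnings(study_config):
    earned, _ = compute_incentive(
        2, 1, 1, True, False, study_config.schedule, prior_total=29900
    )
    assert earned == 100


def test_cohort3_floor_paid_unconditionally(study_config):
    earned, foregone = compute_incentive(
        2, 3, 1, False, False, study_config.schedule
    )
    assert earned == 200
    # foregone is the week's component shortfall; the floor cancels out
    assert foregone == study_config.schedule.diet_amount(1)


def test_unknown_group_is_fatal(study_config):
    with pytest.raises(ValueError, match="unknown group"):
        compute_incentive(5, 1, 1, True, True, study_config.schedule)


@settings(deadline=None, max_examples=200)
@given(
    group=st.integers(1, 4),
    cohort=st.integers(1, 3),
    week=st.integers(1, 24),
    diet_met=st.booleans(),
    weight_met=st.booleans(),
    prior=st.integers(0, 30000),
)
def test_conservation_and_caps(
    group, cohort, week, diet_met, weight_met, prior, study_config
):
    """Pre-cap conservation: earned + foregone = weekly maximum
    attainable; post-cap earnings never breach either cap."""
    sched = study_config.schedule
    earned, foregone = compute_incentive(
        group, cohort, week, diet_met, weight_met, sched, prior
    )
    uncapped, _ = compute_incentive(
        group, cohort, week, diet_met, weight_met, sched, 0
    )
    assert uncapped + foregone == sched.max_attainable(group, cohort, week)
    assert earned == min(uncapped, sched.total_cap - prior)
    assert earned <= sched.weekly_cap
    assert prior + earned <= sched.total_cap


def test_scenarios_follow_group_applicability():
    assert scenario_for(4, True, True) is Scenario.CONTROL
    assert scenario_for(1, True, True) is Scenario.EARNED_BOTH
    assert scenario_for(1, True, False) is Scenario.EARNED_DIET
    assert scenario_for(1, False, True) is Scenario.EARNED_WEIGHT
    assert scenario_for(2, True, True) is Scenario.EARNED_DIET
    assert scenario_for(2, False, True) is Scenario.MISSED
    assert scenario_for(3, False, True) is Scenario.EARNED_WEIGHT
    assert scenario_for(3, True, False) is Scenario.MISSED


# ------------------------------------------------------------ run_week ----

def small_roster():
    mk = lambda pid, group, status: Participant(
        participant_id=pid, sex="female", cohort=1, group=group,
        enrollment_date=MONDAY, status=status, scale_id="",
    )
    return [
        mk("P001", 2, "active"),
        mk("P002", 3, "active"),
        mk("P003", 1, "withdrawn"),
    ]


def test_run_week_skips_withdrawn(study_config, tz):
    results, errors = run_week(small_roster(), [], [], 1, study_config)
    assert sorted(r.participant_id for r in results) == ["P001", "P002"]
    assert errors == []


def test_run_week_empty_streams_all_missed(study_config):
    results, _ = run_week(small_roster(), [], [], 1, study_config)
    assert all(r.scenario is Scenario.MISSED for r in results)
    assert all(not r.diet_met and not r.weight_met for r in results)


def test_run_week_flags_off_roster_events(study_config, tz):
    events = [make_event(tz, pid="GHOST")]
    results, errors = run_week(small_roster(), [], events, 1, study_config)
    assert len(results) == 2
    assert [e.code for e in errors] == [ErrorCode.UNKNOWN_PARTICIPANT]
    assert not any(r.participant_id == "GHOST" for r in results)


def test_run_week_respects_as_of_due_rule(study_config, tz):
    # week 1 ends after day 7; adjudicating mid-week yields nothing
    mid_week = dt.datetime.combine(
        MONDAY + dt.timedelta(days=3), dt.time(12), tzinfo=tz
    )
    results, _ = run_week(small_roster(), [], [], 1, study_config, mid_week)
    assert results == []
    due = dt.datetime.combine(
        MONDAY + dt.timedelta(days=7), dt.time(0), tzinfo=tz
    )
    results, _ = run_week(small_roster(), [], [], 1, study_config, due)
    assert len(results) == 2


def test_run_week_applies_qc_to_raw_stream(study_config, tz):
    # a gamed day plus a clean day: retained set has one event -> not
    # evaluable -> weight criterion fails despite an apparent big loss
    events = [
        make_event(tz, pid="P002", day=0, hour=8, weight=100.0),
        make_event(tz, pid="P002", day=0, hour=9, weight=120.0),
        make_event(tz, pid="P002", day=6, hour=8, weight=90.0),
    ]
    results, _ = run_week(small_roster(), [], events, 1, study_config)
    r = next(r for r in results if r.participant_id == "P002")
    assert r.weight_met is False and r.weight_delta_kg is None


def test_run_week_deterministic_under_permutation(study_config, tz):
    events = [
        make_event(tz, pid=pid, day=d, hour=8, weight=100.0 - d * 0.1)
        for pid in ("P001", "P002") for d in range(5)
    ]
    diet = [
        DietDayRecord(pid, MONDAY + dt.timedelta(days=d), 1200)
        for pid in ("P001", "P002") for d in [0, 1, 2, 3, SAT]
    ]
    base, _ = run_week(small_roster(), diet, events, 1, study_config)
    for seed in range(3):
        ev2, diet2 = events[:], diet[:]
        random.Random(seed).shuffle(ev2)
        random.Random(seed).shuffle(diet2)
        again, _ = run_week(small_roster(), diet2, ev2, 1, study_config)
        assert again == base


def test_run_study_all_due_equals_union_of_weeks(study_config, tz):
    events = [
        make_event(tz, pid="P001", day=d, hour=8, weight=100.0 - 0.05 * d)
        for d in range(21)
    ]
    as_of = dt.datetime.combine(
        MONDAY + dt.timedelta(days=16), dt.time(9), tzinfo=tz
    )
    all_due, _ = run_study(small_roster(), [], events, study_config, as_of)
    manual = []
    totals = {}
    for week in (1, 2, 3):
        res, _ = run_week(small_roster(), [], events, week, study_config, as_of, totals)
        for r in res:
            totals[r.participant_id] = totals.get(r.participant_id, 0) + r.amount_earned
        manual.extend(res)
    assert all_due == manual
    # only weeks 1 and 2 have fully elapsed by day 16
    assert {r.week for r in all_due} == {1, 2}
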