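"""Weekly criteria evaluation and incentive computation.

The two incented behaviors:

* **Dietary self-monitoring** — log at least the sex-specific daily
  calorie threshold (1000 kcal women / 1200 kcal men) on at least 5 days
  of the week, at least one of them a Saturday or Sunday.
* **Weight loss** — any strictly positive difference between the first
  and last retained weigh-in of the week; a week with fewer than two
  retained weigh-ins (or a single instant) is not evaluable and fails.

Payouts follow the 2x2 arm design.  The combined arm earns half of each
component per behavior met, so its weekly maximum matches the single
behavior arms; the control arm earns nothing.  An unconditional cohort
floor (e.g. $2/week in cohort 3) is added for incentive arms, the weekly
payout is clipped at the weekly cap, and cumulative earnings are
truncated at the study total cap.  The foregone amount — what a missed
week *would* have paid — feeds the loss-framed notification.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping

from .models import (
    AdjudicationResult,
    CriteriaConfig,
    DietDayRecord,
    ErrorCode,
    IncentiveSchedule,
    IngestError,
    Participant,
    QCStatus,
    Scenario,
    Sex,
    Status,
    StudyConfig,
    WeighInEvent,
    study_week_of,
    week_end_date,
)
from .qc import apply_qc, evaluable_for_weight

SATURDAY, SUNDAY = 5, 6  # date.weekday() codes


def evaluate_diet_criterion(
    week_records: Iterable[DietDayRecord],
    sex: Sex,
    config: CriteriaConfig,
) -> bool:
    """True iff enough qualifying logging days, including a weekend day.

    A day qualifies when its logged total meets the sex-specific
    threshold.  Records must already be normalized to one per date.
    """
    records = list(week_records)
    dates = [r.date for r in records]
    if len(set(dates)) != len(dates):
        raise ValueError("diet records must be normalized to one per date")
    threshold = config.kcal_threshold(sex)
    qualifying = {r.date for r in records if r.calories_logged >= threshold}
    if len(qualifying) < config.min_logging_days:
        return False
    if config.require_weekend_day:
        return any(d.weekday() in (SATURDAY, SUNDAY) for d in qualifying)
    return True


def evaluate_weight_criterion(
    week_events: Iterable[WeighInEvent],
    config: CriteriaConfig,
) -> tuple[bool, float | None]:
    """Weight-loss verdict and the first-minus-last delta in kg.

    Returns ``(False, None)`` for non-evaluable weeks.  The delta is
    computed over retained events ordered by timestamp; strictly positive
    delta (net loss) meets the criterion — zero change is not loss.
    """
    events = sorted(week_events, key=lambda ev: (ev.timestamp, ev.weight_kg))
    if not evaluable_for_weight(events, config):
        return False, None
    retained = [ev for ev in events if ev.qc_status is QCStatus.RETAINED]
    delta = retained[0].weight_kg - retained[-1].weight_kg
    return delta > 0, delta


def compute_incentive(
    group: int,
    cohort: int,
    week: int,
    diet_met: bool,
    weight_met: bool,
    schedule: IncentiveSchedule,
    prior_total: int = 0,
) -> tuple[int, int]:
    """Cents earned and foregone for one participant-week.

    Components: group 2 earns the full diet amount iff the diet criterion
    is met, group 3 the full weight amount iff weight was lost, group 1
    half of each independently (odd cent to the diet half), group 4
    nothing.  The cohort weekly floor is added unconditionally for groups
    1-3 and the sum clipped at the weekly cap.  ``amount_earned`` is then
    truncated so that ``prior_total + amount_earned`` never exceeds the
    study total cap; ``amount_foregone`` is the pre-truncation shortfall
    from the week's maximum attainable.
    """
    if group not in (1, 2, 3, 4):
        raise ValueError(f"unknown group {group}")
    if not 1 <= week <= schedule.n_weeks:
        raise ValueError(f"week {week} outside schedule (1..{schedule.n_weeks})")
    if prior_total > schedule.total_cap:
        raise ValueError("prior_total exceeds the study total cap")
    if group == 4:
        return 0, 0
    if group == 1:
        half_diet, half_weight = schedule.halves(week)
        components = half_diet * diet_met + half_weight * weight_met
    elif group == 2:
        components = schedule.diet_amount(week) * diet_met
    else:  # group 3
        components = schedule.weight_amount(week) * weight_met
    floor = schedule.floor(cohort)
    attainable = schedule.max_attainable(group, cohort, week)
    earned = min(schedule.weekly_cap, floor + components)
    foregone = attainable - earned
    earned = min(earned, schedule.total_cap - prior_total)
    return earned, foregone


def scenario_for(group: int, diet_met: bool, weight_met: bool) -> Scenario:
    """Outcome scenario given the group's incented behaviors."""
    if group == 4:
        return Scenario.CONTROL
    diet_incented = group in (1, 2)
    weight_incented = group in (1, 3)
    earned_diet = diet_incented and diet_met
    earned_weight = weight_incented and weight_met
    if earned_diet and earned_weight:
        return Scenario.EARNED_BOTH
    if earned_diet:
        return Scenario.EARNED_DIET
    if earned_weight:
        return Scenario.EARNED_WEIGHT
    return Scenario.MISSED


def adjudicate_week(
    participant: Participant,
    week_diet: Iterable[DietDayRecord],
    week_events: Iterable[WeighInEvent],
    week: int,
    config: StudyConfig,
    prior_total: int = 0,
) -> AdjudicationResult:
    """Adjudicate one participant-week from already-windowed streams."""
    diet_met = evaluate_diet_criterion(week_diet, participant.sex, config.criteria)
    weight_met, delta = evaluate_weight_criterion(week_events, config.criteria)
    earned, foregone = compute_incentive(
        participant.group, participant.cohort, week,
        diet_met, weight_met, config.schedule, prior_total,
    )
    return AdjudicationResult(
        participant_id=participant.participant_id,
        week=week,
        diet_met=diet_met,
        weight_met=weight_met,
        weight_delta_kg=delta,
        amount_earned=earned,
        amount_foregone=foregone,
        scenario=scenario_for(participant.group, diet_met, weight_met),
    )


def run_week(
    roster: Iterable[Participant],
    diet: Iterable[DietDayRecord],
    weights: Iterable[WeighInEvent],
    week: int,
    config: StudyConfig,
    as_of: dt.datetime | None = None,
    prior_totals: Mapping[str, int] | None = None,
) -> tuple[list[AdjudicationResult], list[IngestError]]:
    """Adjudicate study week ``week`` for every participant who is due.

    Due means: roster status ``active`` (or ``completed``, for
    retrospective reruns) and, when ``as_of`` is given, the week's window
    fully elapsed by then.  Withdrawn participants are skipped.  Events
    for ids absent from the roster yield ``unknown_participant`` errors
    and no result.  QC runs here on the raw weigh-in stream, so results
    never depend on whether the caller prefiltered.
    """
    roster = list(roster)
    if not 1 <= week <= config.n_weeks:
        raise ValueError(f"week {week} outside the study (1..{config.n_weeks})")
    by_id = {p.participant_id: p for p in roster}
    prior_totals = dict(prior_totals or {})

    errors: list[IngestError] = []
    unknown: set[str] = set()
    diet_by_pid: dict[str, list[DietDayRecord]] = {}
    for rec in diet:
        if rec.participant_id not in by_id:
            unknown.add(rec.participant_id)
            continue
        diet_by_pid.setdefault(rec.participant_id, []).append(rec)
    events_by_pid: dict[str, list[WeighInEvent]] = {}
    for ev in weights:
        if ev.participant_id not in by_id:
            unknown.add(ev.participant_id)
            continue
        events_by_pid.setdefault(ev.participant_id, []).append(ev)
    for pid in sorted(unknown):
        errors.append(IngestError(
            ErrorCode.UNKNOWN_PARTICIPANT,
            f"events for participant {pid!r} absent from roster",
        ))

    results: list[AdjudicationResult] = []
    for p in sorted(roster, key=lambda p: p.participant_id):
        if p.status is Status.WITHDRAWN:
            continue
        if as_of is not None:
            due_on = week_end_date(p, week)
            if as_of.astimezone(config.tzinfo).date() < due_on:
                continue
        week_diet = [
            r for r in diet_by_pid.get(p.participant_id, [])
            if study_week_of(p, dt.datetime.combine(
                r.date, dt.time(12), tzinfo=config.tzinfo), config) == week
        ]
        raw = events_by_pid.get(p.participant_id, [])
        filtered, _ = apply_qc(raw, config.criteria, config.tzinfo)
        week_events = [
            ev for ev in filtered
            if study_week_of(p, ev.timestamp, config) == week
        ]
        results.append(adjudicate_week(
            p, week_diet, week_events, week, config,
            prior_totals.get(p.participant_id, 0),
        ))
    return results, errors


def run_study(
    roster: Iterable[Participant],
    diet: Iterable[DietDayRecord],
    weights: Iterable[WeighInEvent],
    config: StudyConfig,
    as_of: dt.datetime | None = None,
    through_week: int | None = None,
) -> tuple[list[AdjudicationResult], list[IngestError]]:
    """Run all due weeks 1..``through_week`` in order, accumulating each
    participant's cumulative earnings so the study total cap binds."""
    roster = list(roster)
    diet = list(diet)
    weights = list(weights)
    through_week = through_week or config.n_weeks
    totals: dict[str, int] = {}
    all_results: list[AdjudicationResult] = []
    all_errors: list[IngestError] = []
    for week in range(1, through_week + 1):
        results, errors = run_week(
            roster, diet, weights, week, config, as_of, totals
        )
        for r in results:
            totals[r.participant_id] = totals.get(r.participant_id, 0) + r.amount_earned
        all_results.extend(results)
        if week == 1:
            all_errors.extend(errors)  # identical every week; report once
    return all_results, all_errors


def write_results(results: Iterable[AdjudicationResult], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "participant_id", "week", "diet_met", "weight_met",
            "weight_delta_kg", "amount_earned_cents",
            "amount_foregone_cents", "scenario",
        ])
        for r in results:
            w.writerow([
                r.participant_id, r.week, r.diet_met, r.weight_met,
                "" if r.weight_delta_kg is None else f"{r.weight_delta_kg:.3f}",
                r.amount_earned, r.amount_foregone, r.scenario.value,
            ])
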