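"""Synthetic 24-week adherence cohort generator.

No public dataset of home weigh-in and calorie-logging streams exists
for this kind of trial, so the package ships a simulator that emulates
the behavioral structure the engine assumes: per-participant logging and
weighing propensities (Beta-distributed across the cohort, with an
optional slow decline over the study), a drifting noisy weight
trajectory that loses weight only in adherent weeks, occasional injected
same-day "gaming" weigh-ins that the QC filter must catch, and weekly
dropout.  Ground truth for both weekly criteria is computed during
generation by a literal, self-contained re-application of the criteria
definitions to the written streams, so every engine stage can be checked
end to end.

All randomness flows from one seed through a single
``numpy.random.Generator``; a fixed seed reproduces the output files
byte for byte.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from .io import write_diet_stream, write_roster, write_weighin_stream
from .models import (
    DietDayRecord,
    Participant,
    Sex,
    Status,
    StudyConfig,
    WeighInEvent,
)

SATURDAY, SUNDAY = 5, 6


class SimulationConfig(BaseModel):
    """Generator parameters.

    Propensity defaults are loosely calibrated to the high-but-declining
    adherence such trials report (participants averaging ~5 weigh-in days
    per week early on): Beta(6,2) logging (mean 0.75) and Beta(5,3)
    weighing (mean 0.625) propensities with a small negative weekly logit
    drift.  ``p_log_day`` / ``p_weigh_day``, when set, override the Beta
    draw with a fixed probability for every participant (useful for
    forced-adherence scenarios).
    """

    seed: int = 0
    cohort_sizes: list[int] = Field(default_factory=lambda: [34, 31, 31])
    p_log_day: float | None = None
    p_log_day_beta: tuple[float, float] = (6.0, 2.0)
    p_weigh_day: float | None = None
    p_weigh_day_beta: tuple[float, float] = (5.0, 3.0)
    kcal_mean: float = 1400.0
    kcal_sd: float = Field(default=250.0, ge=0.0)
    true_loss_rate_kg_per_week: float = 0.25
    weight_noise_sd_kg: float = Field(default=0.4, ge=0.0)
    baseline_weight_mean_kg: float = 105.0
    baseline_weight_sd_kg: float = Field(default=15.0, ge=0.0)
    gaming_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    dropout_hazard: float = Field(default=0.01, ge=0.0, le=1.0)
    adherence_drift_per_week: float = -0.02
    p_second_reading: float = Field(default=0.15, ge=0.0, le=1.0)
    study_start: dt.date = dt.date(2023, 1, 9)  # a Monday
    cohort_stagger_weeks: int = 12
    enrollment_jitter_days: int = Field(default=6, ge=0)


@dataclass(frozen=True)
class GroundTruthRow:
    """True weekly verdicts, recorded at generation time."""

    participant_id: str
    week: int
    diet_met: bool
    weight_met: bool
    n_gaming_days: int


@dataclass
class SimulatedCohort:
    roster: list[Participant]
    weighins: list[WeighInEvent]
    diet: list[DietDayRecord]
    ground_truth: list[GroundTruthRow]
    # per-participant (logging, weighing) propensities, for recovery tests
    propensities: dict[str, tuple[float, float]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "roster": outdir / "roster.csv",
            "weighins": outdir / "weighins.csv",
            "diet": outdir / "diet.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        write_roster(self.roster, paths["roster"])
        write_weighin_stream(
            sorted(self.weighins, key=WeighInEvent.sort_key), paths["weighins"]
        )
        write_diet_stream(
            sorted(self.diet, key=DietDayRecord.sort_key), paths["diet"]
        )
        with paths["ground_truth"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([
                "participant_id", "week", "diet_met", "weight_met", "n_gaming_days",
            ])
            for row in self.ground_truth:
                w.writerow([
                    row.participant_id, row.week, row.diet_met,
                    row.weight_met, row.n_gaming_days,
                ])
        return paths


def _drifted(p: float, week: int, drift: float) -> float:
    """Weekly logit drift of a propensity; degenerate 0/1 stay fixed."""
    if p <= 0.0 or p >= 1.0 or drift == 0.0:
        return min(max(p, 0.0), 1.0)
    logit = np.log(p / (1 - p)) + drift * (week - 1)
    return float(1 / (1 + np.exp(-logit)))


def inject_gaming_event(
    day_events: list[WeighInEvent],
    rng: np.random.Generator,
    threshold: float,
) -> WeighInEvent:
    """Fabricate a discordant same-day weigh-in (a proxy weigher).

    The injected weight is the day's minimum times a factor drawn
    uniformly from (1 + threshold, 1.5); after rounding to scale
    precision it is nudged upward if needed so the day's relative spread
    is strictly above the threshold and the QC filter must fire.
    """
    if not day_events:
        raise ValueError("gaming injection needs at least one genuine weigh-in")
    day_min = min(ev.weight_kg for ev in day_events)
    factor = float(rng.uniform(1 + threshold, 1.5))
    weight = round(day_min * factor, 2)
    while (weight - day_min) / day_min <= threshold:
        weight = round(weight + 0.01, 2)
    base = day_events[0]
    ts = base.timestamp + dt.timedelta(
        minutes=int(rng.integers(1, 120))
    )
    return WeighInEvent(base.participant_id, ts, weight)


def generate_cohort(
    config: SimulationConfig, study: StudyConfig
) -> SimulatedCohort:
    """Generate a full study's roster, event streams, and ground truth."""
    rng = np.random.default_rng(config.seed)
    tz = study.tzinfo
    criteria = study.criteria
    threshold_frac = criteria.same_day_gaming_fraction

    roster: list[Participant] = []
    weighins: list[WeighInEvent] = []
    diet: list[DietDayRecord] = []
    truth: list[GroundTruthRow] = []
    propensities: dict[str, tuple[float, float]] = {}

    pid_counter = 0
    for cohort_idx, size in enumerate(config.cohort_sizes, start=1):
        cohort_start = config.study_start + dt.timedelta(
            weeks=config.cohort_stagger_weeks * (cohort_idx - 1)
        )
        # blocked randomization: permuted blocks of the four arms
        groups: list[int] = []
        while len(groups) < size:
            groups.extend(int(g) for g in rng.permutation([1, 2, 3, 4]))
        groups = groups[:size]

        for g in groups:
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            kcal_threshold = criteria.kcal_threshold(sex)
            enrollment = cohort_start + dt.timedelta(
                days=int(rng.integers(0, config.enrollment_jitter_days + 1))
            )
            p_log = (
                config.p_log_day
                if config.p_log_day is not None
                else float(rng.beta(*config.p_log_day_beta))
            )
            p_weigh = (
                config.p_weigh_day
                if config.p_weigh_day is not None
                else float(rng.beta(*config.p_weigh_day_beta))
            )
            baseline = max(
                60.0,
                float(rng.normal(
                    config.baseline_weight_mean_kg, config.baseline_weight_sd_kg
                )),
            )
            propensities[pid] = (p_log, p_weigh)

            status = Status.ACTIVE
            adherent_weeks = 0
            for week in range(1, study.n_weeks + 1):
                if week > 1 and rng.random() < config.dropout_hazard:
                    status = Status.WITHDRAWN
                    break
                p_log_w = _drifted(p_log, week, config.adherence_drift_per_week)
                p_weigh_w = _drifted(p_weigh, week, config.adherence_drift_per_week)
                week_start = enrollment + dt.timedelta(days=7 * (week - 1))

                # --- diet days ---------------------------------------------
                qualifying_dates: set[dt.date] = set()
                for d in range(7):
                    if rng.random() >= p_log_w:
                        continue
                    date = week_start + dt.timedelta(days=d)
                    kcal = max(0, int(round(rng.normal(
                        config.kcal_mean, config.kcal_sd
                    ))))
                    diet.append(DietDayRecord(pid, date, kcal))
                    if kcal >= kcal_threshold:
                        qualifying_dates.add(date)
                diet_met = len(qualifying_dates) >= criteria.min_logging_days and (
                    not criteria.require_weekend_day
                    or any(d.weekday() in (SATURDAY, SUNDAY)
                           for d in qualifying_dates)
                )

                # --- weigh-ins ---------------------------------------------
                start_weight = baseline - (
                    config.true_loss_rate_kg_per_week * adherent_weeks
                )
                week_events: dict[dt.date, list[WeighInEvent]] = {}
                n_gaming_days = 0
                for d in range(7):
                    if rng.random() >= p_weigh_w:
                        continue
                    date = week_start + dt.timedelta(days=d)
                    true_w = start_weight - (
                        config.true_loss_rate_kg_per_week * d / 7
                        if diet_met else 0.0
                    )
                    n_readings = 1 + (rng.random() < config.p_second_reading)
                    day_events = []
                    used_minutes: set[int] = set()
                    for _ in range(n_readings):
                        minute = int(rng.integers(6 * 60, 22 * 60))
                        while minute in used_minutes:
                            minute = (minute + 7) % (24 * 60)
                        used_minutes.add(minute)
                        ts = dt.datetime.combine(
                            date, dt.time(minute // 60, minute % 60), tzinfo=tz
                        )
                        measured = max(30.0, round(
                            true_w + float(rng.normal(0, config.weight_noise_sd_kg)),
                            2,
                        ))
                        day_events.append(WeighInEvent(pid, ts, measured))
                    if rng.random() < config.gaming_rate:
                        day_events.append(inject_gaming_event(
                            day_events, rng, threshold_frac
                        ))
                        n_gaming_days += 1
                    week_events[date] = day_events

                for evs in week_events.values():
                    weighins.extend(evs)

                # --- ground truth: literal criteria re-application ---------
                retained: list[WeighInEvent] = []
                for date, evs in week_events.items():
                    ws = [e.weight_kg for e in evs]
                    if (max(ws) - min(ws)) / min(ws) > threshold_frac:
                        continue  # whole day discarded
                    retained.extend(evs)
                retained.sort(key=lambda e: (e.timestamp, e.weight_kg))
                weight_met = False
                if (
                    len(retained) >= criteria.min_weighins_per_week
                    and len({e.timestamp for e in retained}) >= 2
                ):
                    weight_met = (
                        retained[0].weight_kg - retained[-1].weight_kg > 0
                    )

                truth.append(GroundTruthRow(
                    pid, week, diet_met, weight_met, n_gaming_days
                ))
                if diet_met:
                    adherent_weeks += 1

            roster.append(Participant(
                participant_id=pid,
                sex=sex,
                cohort=cohort_idx,
                group=g,
                enrollment_date=enrollment,
                status=status,
                scale_id=f"SC{pid_counter:04d}",
            ))

    weighins.sort(key=WeighInEvent.sort_key)
    diet.sort(key=DietDayRecord.sort_key)
    return SimulatedCohort(roster, weighins, diet, truth, propensities)


def read_ground_truth(path: str | Path) -> list[GroundTruthRow]:
    rows = []
    with Path(path).open(newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(GroundTruthRow(
                participant_id=rec["participant_id"],
                week=int(rec["week"]),
                diet_met=rec["diet_met"] == "True",
                weight_met=rec["weight_met"] == "True",
                n_gaming_days=int(rec["n_gaming_days"]),
            ))
    return rows
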