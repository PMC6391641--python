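"""Domain types for a weekly-incentive weight-loss trial engine.

The engine adjudicates two weekly behaviors per participant — dietary
self-monitoring (calorie logging in a phone app) and weight loss (measured
on a cellular home scale) — under a 2x2 factorial incentive design:

* group 1: incentives for both self-monitoring and weight loss (half of
  each component per behavior, so the weekly maximum matches the
  single-behavior arms),
* group 2: incentives for dietary self-monitoring only,
* group 3: incentives for weekly weight loss only,
* group 4: no incentives (attention control, messages only).

All money is carried as integer cents; the study envelope is a $300.00
total cap and a $28.00 weekly cap, with an optional unconditional weekly
floor per cohort ($2.00 in cohort 3 by default).

Weeks are enrollment-anchored, 7-day, half-open windows in a single
configurable study timezone — cohorts enrolled on a staggered calendar,
so calendar weeks would misalign participants at different study stages.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace
from zoneinfo import ZoneInfo

from pydantic import BaseModel, Field, field_validator, model_validator


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class Sex(str, enum.Enum):
    """Participant sex; selects the daily calorie-logging threshold."""

    FEMALE = "female"
    MALE = "male"


class Status(str, enum.Enum):
    ACTIVE = "active"
    WITHDRAWN = "withdrawn"
    COMPLETED = "completed"


class QCStatus(str, enum.Enum):
    """Lifecycle of a weigh-in through quality control.

    Transitions are one-way: ``raw`` -> ``retained`` or ``raw`` -> ``removed``.
    """

    RAW = "raw"
    RETAINED = "retained"
    REMOVED = "removed"


class ErrorCode(str, enum.Enum):
    """Machine-detectable ingestion failures.

    Mirrors the troubleshooting taxonomy of remote-monitoring trials:
    missing data, upstream connection failures, duplicated transmissions,
    malformed payloads, and events for unenrolled scale/app accounts.
    """

    NO_DATA = "no_data"
    CONNECTION_ERROR = "connection_error"
    DUPLICATE_RECORD = "duplicate_record"
    MALFORMED_RECORD = "malformed_record"
    UNKNOWN_PARTICIPANT = "unknown_participant"


class Scenario(str, enum.Enum):
    """Weekly outcome scenario driving payout and message choice."""

    EARNED_BOTH = "earned_both"
    EARNED_DIET = "earned_diet"
    EARNED_WEIGHT = "earned_weight"
    MISSED = "missed"
    CONTROL = "control"


# --------------------------------------------------------------------------
# Event records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeighInEvent:
    """One time-stamped scale transmission.

    ``weight_kg`` must be strictly positive.  ``qc_status`` starts ``raw``;
    the QC filter produces ``retained``/``removed`` copies (the dataclass is
    frozen — use :meth:`with_status`).
    """

    participant_id: str
    timestamp: dt.datetime  # timezone-aware
    weight_kg: float
    qc_status: QCStatus = QCStatus.RAW

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight must be positive, got {self.weight_kg}")
        if self.timestamp.tzinfo is None:
            raise ValueError("weigh-in timestamps must be timezone-aware")

    def with_status(self, status: QCStatus) -> "WeighInEvent":
        if self.qc_status is not QCStatus.RAW and status is not self.qc_status:
            raise ValueError(
                f"illegal QC transition {self.qc_status.value} -> {status.value}"
            )
        return replace(self, qc_status=status)

    def sort_key(self) -> tuple:
        return (self.participant_id, self.timestamp, self.weight_kg)


@dataclass(frozen=True)
class DietDayRecord:
    """Total calories logged by one participant on one calendar day."""

    participant_id: str
    date: dt.date
    calories_logged: int

    def __post_init__(self) -> None:
        if self.calories_logged < 0:
            raise ValueError("calories_logged must be nonnegative")

    def sort_key(self) -> tuple:
        return (self.participant_id, self.date)


@dataclass(frozen=True)
class IngestError:
    code: ErrorCode
    detail: str


# --------------------------------------------------------------------------
# Participant
# --------------------------------------------------------------------------

class Participant(BaseModel):
    """Enrollment record — the unit of weekly adjudication."""

    model_config = {"frozen": True}

    participant_id: str
    sex: Sex
    cohort: int = Field(ge=1, le=3)
    group: int = Field(ge=1, le=4)
    enrollment_date: dt.date
    status: Status = Status.ACTIVE
    scale_id: str = ""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class CriteriaConfig(BaseModel):
    """Thresholds defining the two weekly incentive criteria.

    Defaults are the trial's printed rules: log at least 1000 kcal (women)
    or 1200 kcal (men) on 5+ days including a weekend day; weigh in at
    least twice per week; discard any day whose weigh-ins spread by more
    than 10% (anti-gaming screen).
    """

    kcal_threshold_female: int = Field(default=1000, gt=0)
    kcal_threshold_male: int = Field(default=1200, gt=0)
    min_logging_days: int = Field(default=5, ge=1, le=7)
    require_weekend_day: bool = True
    min_weighins_per_week: int = Field(default=2, ge=1)
    same_day_gaming_fraction: float = Field(default=0.10, gt=0.0, lt=1.0)

    def kcal_threshold(self, sex: Sex) -> int:
        return (
            self.kcal_threshold_male
            if sex is Sex.MALE
            else self.kcal_threshold_female
        )


def _default_weekly_cents() -> list[int]:
    # Escalating 24-week component schedule: $10 x 12, $13 x 8, $16 x 3,
    # $28 final week.  Sums to exactly the $300 study cap for a
    # single-component arm; no week exceeds the $28 weekly cap.
    return [1000] * 12 + [1300] * 8 + [1600] * 3 + [2800]


class IncentiveSchedule(BaseModel):
    """Per-week payout amounts for each incented component, in cents.

    ``diet_cents[w-1]`` / ``weight_cents[w-1]`` are the full single-arm
    amounts for study week ``w``.  The combined arm (group 1) earns half of
    each component per behavior met, odd cents going to the diet half, so
    its weekly maximum equals the single-arm maximum.  ``weekly_floor_by_
    cohort`` is an unconditional weekly payment to incentive-arm
    participants; the weekly payout including the floor is clipped at
    ``weekly_cap``, and cumulative earnings are truncated at ``total_cap``.
    """

    diet_cents: list[int] = Field(default_factory=_default_weekly_cents)
    weight_cents: list[int] = Field(default_factory=_default_weekly_cents)
    weekly_floor_by_cohort: dict[int, int] = Field(
        default_factory=lambda: {1: 0, 2: 0, 3: 200}
    )
    total_cap: int = 30000
    weekly_cap: int = 2800

    @model_validator(mode="after")
    def _check_envelope(self) -> "IncentiveSchedule":
        if len(self.diet_cents) != len(self.weight_cents):
            raise ValueError("diet and weight schedules must cover the same weeks")
        if any(a < 0 for a in self.diet_cents + self.weight_cents):
            raise ValueError("schedule amounts must be nonnegative")
        if any(f < 0 for f in self.weekly_floor_by_cohort.values()):
            raise ValueError("weekly floors must be nonnegative")
        for w in range(1, len(self.diet_cents) + 1):
            for g in (1, 2, 3):
                if self.max_components(g, w) > self.weekly_cap:
                    raise ValueError(
                        f"week {w} group {g} attainable exceeds weekly cap"
                    )
        if sum(self.diet_cents) != self.total_cap:
            raise ValueError("diet component weekly maxima must sum to total_cap")
        if sum(self.weight_cents) != self.total_cap:
            raise ValueError("weight component weekly maxima must sum to total_cap")
        return self

    @property
    def n_weeks(self) -> int:
        return len(self.diet_cents)

    def diet_amount(self, week: int) -> int:
        return self.diet_cents[week - 1]

    def weight_amount(self, week: int) -> int:
        return self.weight_cents[week - 1]

    def floor(self, cohort: int) -> int:
        return self.weekly_floor_by_cohort.get(cohort, 0)

    def halves(self, week: int) -> tuple[int, int]:
        """Combined-arm (group 1) per-behavior amounts; odd cent to diet."""
        d, w = self.diet_amount(week), self.weight_amount(week)
        return (d + 1) // 2, w // 2

    def max_components(self, group: int, week: int) -> int:
        """Maximum component earnings for the week, before floor/caps."""
        if group == 1:
            hd, hw = self.halves(week)
            return hd + hw
        if group == 2:
            return self.diet_amount(week)
        if group == 3:
            return self.weight_amount(week)
        if group == 4:
            return 0
        raise ValueError(f"unknown group {group}")

    def max_attainable(self, group: int, cohort: int, week: int) -> int:
        """Weekly maximum payout including the cohort floor, clipped at
        the weekly cap."""
        if group == 4:
            return 0
        return min(self.weekly_cap, self.floor(cohort) + self.max_components(group, week))


# Default message templates.  The earned/missed frames are the trial's
# notification wording; behavior phrases are tailored per group.  The
# both-missed phrase omits "enough" so every reachable rendering fits a
# single 160-character SMS.
EARNED_TEMPLATE = (
    "Great job on {behavior} this week! {amount} will be added to your "
    "debit card. Keep up the good work!"
)
MISSED_TEMPLATE = (
    "You did not {behavior} this week. If you had, you would have earned "
    "{amount}. Please log your food and lose weight for a chance to earn money."
)
CONTROL_TEMPLATE = (
    "Keep going! Remember to weigh in on your scale and log your meals "
    "this week. Every day counts toward your goal."
)
REMINDER_TEMPLATE = (
    "Reminder: your in-person group session is on {date}. See you there!"
)

EARNED_PHRASES = {
    Scenario.EARNED_BOTH: "logging your food and losing weight",
    Scenario.EARNED_DIET: "logging your food",
    Scenario.EARNED_WEIGHT: "losing weight",
}
# Missed phrase depends on which behaviors the group is incented for.
MISSED_PHRASES = {
    1: "log your food or lose weight",
    2: "log your food",
    3: "lose enough weight",
}

DEFAULT_TIPS = [
    "Tip: plan tomorrow's meals tonight - logging is easier when it's decided.",
    "You're building a habit. One honest log at a time.",
    "Tip: weigh in first thing in the morning for consistent readings.",
    "Small steps add up. Keep logging!",
    "Tip: pre-log your restaurant order before you arrive.",
    "Every weigh-in is data you can use. Step on the scale today.",
    "Tip: batch-cook once and log the recipe, then reuse it all week.",
    "Proud of you for sticking with it this week.",
    "Tip: a food scale makes calorie logs far more accurate.",
    "Consistency beats perfection. Log what you actually ate.",
]


class MessagingConfig(BaseModel):
    """SMS templating: scenario templates, length bound, and tip library.

    Every template must fit ``max_length`` when rendered with its longest
    behavior phrase and a worst-case dollar amount — validated here so a
    misconfigured template fails at load, never at send time.
    """

    max_length: int = 160
    earned_template: str = EARNED_TEMPLATE
    missed_template: str = MISSED_TEMPLATE
    control_template: str = CONTROL_TEMPLATE
    reminder_template: str = REMINDER_TEMPLATE
    earned_phrases: dict[Scenario, str] = Field(
        default_factory=lambda: dict(EARNED_PHRASES)
    )
    missed_phrases: dict[int, str] = Field(
        default_factory=lambda: dict(MISSED_PHRASES)
    )
    tip_library: list[str] = Field(default_factory=lambda: list(DEFAULT_TIPS))
    tips_per_week: int = 2
    tip_cohorts: list[int] = Field(default_factory=lambda: [2, 3])

    @model_validator(mode="after")
    def _check_lengths(self) -> "MessagingConfig":
        worst_amount = "$27.50"  # six characters: two dollar digits + cents
        candidates = [
            self.earned_template.format(behavior=b, amount=worst_amount)
            for b in self.earned_phrases.values()
        ] + [
            self.missed_template.format(behavior=b, amount=worst_amount)
            for b in self.missed_phrases.values()
        ] + [
            self.control_template,
            self.reminder_template.format(date="September 27, 2026"),
        ] + list(self.tip_library)
        for body in candidates:
            if len(body) > self.max_length:
                raise ValueError(
                    f"template renders to {len(body)} chars, over the "
                    f"{self.max_length}-char limit: {body!r}"
                )
        return self


class StudyConfig(BaseModel):
    """Top-level trial configuration."""

    n_weeks: int = Field(default=24, ge=1)
    cohort_sizes: list[int] = Field(default_factory=lambda: [34, 31, 31])
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    schedule: IncentiveSchedule = Field(default_factory=IncentiveSchedule)
    messaging: MessagingConfig = Field(default_factory=MessagingConfig)
    study_timezone: str = "America/New_York"

    @field_validator("cohort_sizes")
    @classmethod
    def _cohorts_positive(cls, v: list[int]) -> list[int]:
        if not v or any(n < 1 for n in v):
            raise ValueError("every cohort size must be >= 1")
        return v

    @model_validator(mode="after")
    def _schedule_covers_weeks(self) -> "StudyConfig":
        if self.schedule.n_weeks < self.n_weeks:
            raise ValueError(
                f"schedule covers {self.schedule.n_weeks} weeks but the "
                f"study runs {self.n_weeks}"
            )
        ZoneInfo(self.study_timezone)  # raises on unknown zone
        return self

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.study_timezone)


# --------------------------------------------------------------------------
# Study-week arithmetic
# --------------------------------------------------------------------------

def study_week_of(
    participant: Participant, instant: dt.datetime, config: StudyConfig
) -> int | None:
    """Map an instant to the participant's enrollment-anchored study week.

    Week ``w`` covers local dates ``[enrollment + 7*(w-1), enrollment + 7*w)``
    in the study timezone.  Returns ``None`` before enrollment or after
    week ``n_weeks``.
    """
    local_date = instant.astimezone(config.tzinfo).date()
    days = (local_date - participant.enrollment_date).days
    if days < 0:
        return None
    week = days // 7 + 1
    return week if week <= config.n_weeks else None


def week_start_date(participant: Participant, week: int) -> dt.date:
    return participant.enrollment_date + dt.timedelta(days=7 * (week - 1))


def week_end_date(participant: Participant, week: int) -> dt.date:
    """First date after the week's window (the adjudication date)."""
    return participant.enrollment_date + dt.timedelta(days=7 * week)


# --------------------------------------------------------------------------
# Adjudication result
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjudicationResult:
    """One participant-week verdict.

    Both criteria are evaluated for every participant (the data streams
    exist in all arms and staff review both); the participant's group
    determines which criteria pay out and which scenario applies.
    ``amount_earned + amount_foregone`` equals the week's maximum
    attainable payout for the participant's group and cohort (before
    truncation at the study total cap).
    """

    participant_id: str
    week: int
    diet_met: bool | None
    weight_met: bool | None
    weight_delta_kg: float | None
    amount_earned: int
    amount_foregone: int
    scenario: Scenario

    def __post_init__(self) -> None:
        if self.amount_earned < 0 or self.amount_foregone < 0:
            raise ValueError("amounts must be nonnegative")


def format_cents(cents: int) -> str:
    """Render cents as the dollar string used in messages: ``$28``,
    ``$27.50``, ``$2``."""
    dollars, rem = divmod(cents, 100)
    return f"${dollars}" if rem == 0 else f"${dollars}.{rem:02d}"
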