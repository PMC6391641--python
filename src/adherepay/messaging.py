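"""Weekly SMS composition.

Every adjudicated participant-week produces exactly one outcome message.
Earned weeks celebrate the behavior and state the amount added to the
participant's debit card; missed weeks are loss-framed — they state the
amount the participant *would have earned* — because foregone gains are
felt more sharply than absent ones.  Control-arm participants get an
encouragement message with no dollar amount.  All bodies must fit one
160-character SMS so they never split across two messages.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .models import (
    AdjudicationResult,
    MessagingConfig,
    Participant,
    Scenario,
    format_cents,
    week_end_date,
)


class MessageKind(str, enum.Enum):
    INCENTIVE_EARNED = "incentive_earned"
    INCENTIVE_MISSED = "incentive_missed"
    CONTROL_ENCOURAGEMENT = "control_encouragement"
    SESSION_REMINDER = "session_reminder"
    TIP = "tip"

_AMOUNT_KINDS = {MessageKind.INCENTIVE_EARNED, MessageKind.INCENTIVE_MISSED}


@dataclass(frozen=True)
class OutboundMessage:
    participant_id: str
    send_on: dt.date
    body: str
    kind: MessageKind

    def __post_init__(self) -> None:
        has_amount = "$" in self.body
        if has_amount != (self.kind in _AMOUNT_KINDS):
            raise ValueError(
                f"{self.kind.value} message must contain a dollar amount "
                f"iff it reports an incentive: {self.body!r}"
            )


class TemplateLengthError(ValueError):
    """A rendered body exceeded the SMS length bound.

    This is a configuration defect: truncating silently could corrupt the
    stated dollar amount, so rendering fails loudly instead.
    """


def _render(template: str, config: MessagingConfig, **fields: str) -> str:
    body = template.format(**fields)
    if len(body) > config.max_length:
        raise TemplateLengthError(
            f"rendered body is {len(body)} chars "
            f"(limit {config.max_length}): {body!r}"
        )
    return body


def compose_weekly_message(
    result: AdjudicationResult,
    group: int,
    config: MessagingConfig,
    send_on: dt.date | None = None,
) -> OutboundMessage:
    """Compose the single weekly outcome message for one adjudication.

    Earned scenarios report ``amount_earned``; the missed scenario
    reports ``amount_foregone`` (loss framing); the control scenario has
    no amount.
    """
    send_on = send_on or dt.date(1970, 1, 1)
    if result.scenario is Scenario.CONTROL:
        body = _render(config.control_template, config)
        kind = MessageKind.CONTROL_ENCOURAGEMENT
    elif result.scenario is Scenario.MISSED:
        body = _render(
            config.missed_template, config,
            behavior=config.missed_phrases[group],
            amount=format_cents(result.amount_foregone),
        )
        kind = MessageKind.INCENTIVE_MISSED
    else:
        body = _render(
            config.earned_template, config,
            behavior=config.earned_phrases[result.scenario],
            amount=format_cents(result.amount_earned),
        )
        kind = MessageKind.INCENTIVE_EARNED
    return OutboundMessage(result.participant_id, send_on, body, kind)


def schedule_tips(
    participant: Participant, week: int, config: MessagingConfig
) -> list[OutboundMessage]:
    """Twice-weekly encouragement/skill tips, tip-library cohorts only.

    Tips cycle deterministically through the library, so participant
    ``w``-th week sees items ``(w-1)*tips_per_week ..`` modulo the
    library size.  Sent on the 2nd and 5th day of the week by default.
    """
    if participant.cohort not in config.tip_cohorts:
        return []
    if not config.tip_library:
        raise ValueError("tip library is empty")
    messages = []
    week_start = participant.enrollment_date + dt.timedelta(days=7 * (week - 1))
    for i in range(config.tips_per_week):
        idx = ((week - 1) * config.tips_per_week + i) % len(config.tip_library)
        offset = min(1 + 3 * i, 6)  # days 2 and 5 of the week by default
        messages.append(OutboundMessage(
            participant_id=participant.participant_id,
            send_on=week_start + dt.timedelta(days=offset),
            body=config.tip_library[idx],
            kind=MessageKind.TIP,
        ))
    return messages


def schedule_session_reminder(
    participant: Participant,
    session_date: dt.date,
    config: MessagingConfig | None = None,
) -> OutboundMessage | None:
    """One session reminder per participant, every arm alike; none if the
    session predates the participant's enrollment."""
    config = config or MessagingConfig()
    if session_date < participant.enrollment_date:
        return None
    body = _render(
        config.reminder_template, config,
        date=session_date.strftime("%b %d").replace(" 0", " "),
    )
    return OutboundMessage(
        participant_id=participant.participant_id,
        send_on=session_date - dt.timedelta(days=1),
        body=body,
        kind=MessageKind.SESSION_REMINDER,
    )


def compose_outbox(
    results: Iterable[AdjudicationResult],
    roster: Iterable[Participant],
    config: MessagingConfig,
) -> list[OutboundMessage]:
    """One outcome message per adjudicated participant-week."""
    by_id = {p.participant_id: p for p in roster}
    outbox = []
    for r in results:
        p = by_id[r.participant_id]
        outbox.append(compose_weekly_message(
            r, p.group, config, send_on=week_end_date(p, r.week)
        ))
    return outbox


def write_outbox(messages: Iterable[OutboundMessage], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "send_on", "kind", "body"])
        for m in messages:
            w.writerow([m.participant_id, m.send_on.isoformat(), m.kind.value, m.body])
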