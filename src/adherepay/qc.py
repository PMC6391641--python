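"""Anti-gaming quality control for home weigh-in streams.

Cellular home scales can be gamed: someone else steps on, or the
participant bears only part of their weight.  The screen used here flags
any participant-local calendar day whose readings spread by strictly more
than a configured fraction of the day's minimum, and discards the whole
day — with discordant readings there is no way to tell which one belongs
to the participant.  Cross-day variation is never touched; week-to-week
change is exactly the signal being adjudicated.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable
from zoneinfo import ZoneInfo

from .models import CriteriaConfig, QCStatus, WeighInEvent


@dataclass(frozen=True)
class QCReport:
    """One discarded participant-day of weigh-ins."""

    participant_id: str
    date: dt.date
    removed_events: tuple[WeighInEvent, ...]
    reason: str
    max_relative_spread: float

    def __post_init__(self) -> None:
        if not self.removed_events:
            raise ValueError("a QC report must carry removed events")


def filter_same_day_weights(
    events: Iterable[WeighInEvent],
    threshold: float,
    tz: ZoneInfo | dt.tzinfo,
) -> tuple[list[WeighInEvent], list[QCReport]]:
    """Apply the same-day discordance filter to one participant's events.

    For each local calendar day, the relative spread is
    ``(max - min) / min`` over that day's weights.  Days with spread
    strictly greater than ``threshold`` have every event marked
    ``removed`` and yield one :class:`QCReport`; all other events are
    marked ``retained``.  Idempotent: re-filtering the retained set
    removes nothing.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    events = list(events)
    pids = {ev.participant_id for ev in events}
    if len(pids) > 1:
        raise ValueError(f"events span multiple participants: {sorted(pids)}")

    by_day: dict[dt.date, list[WeighInEvent]] = {}
    for ev in events:
        by_day.setdefault(ev.timestamp.astimezone(tz).date(), []).append(ev)

    out: list[WeighInEvent] = []
    reports: list[QCReport] = []
    for day in sorted(by_day):
        day_events = sorted(by_day[day], key=WeighInEvent.sort_key)
        weights = [ev.weight_kg for ev in day_events]
        spread = (max(weights) - min(weights)) / min(weights)
        if spread > threshold:
            removed = tuple(ev.with_status(QCStatus.REMOVED) for ev in day_events)
            out.extend(removed)
            reports.append(QCReport(
                participant_id=day_events[0].participant_id,
                date=day,
                removed_events=removed,
                reason="same_day_gaming",
                max_relative_spread=spread,
            ))
        else:
            out.extend(ev.with_status(QCStatus.RETAINED) for ev in day_events)
    out.sort(key=WeighInEvent.sort_key)
    return out, reports


def apply_qc(
    events: Iterable[WeighInEvent],
    config: CriteriaConfig,
    tz: ZoneInfo | dt.tzinfo,
) -> tuple[list[WeighInEvent], list[QCReport]]:
    """Same-day filter over a multi-participant stream."""
    by_pid: dict[str, list[WeighInEvent]] = {}
    for ev in events:
        by_pid.setdefault(ev.participant_id, []).append(ev)
    out: list[WeighInEvent] = []
    reports: list[QCReport] = []
    for pid in sorted(by_pid):
        filtered, reps = filter_same_day_weights(
            by_pid[pid], config.same_day_gaming_fraction, tz
        )
        out.extend(filtered)
        reports.extend(reps)
    out.sort(key=WeighInEvent.sort_key)
    return out, reports


def evaluable_for_weight(
    week_events: Iterable[WeighInEvent], config: CriteriaConfig
) -> bool:
    """True iff the week has enough retained weigh-ins to compute a
    first-minus-last weight change: at least ``min_weighins_per_week``
    retained events spanning at least two distinct timestamps."""
    retained = [
        ev for ev in week_events if ev.qc_status is QCStatus.RETAINED
    ]
    if len(retained) < config.min_weighins_per_week:
        return False
    return len({ev.timestamp for ev in retained}) >= 2


def write_qc_reports(reports: Iterable[QCReport], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "date", "n_removed", "max_relative_spread"])
        for r in reports:
            w.writerow([
                r.participant_id, r.date.isoformat(),
                len(r.removed_events), f"{r.max_relative_spread:.6f}",
            ])
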