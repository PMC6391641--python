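"""Readers and writers for the line-oriented study files.

Two interchangeable on-disk encodings are accepted for the event streams:
CSV with a fixed header, or JSON-lines (one object per line).  A file
whose first non-blank line starts with ``{`` is parsed as JSON-lines.
Malformed lines are skipped and reported as :class:`IngestError`; they are
never fatal — remote-monitoring pipelines must tolerate bad transmissions.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Iterable

import yaml

from .models import (
    StudyConfig,
    DietDayRecord,
    ErrorCode,
    IngestError,
    Participant,
    WeighInEvent,
)

WEIGHIN_FIELDS = ["participant_id", "timestamp", "weight_kg"]
DIET_FIELDS = ["participant_id", "date", "calories"]
ROSTER_FIELDS = [
    "participant_id", "sex", "cohort", "group",
    "enrollment_date", "status", "scale_id",
]


def _iter_records(path: Path, fields: list[str]) -> Iterable[tuple[int, dict | None]]:
    """Yield (lineno, record-dict) pairs; None for unparseable lines."""
    text = path.read_text()
    lines = text.splitlines()
    first = next((ln for ln in lines if ln.strip()), "")
    if first.lstrip().startswith("{"):
        for i, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            try:
                obj = json.loads(ln)
                if not isinstance(obj, dict):
                    raise ValueError("not an object")
                yield i, obj
            except (json.JSONDecodeError, ValueError):
                yield i, None
    else:
        reader = csv.DictReader(lines)
        if reader.fieldnames is None:
            return
        missing = set(fields) - set(reader.fieldnames)
        if missing:
            raise ValueError(
                f"{path}: CSV header missing fields {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):
            yield i, row


def read_weighin_stream(
    path: str | Path,
    known_ids: set[str] | None = None,
) -> tuple[list[WeighInEvent], list[IngestError]]:
    """Parse a weigh-in stream file.

    Exact duplicates (same participant, timestamp, and weight) are dropped
    with a ``duplicate_record`` error.  If ``known_ids`` is given, events
    for other participants are dropped with ``unknown_participant``.
    Output is sorted by (participant_id, timestamp) regardless of input
    order.
    """
    path = Path(path)
    events: list[WeighInEvent] = []
    errors: list[IngestError] = []
    seen: set[tuple] = set()
    for lineno, rec in _iter_records(path, WEIGHIN_FIELDS):
        if rec is None:
            errors.append(IngestError(
                ErrorCode.MALFORMED_RECORD, f"{path.name}:{lineno}: unparseable line"
            ))
            continue
        try:
            pid = str(rec["participant_id"]).strip()
            ts = dt.datetime.fromisoformat(str(rec["timestamp"]).strip())
            weight = float(rec["weight_kg"])
            if not pid:
                raise ValueError("empty participant_id")
            ev = WeighInEvent(pid, ts, weight)
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(IngestError(
                ErrorCode.MALFORMED_RECORD, f"{path.name}:{lineno}: {exc}"
            ))
            continue
        if known_ids is not None and pid not in known_ids:
            errors.append(IngestError(
                ErrorCode.UNKNOWN_PARTICIPANT,
                f"{path.name}:{lineno}: participant {pid!r} not on roster",
            ))
            continue
        key = (ev.participant_id, ev.timestamp, ev.weight_kg)
        if key in seen:
            errors.append(IngestError(
                ErrorCode.DUPLICATE_RECORD,
                f"{path.name}:{lineno}: duplicate weigh-in {key}",
            ))
            continue
        seen.add(key)
        events.append(ev)
    events.sort(key=WeighInEvent.sort_key)
    return events, errors


def read_diet_stream(
    path: str | Path,
    known_ids: set[str] | None = None,
) -> tuple[list[DietDayRecord], list[IngestError]]:
    """Parse a diet-log file, summing per-entry rows into daily totals.

    Logging apps emit one row per food entry; the weekly criterion is
    about daily totals, so multiple rows for a participant-date are summed
    into a single record.
    """
    path = Path(path)
    totals: dict[tuple[str, dt.date], int] = {}
    errors: list[IngestError] = []
    for lineno, rec in _iter_records(path, DIET_FIELDS):
        if rec is None:
            errors.append(IngestError(
                ErrorCode.MALFORMED_RECORD, f"{path.name}:{lineno}: unparseable line"
            ))
            continue
        try:
            pid = str(rec["participant_id"]).strip()
            date = dt.date.fromisoformat(str(rec["date"]).strip())
            kcal = int(rec["calories"])
            if not pid:
                raise ValueError("empty participant_id")
            if kcal < 0:
                raise ValueError(f"negative calories {kcal}")
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(IngestError(
                ErrorCode.MALFORMED_RECORD, f"{path.name}:{lineno}: {exc}"
            ))
            continue
        if known_ids is not None and pid not in known_ids:
            errors.append(IngestError(
                ErrorCode.UNKNOWN_PARTICIPANT,
                f"{path.name}:{lineno}: participant {pid!r} not on roster",
            ))
            continue
        totals[(pid, date)] = totals.get((pid, date), 0) + kcal
    records = [
        DietDayRecord(pid, date, kcal)
        for (pid, date), kcal in sorted(totals.items())
    ]
    return records, errors


def read_roster(path: str | Path) -> list[Participant]:
    """Read the participant roster CSV.  Roster errors are fatal: the
    trial cannot adjudicate against an ambiguous enrollment list."""
    path = Path(path)
    participants: list[Participant] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            p = Participant(
                participant_id=row["participant_id"],
                sex=row["sex"],
                cohort=int(row["cohort"]),
                group=int(row["group"]),
                enrollment_date=dt.date.fromisoformat(row["enrollment_date"]),
                status=row["status"],
                scale_id=row.get("scale_id", ""),
            )
            if p.participant_id in seen:
                raise ValueError(f"duplicate roster id {p.participant_id!r}")
            seen.add(p.participant_id)
            participants.append(p)
    return participants


# --------------------------------------------------------------------------
# Writers (CSV; exact round-trip with the readers above)
# --------------------------------------------------------------------------

def write_weighin_stream(events: Iterable[WeighInEvent], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(WEIGHIN_FIELDS)
        for ev in events:
            # repr() of the float guarantees value-exact round-trip
            w.writerow([ev.participant_id, ev.timestamp.isoformat(), repr(ev.weight_kg)])


def write_diet_stream(records: Iterable[DietDayRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DIET_FIELDS)
        for r in records:
            w.writerow([r.participant_id, r.date.isoformat(), r.calories_logged])


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML study configuration; defaults when ``path`` is None."""
    if path is None:
        return StudyConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig.model_validate(data)


def save_study_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )


def write_roster(participants: Iterable[Participant], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ROSTER_FIELDS)
        for p in participants:
            w.writerow([
                p.participant_id, p.sex.value, p.cohort, p.group,
                p.enrollment_date.isoformat(), p.status.value, p.scale_id,
            ])
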