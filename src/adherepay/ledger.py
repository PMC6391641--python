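"""Payment ledger: the human-in-the-loop workflow behind each incentive.

Institutional payment rules kept the study from paying automatically:
after the engine computed an amount, study staff reviewed it (approve /
edit / deny), a transfer was requested, and the money landed on the
participant's debit card roughly one day after the notification text.
The ledger models that lifecycle as a small state machine,

    computed -> approved | edited | denied
    approved | edited -> scheduled -> paid

and is event-sourced: every mutation appends an event, and replaying the
event log reconstructs the identical ledger state.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .models import AdjudicationResult


class LedgerState(str, enum.Enum):
    COMPUTED = "computed"
    APPROVED = "approved"
    EDITED = "edited"
    DENIED = "denied"
    SCHEDULED = "scheduled"
    PAID = "paid"


class ReviewAction(str, enum.Enum):
    APPROVE = "approve"
    EDIT = "edit"
    DENY = "deny"


_LEGAL = {
    LedgerState.COMPUTED: {LedgerState.APPROVED, LedgerState.EDITED, LedgerState.DENIED},
    LedgerState.APPROVED: {LedgerState.SCHEDULED},
    LedgerState.EDITED: {LedgerState.SCHEDULED},
    LedgerState.SCHEDULED: {LedgerState.PAID},
    LedgerState.DENIED: set(),
    LedgerState.PAID: set(),
}


class LedgerError(ValueError):
    pass


@dataclass(frozen=True)
class LedgerEntry:
    participant_id: str
    week: int
    amount: int  # computed cents
    state: LedgerState
    amount_final: int
    state_timestamps: tuple[tuple[LedgerState, dt.datetime], ...] = ()
    hold_reason: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.participant_id, self.week)

    def timestamp_of(self, state: LedgerState) -> dt.datetime | None:
        for s, t in self.state_timestamps:
            if s is state:
                return t
        return None

    def _advance(self, state: LedgerState, at: dt.datetime, **changes) -> "LedgerEntry":
        if state not in _LEGAL[self.state]:
            raise LedgerError(
                f"illegal transition {self.state.value} -> {state.value} "
                f"for {self.key}"
            )
        last = self.state_timestamps[-1][1] if self.state_timestamps else None
        if last is not None and at < last:
            raise LedgerError(f"timestamps must be monotone for {self.key}")
        return replace(
            self, state=state,
            state_timestamps=self.state_timestamps + ((state, at),),
            hold_reason=None, **changes,
        )


class Ledger:
    """Event-sourced entry store with cap enforcement.

    ``delay`` is the institutional gap between approval and the scheduled
    transfer, default 24 hours.
    """

    def __init__(
        self,
        total_cap: int = 30000,
        weekly_cap: int = 2800,
        delay: dt.timedelta = dt.timedelta(days=1),
    ) -> None:
        self.total_cap = total_cap
        self.weekly_cap = weekly_cap
        self.delay = delay
        self.entries: dict[tuple[str, int], LedgerEntry] = {}
        self.events: list[tuple] = []

    # -- commands ----------------------------------------------------------

    def stage(
        self, results: Iterable[AdjudicationResult], at: dt.datetime
    ) -> list[LedgerEntry]:
        """Create a ``computed`` entry for every result with a positive
        amount; zero-amount results produce none.  Restaging an existing
        (participant, week) is fatal — duplicate payments must never be
        possible to stage."""
        staged = []
        for r in results:
            if r.amount_earned <= 0:
                continue
            key = (r.participant_id, r.week)
            if key in self.entries:
                raise LedgerError(f"entry already staged for {key}")
            entry = LedgerEntry(
                participant_id=r.participant_id,
                week=r.week,
                amount=r.amount_earned,
                state=LedgerState.COMPUTED,
                amount_final=r.amount_earned,
                state_timestamps=((LedgerState.COMPUTED, at),),
            )
            self.entries[key] = entry
            self.events.append(("stage", r.participant_id, r.week, r.amount_earned, at))
            staged.append(entry)
        return staged

    def review(
        self,
        key: tuple[str, int],
        action: ReviewAction,
        at: dt.datetime,
        new_amount: int | None = None,
    ) -> LedgerEntry:
        """Apply a staff review action to a ``computed`` entry."""
        entry = self.entries[key]
        if action is ReviewAction.EDIT:
            if new_amount is None:
                raise LedgerError("edit requires new_amount")
            if not 0 <= new_amount <= self.weekly_cap:
                raise LedgerError(
                    f"edited amount {new_amount} violates the weekly cap"
                )
            others = self._committed_total(key[0], exclude=key)
            if others + new_amount > self.total_cap:
                raise LedgerError(
                    f"edited amount {new_amount} would breach the total cap"
                )
            entry = entry._advance(LedgerState.EDITED, at, amount_final=new_amount)
        elif action is ReviewAction.APPROVE:
            if new_amount is not None:
                raise LedgerError("approve does not take an amount")
            entry = entry._advance(LedgerState.APPROVED, at)
        elif action is ReviewAction.DENY:
            entry = entry._advance(LedgerState.DENIED, at)
        else:  # pragma: no cover - enum is exhaustive
            raise LedgerError(f"unknown action {action}")
        self.entries[key] = entry
        self.events.append(("review", *key, action.value, new_amount, at))
        return entry

    def schedule_payments(self, at: dt.datetime) -> list[LedgerEntry]:
        """Schedule every reviewed (approved/edited) entry at ``at`` plus
        the institutional delay.  An entry that would push a participant's
        committed total past the study cap is held, not scheduled."""
        scheduled = []
        for key in sorted(self.entries):
            entry = self.entries[key]
            if entry.state not in (LedgerState.APPROVED, LedgerState.EDITED):
                continue
            committed = self._committed_total(key[0], exclude=key)
            if committed + entry.amount_final > self.total_cap:
                self.entries[key] = replace(
                    entry,
                    hold_reason=(
                        f"would raise participant total to "
                        f"{committed + entry.amount_final} cents, over the "
                        f"{self.total_cap}-cent cap"
                    ),
                )
                continue
            entry = entry._advance(LedgerState.SCHEDULED, at + self.delay)
            self.entries[key] = entry
            scheduled.append(entry)
        self.events.append(("schedule", at))
        return scheduled

    def mark_paid(self, at: dt.datetime) -> list[LedgerEntry]:
        """Confirm receipt of every scheduled transfer whose scheduled
        time has arrived."""
        paid = []
        for key in sorted(self.entries):
            entry = self.entries[key]
            if entry.state is not LedgerState.SCHEDULED:
                continue
            if at < entry.timestamp_of(LedgerState.SCHEDULED):
                continue
            entry = entry._advance(LedgerState.PAID, at)
            self.entries[key] = entry
            paid.append(entry)
        self.events.append(("paid", at))
        return paid

    # -- queries -----------------------------------------------------------

    def _committed_total(self, pid: str, exclude: tuple | None = None) -> int:
        """Cents already scheduled or paid for a participant."""
        return sum(
            e.amount_final for e in self.entries.values()
            if e.participant_id == pid and e.key != exclude
            and e.state in (LedgerState.SCHEDULED, LedgerState.PAID)
        )

    def total_paid(self, pid: str) -> int:
        return sum(
            e.amount_final for e in self.entries.values()
            if e.participant_id == pid and e.state is LedgerState.PAID
        )

    # -- event sourcing ----------------------------------------------------

    @classmethod
    def replay(
        cls,
        events: Iterable[tuple],
        total_cap: int = 30000,
        weekly_cap: int = 2800,
        delay: dt.timedelta = dt.timedelta(days=1),
    ) -> "Ledger":
        """Rebuild a ledger by re-running its event log."""
        ledger = cls(total_cap, weekly_cap, delay)
        for ev in events:
            kind = ev[0]
            if kind == "stage":
                _, pid, week, amount, at = ev
                ledger.stage(
                    [_StageStub(pid, week, amount)], at  # type: ignore[list-item]
                )
            elif kind == "review":
                _, pid, week, action, new_amount, at = ev
                ledger.review((pid, week), ReviewAction(action), at, new_amount)
            elif kind == "schedule":
                ledger.schedule_payments(ev[1])
            elif kind == "paid":
                ledger.mark_paid(ev[1])
            else:
                raise LedgerError(f"unknown event kind {kind!r}")
        return ledger

    # -- files -------------------------------------------------------------

    def apply_actions_csv(self, path: str | Path, at: dt.datetime) -> None:
        """Apply a staff review-actions file, all-or-nothing.

        Columns: participant_id, week, action, new_amount_cents (blank
        unless action is ``edit``).  Duplicate actions for one entry are
        a conflict; nothing is applied."""
        with Path(path).open(newline="") as fh:
            rows = list(csv.DictReader(fh))
        seen: set[tuple[str, int]] = set()
        parsed = []
        for row in rows:
            key = (row["participant_id"], int(row["week"]))
            if key in seen:
                raise LedgerError(f"conflicting duplicate actions for {key}")
            seen.add(key)
            raw_amount = (row.get("new_amount_cents") or "").strip()
            parsed.append((
                key,
                ReviewAction(row["action"]),
                int(raw_amount) if raw_amount else None,
            ))
        for key, action, new_amount in parsed:
            self.review(key, action, at, new_amount)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([
                "participant_id", "week", "amount_cents", "amount_final_cents",
                "state", "state_timestamps", "hold_reason",
            ])
            for key in sorted(self.entries):
                e = self.entries[key]
                stamps = ";".join(
                    f"{s.value}={t.isoformat()}" for s, t in e.state_timestamps
                )
                w.writerow([
                    e.participant_id, e.week, e.amount, e.amount_final,
                    e.state.value, stamps, e.hold_reason or "",
                ])


@dataclass(frozen=True)
class _StageStub:
    """Minimal result-shaped record used when replaying stage events."""

    participant_id: str
    week: int
    amount_earned: int
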