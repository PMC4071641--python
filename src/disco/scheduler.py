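"""Re-harvest scheduling: next-occurrence computation, due-task queue,
run history, and advisory source probing.

Supported frequencies: weekly (anchored to a day of week), biweekly
(every 14 days from an anchor date), monthly (day of month, days 29–31
clamped to the month's last day), and ad hoc (never due on its own).
All timestamps are naive and interpreted in one configured zone.
"""

from __future__ import annotations

import calendar
import os
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

from .errors import UsageError, ValidationError
from .scripts import parse_script
from .store import Store

FREQUENCIES = {"weekly", "biweekly", "monthly", "adhoc"}

_EPOCH = datetime(1970, 1, 1)


@dataclass(frozen=True)
class Schedule:
    resource_id: str
    frequency: str
    anchor: object | None          # weekday int | anchor date | day-of-month int
    time_of_day: time

    def __post_init__(self) -> None:
        if self.frequency not in FREQUENCIES:
            raise ValidationError(f"unknown frequency {self.frequency!r}")
        if self.frequency == "adhoc":
            if self.anchor is not None:
                raise ValidationError("ad hoc schedules take no anchor")
        elif self.frequency == "weekly":
            if not isinstance(self.anchor, int) or not 0 <= self.anchor <= 6:
                raise ValidationError("weekly anchor must be a weekday 0-6 (Mon=0)")
        elif self.frequency == "biweekly":
            if not isinstance(self.anchor, date) or isinstance(self.anchor, datetime):
                raise ValidationError("biweekly anchor must be a date")
        elif self.frequency == "monthly":
            if not isinstance(self.anchor, int) or not 1 <= self.anchor <= 31:
                raise ValidationError("monthly anchor must be a day of month 1-31")
        if self.time_of_day.second or self.time_of_day.microsecond:
            raise ValidationError("time_of_day has minute resolution")


def _clamped_monthly_day(year: int, month: int, anchor: int) -> int:
    return min(anchor, calendar.monthrange(year, month)[1])


def next_run(schedule: Schedule, after: datetime) -> datetime | None:
    """Smallest timestamp strictly after ``after`` matching the schedule."""
    if schedule.frequency == "adhoc":
        return None
    tod = schedule.time_of_day
    if schedule.frequency == "weekly":
        d = after.date()
        for _ in range(8):
            if d.weekday() == schedule.anchor:
                candidate = datetime.combine(d, tod)
                if candidate > after:
                    return candidate
            d += timedelta(days=1)
        raise AssertionError("unreachable")
    if schedule.frequency == "biweekly":
        d = after.date()
        for _ in range(15):
            if (d - schedule.anchor).days % 14 == 0:
                candidate = datetime.combine(d, tod)
                if candidate > after:
                    return candidate
            d += timedelta(days=1)
        raise AssertionError("unreachable")
    # monthly
    year, month = after.year, after.month
    for _ in range(3):
        day = _clamped_monthly_day(year, month, schedule.anchor)
        candidate = datetime.combine(date(year, month, day), tod)
        if candidate > after:
            return candidate
        month += 1
        if month == 13:
            year, month = year + 1, 1
    raise AssertionError("unreachable")


@dataclass
class QueueEntry:
    due_at: datetime | None
    resource_id: str
    state: str                  # due | manual | in_progress


class Scheduler:
    def __init__(self, store: Store, registry, lifecycle=None):
        self.store = store
        self.registry = registry
        self.lifecycle = lifecycle

    # -- schedule persistence -----------------------------------------

    def set_schedule(self, schedule: Schedule) -> None:
        self.registry.get(schedule.resource_id)
        if schedule.frequency == "biweekly":
            anchor = schedule.anchor.isoformat()
        elif schedule.anchor is None:
            anchor = None
        else:
            anchor = str(schedule.anchor)
        self.store.conn.execute(
            "INSERT OR REPLACE INTO schedules (resource_id, frequency, anchor,"
            " time_of_day) VALUES (?, ?, ?, ?)",
            (schedule.resource_id, schedule.frequency, anchor,
             schedule.time_of_day.strftime("%H:%M")),
        )
        self.store.conn.commit()

    def get_schedule(self, resource_id: str) -> Schedule | None:
        row = self.store.conn.execute(
            "SELECT * FROM schedules WHERE resource_id = ?", (resource_id,)
        ).fetchone()
        if row is None:
            return None
        freq = row["frequency"]
        anchor: object | None
        if freq == "biweekly":
            anchor = date.fromisoformat(row["anchor"])
        elif freq == "adhoc":
            anchor = None
        else:
            anchor = int(row["anchor"])
        hh, mm = row["time_of_day"].split(":")
        return Schedule(resource_id, freq, anchor, time(int(hh), int(mm)))

    def frequency_of(self, resource_id: str) -> str:
        sched = self.get_schedule(resource_id)
        return sched.frequency if sched else "adhoc"

    # -- queue ---------------------------------------------------------

    def _last_completed_run(self, resource_id: str) -> datetime | None:
        row = self.store.conn.execute(
            "SELECT finished_at FROM runs WHERE resource_id = ?"
            " ORDER BY id DESC LIMIT 1",
            (resource_id,),
        ).fetchone()
        return datetime.fromisoformat(row["finished_at"]) if row else None

    def trigger(self, resource_id: str, now: datetime) -> None:
        """Queue a manual (ad hoc) run for the next tick."""
        self.registry.get(resource_id)
        self.store.conn.execute(
            "INSERT OR REPLACE INTO manual_queue (resource_id, requested_at)"
            " VALUES (?, ?)",
            (resource_id, now.isoformat()),
        )
        self.store.conn.commit()

    def due_tasks(self, now: datetime) -> list[QueueEntry]:
        """Snapshot of everything due, manually queued, or running."""
        entries: list[QueueEntry] = []
        in_progress = {
            r["resource_id"]: r["since"]
            for r in self.store.conn.execute("SELECT * FROM in_progress")
        }
        manual = {
            r["resource_id"]: datetime.fromisoformat(r["requested_at"])
            for r in self.store.conn.execute("SELECT * FROM manual_queue")
        }
        for res in self.registry.list_resources().items:
            if "interop" not in res.services or not res.active:
                continue
            rid = res.nif_id
            if rid in in_progress:
                entries.append(QueueEntry(None, rid, "in_progress"))
                continue
            if rid in manual:
                entries.append(QueueEntry(manual[rid], rid, "manual"))
                continue
            sched = self.get_schedule(rid)
            if sched is None or sched.frequency == "adhoc":
                continue
            base = self._last_completed_run(rid)
            # naive comparison: strip any timezone from recorded run stamps
            if base is not None and base.tzinfo is not None:
                base = base.replace(tzinfo=None)
            due = next_run(sched, base if base is not None else _EPOCH)
            if due is not None and due <= now:
                entries.append(QueueEntry(due, rid, "due"))
        entries.sort(key=lambda e: (e.due_at or datetime.min, e.resource_id))
        return entries

    def tick(self, now: datetime) -> list[dict]:
        """Execute all due tasks synchronously; clears manual triggers."""
        if self.lifecycle is None:
            raise UsageError("scheduler has no lifecycle to execute runs")
        results = []
        for entry in self.due_tasks(now):
            if entry.state == "in_progress":
                continue
            run = self.lifecycle.run_update(entry.resource_id)
            self.store.conn.execute(
                "DELETE FROM manual_queue WHERE resource_id = ?",
                (entry.resource_id,),
            )
            self.store.conn.commit()
            results.append({"resource_id": entry.resource_id, "outcome": run.outcome})
        return results

    # -- probing -------------------------------------------------------

    def probe_source(self, resource_id: str) -> str:
        """Advisory change hint from source size/timestamp vs last fetch."""
        res = self.registry.get(resource_id)
        try:
            script = parse_script(res.script_locator)
        except Exception:
            return "unknown"
        hints = []
        for src in script.sources:
            row = self.store.conn.execute(
                "SELECT * FROM fetch_meta WHERE locator = ?", (src.locator,)
            ).fetchone()
            if row is None:
                hints.append("unknown")
                continue
            if "://" in src.locator:
                hints.append("unknown")
                continue
            try:
                st = os.stat(src.locator)
            except OSError:
                hints.append("unknown")
                continue
            if st.st_size != row["size"]:
                hints.append("likely_changed")
            elif row["mtime"] is not None and st.st_mtime != row["mtime"]:
                hints.append("likely_changed")
            else:
                hints.append("likely_unchanged")
        if "likely_changed" in hints:
            return "likely_changed"
        if hints and all(h == "likely_unchanged" for h in hints):
            return "likely_unchanged"
        return "unknown"
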