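"""The data-source lifecycle: run updates, hold pending versions for
curation, gate promotion on unresolved import issues, cascade views.

Status machine::

    (run) ──unchanged──▶ recorded, no version created
    (run) ──changes────▶ pending ──approve──▶ production  (immediate)
                          │  │                 ▲
                          │  └─approve --batch─▶ scheduled ──flush──┘
                          └──problem──▶ problem  (kept for debugging)

At most one version per resource+service is in {pending, approved,
scheduled} at any time; a run while one is in flight is refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Callable

from .errors import ConflictError, DiscoError, NotFoundError, UsageError
from .registry import Registry
from .scripts import coerce_records, extract_records, fetch_source, parse_script
from .staging import ImportIssue, Staging, summarize_changes
from .store import Store
from .version_store import VersionStore

BLOCKING_KINDS = ("data_type_error", "duplicate_key", "field_overflow", "incomplete_import")


@dataclass
class RunRecord:
    id: int
    resource_id: str
    started_at: str
    finished_at: str
    outcome: str               # unchanged | new_pending | failed
    staged_id: int | None
    issue_counts: dict[str, int]
    error: str | None = None
    import_mode: str | None = None


def _issue_counts(issues: list[ImportIssue]) -> dict[str, int]:
    counts = {k: 0 for k in BLOCKING_KINDS}
    for issue in issues:
        counts[issue.kind] += 1
    return counts


class Lifecycle:
    def __init__(
        self,
        store: Store,
        registry: Registry,
        staging: Staging,
        versions: VersionStore,
        views=None,
        clock: Callable[[], datetime] | None = None,
    ):
        self.store = store
        self.registry = registry
        self.staging = staging
        self.versions = versions
        self.views = views
        self.clock = clock or (lambda: datetime.now(timezone.utc))

    def _now(self) -> str:
        return self.clock().isoformat()

    def _append_run(self, resource_id, started_at, outcome, staged_id,
                    issue_counts, error=None, import_mode=None) -> RunRecord:
        finished_at = self._now()
        cur = self.store.conn.execute(
            "INSERT INTO runs (resource_id, started_at, finished_at, outcome,"
            " staged_id, issue_counts, error, import_mode)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            (resource_id, started_at, finished_at, outcome, staged_id,
             json.dumps(issue_counts), error, import_mode),
        )
        self.store.audit(finished_at, resource_id, f"run_{outcome}",
                         {"staged_id": staged_id, "error": error})
        self.store.conn.commit()
        return RunRecord(cur.lastrowid, resource_id, started_at, finished_at,
                         outcome, staged_id, issue_counts, error, import_mode)

    # -- update runs ---------------------------------------------------

    def run_update(self, resource_id: str, import_mode: str = "Update") -> RunRecord:
        """Fetch → extract → coerce → stage → diff for one resource.

        An empty changeset is recorded as ``unchanged`` and the staged
        relation discarded; otherwise the version is held pending with
        its change summary attached.  Failures never touch production.
        """
        resource = self.registry.get(resource_id)
        if "interop" not in resource.services:
            raise UsageError(f"resource {resource_id!r} has no interop service")
        if self.staging.in_flight(resource_id) is not None:
            raise ConflictError(
                f"resource {resource_id!r} has a version awaiting curation;"
                " refusing a new run"
            )
        started_at = self._now()
        self.store.conn.execute(
            "INSERT OR REPLACE INTO in_progress (resource_id, since) VALUES (?, ?)",
            (resource_id, started_at),
        )
        self.store.conn.commit()
        try:
            try:
                script = parse_script(resource.script_locator)
                fetches = [fetch_source(s) for s in script.sources]
                for f in fetches:
                    self.store.conn.execute(
                        "INSERT OR REPLACE INTO fetch_meta"
                        " (locator, fetched_at, size, mtime) VALUES (?, ?, ?, ?)",
                        (f.locator, f.fetched_at.isoformat(), f.size, f.mtime),
                    )
                records = extract_records(script, [f.content for f in fetches])
                _typed, coercion_issues = coerce_records(script, records)
                issues = [
                    ImportIssue(c.kind, c.record_locator, c.field, c.message)
                    for c in coercion_issues
                ]
                staged = self.staging.stage_ingest(
                    resource_id, script, records, issues
                )
                changeset = self.staging.compute_changes(staged, script)
            except DiscoError as exc:
                return self._append_run(
                    resource_id, started_at, "failed", None,
                    _issue_counts([]), error=str(exc), import_mode=import_mode,
                )
            if changeset.is_empty and not staged.issues:
                self.store.drop_relation(staged.relation)
                self.store.conn.execute(
                    "DELETE FROM staged_versions WHERE id = ?", (staged.id,)
                )
                self.store.conn.commit()
                return self._append_run(
                    resource_id, started_at, "unchanged", None,
                    _issue_counts([]), import_mode=import_mode,
                )
            self.staging.attach_changeset(staged.id, changeset)
            return self._append_run(
                resource_id, started_at, "new_pending", staged.id,
                _issue_counts(staged.issues), import_mode=import_mode,
            )
        finally:
            self.store.conn.execute(
                "DELETE FROM in_progress WHERE resource_id = ?", (resource_id,)
            )
            self.store.conn.commit()

    # -- curation ------------------------------------------------------

    def _pending(self, resource_id: str):
        staged = self.staging.in_flight(resource_id)
        if staged is None or staged.status != "pending":
            raise NotFoundError(f"nothing pending for resource {resource_id!r}")
        return staged

    def review(self, resource_id: str) -> dict:
        """Read-only pending summary for curators."""
        staged = self._pending(resource_id)
        changeset = self.staging.get_changeset(staged.id)
        summary = summarize_changes(changeset) if changeset else None
        return {
            "resource_id": resource_id,
            "staged_version": staged.version_number,
            "record_count": staged.record_count,
            "created_at": staged.created_at,
            "status": staged.status,
            "issues": _issue_counts(staged.issues),
            "issue_details": [i.to_json() for i in staged.issues],
            "changes": summary,
            "note": self._staged_note(staged.id),
        }

    def _staged_note(self, staged_id: int) -> str | None:
        row = self.store.conn.execute(
            "SELECT note FROM staged_versions WHERE id = ?", (staged_id,)
        ).fetchone()
        return row["note"] if row else None

    def approve(self, resource_id: str, mode: str = "immediate",
                override: bool = False) -> str:
        """Approve the pending version for promotion.

        Any unresolved import issue blocks approval unless ``override``
        is set (the override is logged in the audit trail).
        """
        if mode not in ("immediate", "batch"):
            raise UsageError(f"unknown approval mode {mode!r}")
        staged = self._pending(resource_id)
        counts = _issue_counts(staged.issues)
        blocking = {k: n for k, n in counts.items() if n}
        if blocking and not override:
            raise UsageError(
                f"approval refused for {resource_id!r}: unresolved issues {blocking}"
            )
        if blocking:
            self.store.audit(self._now(), resource_id, "approve_override",
                             {"issues": blocking})
        if mode == "batch":
            self.staging.set_status(staged.id, "scheduled")
            self.store.audit(self._now(), resource_id, "approved_batch",
                             {"staged_id": staged.id})
            self.store.conn.commit()
            return "scheduled"
        self.staging.set_status(staged.id, "approved")
        self.store.audit(self._now(), resource_id, "approved",
                         {"staged_id": staged.id})
        self.store.conn.commit()
        self._promote(staged.id)
        return "production"

    def _promote(self, staged_id: int) -> int:
        staged = self.staging.get_staged(staged_id)
        changeset = self.staging.get_changeset(staged_id)
        script = parse_script(self.registry.get(staged.resource_id).script_locator)
        version = self.versions.promote(staged, changeset, script)
        self.staging.set_status(staged_id, "production")
        self.store.audit(self._now(), staged.resource_id, "promoted",
                         {"version": version})
        self.store.conn.commit()
        self.cascade_views(staged.resource_id)
        return version

    def flush_batch(self) -> list[str]:
        """Promote every batch-scheduled version, in resource order."""
        rows = self.store.conn.execute(
            "SELECT id, resource_id FROM staged_versions WHERE status = 'scheduled'"
            " ORDER BY resource_id"
        ).fetchall()
        promoted = []
        for row in rows:
            self._promote(row["id"])
            promoted.append(row["resource_id"])
        return promoted

    def mark_problem(self, resource_id: str, note: str) -> None:
        staged = self._pending(resource_id)
        self.staging.set_status(staged.id, "problem", note=note)
        self.store.audit(self._now(), resource_id, "marked_problem", {"note": note})
        self.store.notify(self._now(), "curators", resource_id,
                          f"problem recorded on staged version {staged.version_number}: {note}")
        self.store.conn.commit()

    # -- view cascade --------------------------------------------------

    def cascade_views(self, resource_id: str) -> list[str]:
        """Re-materialize the beta channel of every view using this resource."""
        if self.views is None:
            return []
        regenerated = []
        for view_name in self.views.views_referencing(resource_id):
            try:
                self.views.materialize_view(view_name, "beta")
            except DiscoError as exc:
                self.views.flag_failed(view_name, str(exc))
                self.store.notify(self._now(), "curators", resource_id,
                                  f"view {view_name!r} failed to rebuild: {exc}")
                continue
            regenerated.append(view_name)
            now = self._now()
            self.store.notify(now, "curators", resource_id,
                              f"view {view_name!r} rebuilt on beta channel")
            self.store.notify(now, "resource_contacts", resource_id,
                              f"your data now feeds a new beta of view {view_name!r}")
        self.store.conn.commit()
        return regenerated

    # -- history -------------------------------------------------------

    def runs(self, resource_id: str, limit: int | None = None) -> list[RunRecord]:
        sql = ("SELECT * FROM runs WHERE resource_id = ? ORDER BY id DESC")
        rows = self.store.conn.execute(sql, (resource_id,)).fetchall()
        if limit is not None:
            rows = rows[:limit]
        return [
            RunRecord(r["id"], r["resource_id"], r["started_at"], r["finished_at"],
                      r["outcome"], r["staged_id"], json.loads(r["issue_counts"]),
                      r["error"], r["import_mode"])
            for r in rows
        ]
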