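"""Staging: record identity, temporary ingest relations, change detection.

Records are identified either by the script's declared primary key or —
for unstructured resources with no key — by a digest of the whole record.
Change detection compares staged content to the production relation by
identity and classifies every record as added, deleted, modified, or
unchanged.  Field comparison is exact string equality on raw values; a
missing field and an empty string are different states.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable

from .errors import ConflictError
from .scripts import HarvestScript, Record
from .store import Store

ISSUE_KINDS = {"data_type_error", "duplicate_key", "field_overflow", "incomplete_import"}

_SEP = "\x1f"   # unit separator: unprintable, cannot appear in field names


@dataclass(frozen=True, order=True)
class RecordKey:
    """Identity of a record: PK value tuple or content digest."""

    kind: str          # "pk" | "digest"
    values: tuple

    @classmethod
    def from_pk(cls, values: tuple) -> "RecordKey":
        return cls("pk", tuple(values))

    @classmethod
    def from_digest(cls, digest: str) -> "RecordKey":
        return cls("digest", (digest,))

    def to_json(self) -> list:
        return [self.kind, list(self.values)]

    @classmethod
    def from_json(cls, data: list) -> "RecordKey":
        return cls(data[0], tuple(data[1]))


class MissingKeyValue(Exception):
    """Raised when a PK field is missing or empty; callers convert this
    into a data_type_error issue and quarantine the record."""

    def __init__(self, field_name: str):
        super().__init__(f"primary key field {field_name!r} missing or empty")
        self.field_name = field_name


def content_digest(record: Record) -> str:
    """SHA-256 over ``name=value`` pairs sorted by field name.

    Missing fields are omitted, so the digest is invariant under field
    reordering but sensitive to every present byte.
    """
    parts = [f"{name}={record[name]}" for name in sorted(record)]
    return hashlib.sha256(_SEP.join(parts).encode("utf-8")).hexdigest()


def record_key(script: HarvestScript, record: Record) -> RecordKey:
    if script.primary_key:
        values = []
        for fname in script.primary_key:
            value = record.get(fname)
            if value is None or value == "":
                raise MissingKeyValue(fname)
            values.append(value)
        return RecordKey.from_pk(tuple(values))
    return RecordKey.from_digest(content_digest(record))


@dataclass
class ImportIssue:
    kind: str
    record_locator: str
    field: str | None
    message: str

    def __post_init__(self) -> None:
        if self.kind not in ISSUE_KINDS:
            raise ValueError(f"unknown issue kind {self.kind!r}")

    def to_json(self) -> dict:
        return {
            "kind": self.kind, "record_locator": self.record_locator,
            "field": self.field, "message": self.message,
        }

    @classmethod
    def from_json(cls, data: dict) -> "ImportIssue":
        return cls(data["kind"], data["record_locator"], data["field"], data["message"])


@dataclass
class ChangeSet:
    added: set[RecordKey] = field(default_factory=set)
    deleted: set[RecordKey] = field(default_factory=set)
    modified: dict[RecordKey, list[tuple[str, str | None, str | None]]] = field(
        default_factory=dict
    )
    unchanged_count: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.added and not self.deleted and not self.modified

    @property
    def n_changes(self) -> int:
        return len(self.added) + len(self.deleted) + len(self.modified)

    def field_change_count(self) -> int:
        return sum(len(v) for v in self.modified.values())

    def to_json(self) -> dict:
        return {
            "added": [k.to_json() for k in sorted(self.added)],
            "deleted": [k.to_json() for k in sorted(self.deleted)],
            "modified": [
                [k.to_json(), [list(e) for e in entries]]
                for k, entries in sorted(self.modified.items())
            ],
            "unchanged_count": self.unchanged_count,
        }

    @classmethod
    def from_json(cls, data: dict) -> "ChangeSet":
        return cls(
            added={RecordKey.from_json(k) for k in data["added"]},
            deleted={RecordKey.from_json(k) for k in data["deleted"]},
            modified={
                RecordKey.from_json(k): [tuple(e) for e in entries]
                for k, entries in data["modified"]
            },
            unchanged_count=data["unchanged_count"],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChangeSet):
            return NotImplemented
        return (
            self.added == other.added
            and self.deleted == other.deleted
            and self.modified == other.modified
            and self.unchanged_count == other.unchanged_count
        )


@dataclass
class StagedVersion:
    id: int
    resource_id: str
    service: str
    version_number: int
    base_version: int
    relation: str
    record_count: int
    created_at: str
    status: str
    issues: list[ImportIssue]


def staged_relation_name(nif_id: str, table: str, version: int) -> str:
    return f"{nif_id}_{table}_v{version}_tmp"


def production_relation_name(nif_id: str, table: str) -> str:
    return f"{nif_id}_{table}"


def diff_records(
    staged: dict[RecordKey, Record], production: dict[RecordKey, Record]
) -> ChangeSet:
    """Classify staged vs production records by identity.

    Modified entries are (field, old, new) triples sorted by field name,
    with ``None`` standing for a missing field.
    """
    cs = ChangeSet()
    for key, new_rec in staged.items():
        if key not in production:
            cs.added.add(key)
            continue
        old_rec = production[key]
        entries: list[tuple[str, str | None, str | None]] = []
        for fname in sorted(set(old_rec) | set(new_rec)):
            old_v = old_rec.get(fname)
            new_v = new_rec.get(fname)
            if old_v != new_v:
                entries.append((fname, old_v, new_v))
        if entries:
            cs.modified[key] = entries
        else:
            cs.unchanged_count += 1
    for key in production:
        if key not in staged:
            cs.deleted.add(key)
    return cs


def key_records(
    script: HarvestScript, records: list[Record]
) -> tuple[dict[RecordKey, Record], list[ImportIssue]]:
    """Key a record list, quarantining unkeyable rows and duplicates.

    First occurrence of a duplicate key is kept; later occurrences are
    reported as duplicate_key issues.
    """
    keyed: dict[RecordKey, Record] = {}
    issues: list[ImportIssue] = []
    for i, rec in enumerate(records):
        locator = f"record[{i}]"
        try:
            key = record_key(script, rec)
        except MissingKeyValue as exc:
            issues.append(
                ImportIssue("data_type_error", locator, exc.field_name, str(exc))
            )
            continue
        if key in keyed:
            issues.append(
                ImportIssue(
                    "duplicate_key", locator, None,
                    f"duplicate key {key.values!r}; first occurrence kept",
                )
            )
            continue
        keyed[key] = rec
    return keyed, issues


class Staging:
    def __init__(self, store: Store, clock: Callable[[], datetime] | None = None):
        self.store = store
        self.clock = clock or (lambda: datetime.now(timezone.utc))

    def in_flight(self, resource_id: str, service: str = "interop") -> StagedVersion | None:
        cur = self.store.conn.execute(
            "SELECT * FROM staged_versions WHERE resource_id = ? AND service = ?"
            " AND status IN ('pending', 'approved', 'scheduled')"
            " ORDER BY id DESC LIMIT 1",
            (resource_id, service),
        )
        row = cur.fetchone()
        return self._row_to_staged(row) if row else None

    @staticmethod
    def _row_to_staged(row) -> StagedVersion:
        return StagedVersion(
            id=row["id"],
            resource_id=row["resource_id"],
            service=row["service"],
            version_number=row["version_number"],
            base_version=row["base_version"],
            relation=row["relation"],
            record_count=row["record_count"],
            created_at=row["created_at"],
            status=row["status"],
            issues=[ImportIssue.from_json(i) for i in json.loads(row["issues"])],
        )

    def get_staged(self, staged_id: int) -> StagedVersion:
        row = self.store.conn.execute(
            "SELECT * FROM staged_versions WHERE id = ?", (staged_id,)
        ).fetchone()
        if row is None:
            raise KeyError(staged_id)
        return self._row_to_staged(row)

    def current_production_version(self, resource_id: str, service: str = "interop") -> int:
        cur = self.store.conn.execute(
            "SELECT version FROM production WHERE resource_id = ? AND service = ?",
            (resource_id, service),
        )
        row = cur.fetchone()
        return row["version"] if row else 0

    def stage_ingest(
        self,
        resource_id: str,
        script: HarvestScript,
        records: list[Record],
        issues: list[ImportIssue] | None = None,
        service: str = "interop",
        _fail_after_rows: int | None = None,
    ) -> StagedVersion:
        """Write records into a fresh temporary relation.

        Duplicate keys are detected here (first kept, rest quarantined).
        A storage failure mid-write leaves a staged version carrying an
        incomplete_import issue rather than raising.
        """
        if self.in_flight(resource_id, service) is not None:
            raise ConflictError(
                f"resource {resource_id!r} already has an in-flight staged version"
            )
        all_issues = list(issues or [])
        keyed, key_issues = key_records(script, records)
        all_issues.extend(key_issues)
        base_version = self.current_production_version(resource_id, service)
        version_number = base_version + 1
        relation = staged_relation_name(resource_id, script.table_name, version_number)
        self.store.create_relation(relation, script.field_names)
        written = 0
        try:
            for rec in keyed.values():
                if _fail_after_rows is not None and written >= _fail_after_rows:
                    raise OSError("simulated storage failure")
                self.store.append_row(relation, rec)
                written += 1
        except OSError as exc:
            all_issues.append(
                ImportIssue(
                    "incomplete_import", f"record[{written}]", None,
                    f"data import failed to complete: {exc}",
                )
            )
        created_at = self.clock().isoformat()
        cur = self.store.conn.execute(
            "INSERT INTO staged_versions"
            " (resource_id, service, version_number, base_version, relation,"
            "  record_count, created_at, status, issues)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, 'pending', ?)",
            (
                resource_id, service, version_number, base_version, relation,
                written, created_at,
                json.dumps([i.to_json() for i in all_issues]),
            ),
        )
        self.store.conn.commit()
        return StagedVersion(
            id=cur.lastrowid,
            resource_id=resource_id,
            service=service,
            version_number=version_number,
            base_version=base_version,
            relation=relation,
            record_count=written,
            created_at=created_at,
            status="pending",
            issues=all_issues,
        )

    def compute_changes(
        self, staged: StagedVersion, script: HarvestScript, service: str = "interop"
    ) -> ChangeSet:
        """Diff the staged relation against current production content."""
        staged_rows = self.store.read_rows(staged.relation)
        cur = self.store.conn.execute(
            "SELECT relation FROM production WHERE resource_id = ? AND service = ?",
            (staged.resource_id, service),
        )
        row = cur.fetchone()
        prod_rows = self.store.read_rows(row["relation"]) if row else []
        staged_map = {record_key(script, r): r for r in staged_rows}
        prod_map = {record_key(script, r): r for r in prod_rows}
        return diff_records(staged_map, prod_map)

    def set_status(self, staged_id: int, status: str, note: str | None = None) -> None:
        if note is not None:
            self.store.conn.execute(
                "UPDATE staged_versions SET status = ?, note = ? WHERE id = ?",
                (status, note, staged_id),
            )
        else:
            self.store.conn.execute(
                "UPDATE staged_versions SET status = ? WHERE id = ?",
                (status, staged_id),
            )
        self.store.conn.commit()

    def attach_changeset(self, staged_id: int, changeset: ChangeSet) -> None:
        self.store.conn.execute(
            "UPDATE staged_versions SET changeset = ? WHERE id = ?",
            (json.dumps(changeset.to_json()), staged_id),
        )
        self.store.conn.commit()

    def get_changeset(self, staged_id: int) -> ChangeSet | None:
        row = self.store.conn.execute(
            "SELECT changeset FROM staged_versions WHERE id = ?", (staged_id,)
        ).fetchone()
        if row is None or row["changeset"] is None:
            return None
        return ChangeSet.from_json(json.loads(row["changeset"]))


def summarize_changes(changeset: ChangeSet, max_samples: int = 5) -> dict:
    """Curator-facing summary: exact counts plus deterministic samples."""

    def _samples(keys) -> list:
        return [k.to_json() for k in sorted(keys)[:max_samples]]

    modified_samples = [
        {"key": k.to_json(), "changes": [list(e) for e in entries]}
        for k, entries in sorted(changeset.modified.items())[:max_samples]
    ]
    return {
        "added": len(changeset.added),
        "deleted": len(changeset.deleted),
        "modified": len(changeset.modified),
        "unchanged": changeset.unchanged_count,
        "is_unchanged": changeset.is_empty,
        "samples": {
            "added": _samples(changeset.added),
            "deleted": _samples(changeset.deleted),
            "modified": modified_samples,
        },
    }
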