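"""Concurrent-versioning back-end over an entity–attribute–value layout.

The production relation always holds the newest version in full; each
promotion writes *reverse* data deltas that transform version v+1 back
into version v, and *forward* schema deltas that replay the structural
history from version 1.  When a promotion rewrites more than half of the
production relation, a full snapshot of the old version is stored instead
of deltas — reconstruction then restarts from the nearest snapshot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Callable

from .errors import ConflictError, IntegrityError, NotFoundError, UsageError
from .scripts import HarvestScript, Record, script_from_dict
from .staging import ChangeSet, RecordKey, StagedVersion, production_relation_name, record_key
from .store import Store, canonical_row_key

SNAPSHOT_THRESHOLD = 0.5   # change_fraction above this stores a full copy

DATA_OPS = {"set_field", "restore_record", "remove_record"}
SCHEMA_OPS = {"add_column", "drop_column", "rename_column", "change_type"}


@dataclass(frozen=True)
class DataDelta:
    resource_id: str
    to_version: int
    entity: RecordKey
    op: str
    attribute: str | None = None
    value: object = None     # prior raw value (set_field) or prior record


@dataclass(frozen=True)
class SchemaDelta:
    resource_id: str
    from_version: int
    op: str
    payload: tuple

    def to_json(self) -> list:
        return [self.op, list(self.payload)]


Schema = list   # ordered [name, declared_type] pairs


def record_schema_change(
    old_schema: Schema, new_schema: Schema,
    declared_renames: dict[str, str] | None = None,
    resource_id: str = "", from_version: int = 0,
) -> list[SchemaDelta]:
    """Minimal forward edit script between two ordered schemas.

    Renames are emitted only when declared (never inferred from data);
    everything else is expressed as drop/add/change_type.
    """
    renames = declared_renames or {}
    old_cols = {name: dtype for name, dtype in old_schema}
    new_cols = {name: dtype for name, dtype in new_schema}
    deltas: list[SchemaDelta] = []

    def emit(op: str, payload: tuple) -> None:
        deltas.append(SchemaDelta(resource_id, from_version, op, payload))

    renamed_olds = set()
    for old_name in [n for n, _ in old_schema]:
        new_name = renames.get(old_name)
        if new_name and old_name in old_cols and new_name in new_cols \
                and old_name not in new_cols:
            emit("rename_column", (old_name, new_name))
            renamed_olds.add(old_name)
    effective_old = {}
    for name, dtype in old_schema:
        effective_old[renames[name] if name in renamed_olds else name] = dtype
    for name in [n for n, _ in old_schema]:
        eff = renames[name] if name in renamed_olds else name
        if eff not in new_cols:
            emit("drop_column", (eff,))
    for name, dtype in new_schema:
        if name not in effective_old:
            emit("add_column", (name, dtype))
    for name, dtype in new_schema:
        if name in effective_old and effective_old[name] != dtype:
            emit("change_type", (name, effective_old[name], dtype))
    return deltas


def apply_schema_deltas(schema: Schema, deltas: list[SchemaDelta]) -> Schema:
    cols = [list(pair) for pair in schema]
    for d in deltas:
        if d.op == "rename_column":
            old, new = d.payload
            for c in cols:
                if c[0] == old:
                    c[0] = new
        elif d.op == "drop_column":
            cols = [c for c in cols if c[0] != d.payload[0]]
        elif d.op == "add_column":
            cols.append([d.payload[0], d.payload[1]])
        elif d.op == "change_type":
            name, _old_t, new_t = d.payload
            for c in cols:
                if c[0] == name:
                    c[1] = new_t
        else:
            raise IntegrityError(f"unknown schema op {d.op!r}")
    return [list(c) for c in cols]


class VersionStore:
    def __init__(self, store: Store, clock: Callable[[], datetime] | None = None):
        self.store = store
        self.clock = clock or (lambda: datetime.now(timezone.utc))

    # -- queries -------------------------------------------------------

    def production_row(self, resource_id: str, service: str = "interop"):
        return self.store.conn.execute(
            "SELECT * FROM production WHERE resource_id = ? AND service = ?",
            (resource_id, service),
        ).fetchone()

    def current_version(self, resource_id: str, service: str = "interop") -> int:
        row = self.production_row(resource_id, service)
        return row["version"] if row else 0

    def production_rows(self, resource_id: str, service: str = "interop") -> list[Record]:
        row = self.production_row(resource_id, service)
        if row is None:
            return []
        return self.store.read_rows(row["relation"])

    def production_schema(self, resource_id: str, service: str = "interop") -> Schema | None:
        row = self.production_row(resource_id, service)
        return json.loads(row["schema"]) if row else None

    def production_script(self, resource_id: str, service: str = "interop") -> HarvestScript | None:
        row = self.production_row(resource_id, service)
        return script_from_dict(json.loads(row["script"])) if row else None

    # -- promotion -----------------------------------------------------

    def promote(
        self,
        staged: StagedVersion,
        changeset: ChangeSet,
        script: HarvestScript,
        service: str = "interop",
    ) -> int:
        """Replace production with the staged content, atomically.

        Reverse deltas (or a full snapshot of the old version, when the
        change fraction exceeds the threshold) are written so the prior
        version remains reconstructible.
        """
        if changeset.is_empty:
            raise UsageError("refusing to promote an unchanged version")
        resource_id = staged.resource_id
        prod = self.production_row(resource_id, service)
        current = prod["version"] if prod else 0
        if staged.base_version != current:
            raise ConflictError(
                f"stale changeset: staged against version {staged.base_version},"
                f" production is at {current}"
            )
        new_version = current + 1
        new_schema = script.schema()
        staged_rows = self.store.read_rows(staged.relation)
        prod_relation = production_relation_name(resource_id, script.table_name)
        conn = self.store.conn
        conn.commit()   # flush any autocommit backlog so rollback is scoped
        try:
            if current >= 1:
                old_rows = self.store.read_rows(prod["relation"])
                old_schema = json.loads(prod["schema"])
                change_fraction = changeset.n_changes / max(len(old_rows), 1)
                if change_fraction > SNAPSHOT_THRESHOLD:
                    conn.execute(
                        "INSERT OR REPLACE INTO snapshots"
                        " (resource_id, service, version, rows, schema)"
                        " VALUES (?, ?, ?, ?, ?)",
                        (
                            resource_id, service, current,
                            json.dumps(sorted(old_rows, key=canonical_row_key),
                                       ensure_ascii=False),
                            json.dumps(old_schema),
                        ),
                    )
                else:
                    self._write_reverse_deltas(
                        conn, resource_id, service, current, changeset,
                        {record_key(script, r): r for r in old_rows},
                    )
                for sd in record_schema_change(
                    old_schema, new_schema, script.renames(),
                    resource_id, from_version=current,
                ):
                    conn.execute(
                        "INSERT INTO schema_deltas"
                        " (resource_id, service, from_version, op, payload)"
                        " VALUES (?, ?, ?, ?, ?)",
                        (resource_id, service, current, sd.op, json.dumps(list(sd.payload))),
                    )
                base_schema = prod["base_schema"]
                if prod["relation"] != prod_relation:
                    self.store.drop_relation(prod["relation"])
            else:
                base_schema = json.dumps(new_schema)
            self.store.create_relation(prod_relation, script.field_names)
            self.store.write_rows(prod_relation, staged_rows)
            promoted_at = self.clock().isoformat()
            conn.execute(
                "INSERT OR REPLACE INTO production"
                " (resource_id, service, version, relation, schema, base_schema,"
                "  script, promoted_at)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    resource_id, service, new_version, prod_relation,
                    json.dumps(new_schema), base_schema,
                    json.dumps(script.to_dict()), promoted_at,
                ),
            )
            conn.execute(
                "INSERT INTO promotions"
                " (resource_id, service, version, promoted_at, record_count,"
                "  n_added, n_deleted, n_modified)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    resource_id, service, new_version, promoted_at,
                    len(staged_rows), len(changeset.added), len(changeset.deleted),
                    len(changeset.modified),
                ),
            )
            conn.commit()
        except BaseException:
            conn.rollback()
            raise
        self.store.drop_relation(staged.relation)
        self.store.conn.commit()
        return new_version

    @staticmethod
    def _write_reverse_deltas(
        conn, resource_id: str, service: str, to_version: int,
        changeset: ChangeSet, old_map: dict[RecordKey, Record],
    ) -> None:
        def insert(entity: RecordKey, op: str, attribute=None, value=None):
            conn.execute(
                "INSERT INTO data_deltas"
                " (resource_id, service, to_version, entity, op, attribute, value)"
                " VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    resource_id, service, to_version,
                    json.dumps(entity.to_json()), op, attribute,
                    json.dumps(value, ensure_ascii=False),
                ),
            )

        for key in sorted(changeset.modified):
            for fname, old_value, _new_value in changeset.modified[key]:
                insert(key, "set_field", attribute=fname, value=old_value)
        for key in sorted(changeset.deleted):
            insert(key, "restore_record", value=old_map[key])
        for key in sorted(changeset.added):
            insert(key, "remove_record")

    # -- reconstruction ------------------------------------------------

    def _deltas_for(self, resource_id: str, service: str, to_version: int) -> list:
        return self.store.conn.execute(
            "SELECT * FROM data_deltas WHERE resource_id = ? AND service = ?"
            " AND to_version = ? ORDER BY id",
            (resource_id, service, to_version),
        ).fetchall()

    def _snapshot_for(self, resource_id: str, service: str, version: int):
        return self.store.conn.execute(
            "SELECT rows FROM snapshots WHERE resource_id = ? AND service = ?"
            " AND version = ?",
            (resource_id, service, version),
        ).fetchone()

    def reconstruct_version(
        self, resource_id: str, v: int, service: str = "interop"
    ) -> tuple[list[Record], Schema]:
        """Rebuild the relation and schema exactly as they stood at v."""
        prod = self.production_row(resource_id, service)
        if prod is None:
            raise NotFoundError(f"resource {resource_id!r} has no versions")
        current = prod["version"]
        if not (1 <= v <= current):
            raise NotFoundError(
                f"version {v} out of range for {resource_id!r} (1..{current})"
            )
        script = script_from_dict(json.loads(prod["script"]))
        rows = self.store.read_rows(prod["relation"])
        working = {record_key(script, r): r for r in rows}
        for version in range(current - 1, v - 1, -1):
            snap = self._snapshot_for(resource_id, service, version)
            if snap is not None:
                snap_rows = json.loads(snap["rows"])
                working = {record_key(script, r): r for r in snap_rows}
                continue
            deltas = self._deltas_for(resource_id, service, version)
            if not deltas and version != current:
                # a legitimately empty delta set can only mean the data part
                # of that promotion was schema-only; verify the chain exists
                pass
            for d in deltas:
                entity = RecordKey.from_json(json.loads(d["entity"]))
                op = d["op"]
                if op == "set_field":
                    if entity not in working:
                        raise IntegrityError(
                            f"set_field delta targets unknown entity {entity}"
                        )
                    old_value = json.loads(d["value"])
                    if old_value is None:
                        working[entity].pop(d["attribute"], None)
                    else:
                        working[entity][d["attribute"]] = old_value
                elif op == "restore_record":
                    working[entity] = json.loads(d["value"])
                elif op == "remove_record":
                    if entity not in working:
                        raise IntegrityError(
                            f"remove_record delta targets unknown entity {entity}"
                        )
                    del working[entity]
                else:
                    raise IntegrityError(f"unknown delta op {op!r}")
        schema = self.schema_at(resource_id, v, service)
        out = sorted(working.values(), key=canonical_row_key)
        return out, schema

    def schema_at(self, resource_id: str, v: int, service: str = "interop") -> Schema:
        prod = self.production_row(resource_id, service)
        if prod is None:
            raise NotFoundError(f"resource {resource_id!r} has no versions")
        base = json.loads(prod["base_schema"])
        rows = self.store.conn.execute(
            "SELECT * FROM schema_deltas WHERE resource_id = ? AND service = ?"
            " AND from_version < ? ORDER BY from_version, id",
            (resource_id, service, v),
        ).fetchall()
        deltas = [
            SchemaDelta(resource_id, r["from_version"], r["op"],
                        tuple(json.loads(r["payload"])))
            for r in rows
        ]
        return apply_schema_deltas(base, deltas)

    def schema_deltas_from(
        self, resource_id: str, from_version: int, service: str = "interop"
    ) -> list[SchemaDelta]:
        rows = self.store.conn.execute(
            "SELECT * FROM schema_deltas WHERE resource_id = ? AND service = ?"
            " AND from_version = ? ORDER BY id",
            (resource_id, service, from_version),
        ).fetchall()
        return [
            SchemaDelta(resource_id, r["from_version"], r["op"],
                        tuple(json.loads(r["payload"])))
            for r in rows
        ]

    # -- reporting -----------------------------------------------------

    def storage_report(self, resource_id: str, service: str = "interop") -> list[dict]:
        prod = self.production_row(resource_id, service)
        if prod is None:
            raise NotFoundError(f"resource {resource_id!r} has no versions")
        current = prod["version"]
        report = []
        for v in range(1, current + 1):
            deltas = self._deltas_for(resource_id, service, v)
            snap = self._snapshot_for(resource_id, service, v)
            byte_estimate = sum(
                len(d["entity"]) + len(d["value"] or "") for d in deltas
            )
            if snap is not None:
                byte_estimate += len(snap["rows"])
            report.append(
                {
                    "version": v,
                    "delta_rows": len(deltas),
                    "snapshot": snap is not None,
                    "is_production": v == current,
                    "byte_estimate": byte_estimate,
                }
            )
        return report
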