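"""Single-file embedded SQL storage shared by every subsystem.

Harvested relations are dynamic (their schemas follow the resources), so
they are physicalized generically: one metadata row per relation plus one
row per record, the record held as a canonical JSON object whose keys are
the present field names.  Missing fields are genuinely absent from the
object — a missing cell and an empty string are distinct states.

Rows within a relation are kept in canonical order (sorted by their JSON
serialization) so that any two relations with equal content are
byte-identical when exported.
"""

from __future__ import annotations

import json
import sqlite3
from typing import Iterable

_DDL = """
CREATE TABLE IF NOT EXISTS relations (
    name TEXT PRIMARY KEY,
    columns TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS relation_rows (
    relation TEXT NOT NULL,
    idx INTEGER NOT NULL,
    data TEXT NOT NULL,
    PRIMARY KEY (relation, idx)
);
CREATE TABLE IF NOT EXISTS resources (
    nif_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    services TEXT NOT NULL,
    script_location TEXT NOT NULL,
    script_locator TEXT NOT NULL,
    info_file TEXT NOT NULL,
    contacts TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    active INTEGER NOT NULL DEFAULT 1,
    registered_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS staged_versions (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    version_number INTEGER NOT NULL,
    base_version INTEGER NOT NULL,
    relation TEXT NOT NULL,
    record_count INTEGER NOT NULL,
    created_at TEXT NOT NULL,
    status TEXT NOT NULL,
    issues TEXT NOT NULL,
    changeset TEXT,
    note TEXT
);
CREATE TABLE IF NOT EXISTS production (
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    version INTEGER NOT NULL,
    relation TEXT NOT NULL,
    schema TEXT NOT NULL,
    base_schema TEXT NOT NULL,
    script TEXT NOT NULL,
    promoted_at TEXT NOT NULL,
    PRIMARY KEY (resource_id, service)
);
CREATE TABLE IF NOT EXISTS data_deltas (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    to_version INTEGER NOT NULL,
    entity TEXT NOT NULL,
    op TEXT NOT NULL,
    attribute TEXT,
    value TEXT
);
CREATE TABLE IF NOT EXISTS schema_deltas (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    from_version INTEGER NOT NULL,
    op TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS snapshots (
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    version INTEGER NOT NULL,
    rows TEXT NOT NULL,
    schema TEXT NOT NULL,
    PRIMARY KEY (resource_id, service, version)
);
CREATE TABLE IF NOT EXISTS promotions (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    service TEXT NOT NULL,
    version INTEGER NOT NULL,
    promoted_at TEXT NOT NULL,
    record_count INTEGER NOT NULL,
    n_added INTEGER NOT NULL,
    n_deleted INTEGER NOT NULL,
    n_modified INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS runs (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    started_at TEXT NOT NULL,
    finished_at TEXT NOT NULL,
    outcome TEXT NOT NULL,
    staged_id INTEGER,
    issue_counts TEXT NOT NULL,
    error TEXT,
    import_mode TEXT
);
CREATE TABLE IF NOT EXISTS audit_log (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    ts TEXT NOT NULL,
    resource_id TEXT,
    event TEXT NOT NULL,
    detail TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS notifications (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    ts TEXT NOT NULL,
    audience TEXT NOT NULL,
    resource_id TEXT,
    message TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS schedules (
    resource_id TEXT PRIMARY KEY,
    frequency TEXT NOT NULL,
    anchor TEXT,
    time_of_day TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS fetch_meta (
    locator TEXT PRIMARY KEY,
    fetched_at TEXT NOT NULL,
    size INTEGER NOT NULL,
    mtime REAL
);
CREATE TABLE IF NOT EXISTS manual_queue (
    resource_id TEXT PRIMARY KEY,
    requested_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS in_progress (
    resource_id TEXT PRIMARY KEY,
    since TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS views (
    view_name TEXT PRIMARY KEY,
    definition TEXT NOT NULL,
    beta_mat INTEGER NOT NULL DEFAULT 0,
    beta_at TEXT,
    prod_mat INTEGER NOT NULL DEFAULT 0,
    prod_at TEXT,
    failed INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS term_mappings (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    resource_id TEXT NOT NULL,
    field TEXT NOT NULL,
    raw_term TEXT NOT NULL,
    term_id TEXT,
    tier TEXT NOT NULL,
    version INTEGER NOT NULL
);
"""


def canonical_row_key(record: dict) -> str:
    return json.dumps(record, sort_keys=True, ensure_ascii=False)


class Store:
    """Thin wrapper over a sqlite3 connection holding all warehouse state."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_DDL)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- generic relation storage -------------------------------------

    def create_relation(self, name: str, columns: list[str]) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO relations (name, columns) VALUES (?, ?)",
            (name, json.dumps(columns)),
        )
        self.conn.execute("DELETE FROM relation_rows WHERE relation = ?", (name,))

    def relation_exists(self, name: str) -> bool:
        cur = self.conn.execute("SELECT 1 FROM relations WHERE name = ?", (name,))
        return cur.fetchone() is not None

    def relation_columns(self, name: str) -> list[str]:
        cur = self.conn.execute("SELECT columns FROM relations WHERE name = ?", (name,))
        row = cur.fetchone()
        if row is None:
            raise KeyError(name)
        return json.loads(row["columns"])

    def drop_relation(self, name: str) -> None:
        self.conn.execute("DELETE FROM relations WHERE name = ?", (name,))
        self.conn.execute("DELETE FROM relation_rows WHERE relation = ?", (name,))

    def append_row(self, name: str, record: dict) -> None:
        cur = self.conn.execute(
            "SELECT COALESCE(MAX(idx), -1) + 1 FROM relation_rows WHERE relation = ?",
            (name,),
        )
        idx = cur.fetchone()[0]
        self.conn.execute(
            "INSERT INTO relation_rows (relation, idx, data) VALUES (?, ?, ?)",
            (name, idx, canonical_row_key(record)),
        )

    def write_rows(self, name: str, records: Iterable[dict]) -> None:
        """Replace the relation's content; rows stored in canonical order."""
        ordered = sorted(records, key=canonical_row_key)
        self.conn.execute("DELETE FROM relation_rows WHERE relation = ?", (name,))
        self.conn.executemany(
            "INSERT INTO relation_rows (relation, idx, data) VALUES (?, ?, ?)",
            [(name, i, canonical_row_key(r)) for i, r in enumerate(ordered)],
        )

    def read_rows(self, name: str) -> list[dict]:
        cur = self.conn.execute(
            "SELECT data FROM relation_rows WHERE relation = ? ORDER BY idx",
            (name,),
        )
        return [json.loads(r["data"]) for r in cur.fetchall()]

    def row_count(self, name: str) -> int:
        cur = self.conn.execute(
            "SELECT COUNT(*) FROM relation_rows WHERE relation = ?", (name,)
        )
        return cur.fetchone()[0]

    # -- bookkeeping helpers ------------------------------------------

    def audit(self, ts: str, resource_id: str | None, event: str, detail: dict) -> None:
        self.conn.execute(
            "INSERT INTO audit_log (ts, resource_id, event, detail) VALUES (?, ?, ?, ?)",
            (ts, resource_id, event, json.dumps(detail, sort_keys=True)),
        )

    def notify(self, ts: str, audience: str, resource_id: str | None, message: str) -> None:
        self.conn.execute(
            "INSERT INTO notifications (ts, audience, resource_id, message)"
            " VALUES (?, ?, ?, ?)",
            (ts, audience, resource_id, message),
        )

    def checksum(self) -> str:
        """Content digest over all tables; used to prove reads are pure."""
        import hashlib

        h = hashlib.sha256()
        for table in (
            "relations", "relation_rows", "resources", "staged_versions",
            "production", "data_deltas", "schema_deltas", "snapshots",
            "promotions", "runs", "audit_log", "notifications", "schedules",
            "fetch_meta", "manual_queue", "in_progress", "views",
            "term_mappings",
        ):
            for row in self.conn.execute(f"SELECT * FROM {table}"):
                h.update(repr(tuple(row)).encode())
        return h.hexdigest()
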