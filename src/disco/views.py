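"""Materialized multi-resource views with beta and production channels.

A view is a union-concatenation of member projections: each member maps
every view column to one of its source fields or to a constant, and two
provenance columns (source resource id, source record key) are prepended
so every view row resolves back to exactly one production record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

import yaml

from .errors import NotFoundError, ParseError, UsageError, ValidationError
from .scripts import script_from_dict
from .staging import record_key
from .store import Store, canonical_row_key
from .version_store import VersionStore

PROVENANCE_COLUMNS = ["source_resource", "source_key"]


@dataclass
class ViewMember:
    resource_id: str
    column_map: dict[str, dict]   # view column -> {"field": name} | {"const": value}


@dataclass
class ViewDef:
    view_name: str
    view_columns: list[list[str]]        # ordered [name, declared_type]
    members: list[ViewMember]
    beta_mat: int = 0
    beta_at: str | None = None
    prod_mat: int = 0
    prod_at: str | None = None
    failed: bool = False

    def to_json(self) -> dict:
        return {
            "name": self.view_name,
            "columns": [list(c) for c in self.view_columns],
            "members": [
                {"resource": m.resource_id, "map": m.column_map} for m in self.members
            ],
        }


def _normalize_map(raw_map: dict) -> dict[str, dict]:
    out = {}
    for col, spec in raw_map.items():
        if isinstance(spec, str):
            out[col] = {"field": spec}
        elif isinstance(spec, dict) and ("field" in spec or "const" in spec):
            out[col] = spec
        else:
            raise ValidationError(
                f"column {col!r}: mapping must be a source field name or"
                " {{'const': value}}"
            )
    return out


class Views:
    def __init__(self, store: Store, versions: VersionStore,
                 clock: Callable[[], datetime] | None = None):
        self.store = store
        self.versions = versions
        self.clock = clock or (lambda: datetime.now(timezone.utc))

    # -- definition ----------------------------------------------------

    def define_view(self, definition: dict | str | Path) -> ViewDef:
        """Validate and persist a view definition (no materialization)."""
        if not isinstance(definition, dict):
            path = Path(definition)
            try:
                doc = yaml.safe_load(path.read_text(encoding="utf-8"))
            except (OSError, yaml.YAMLError) as exc:
                raise ParseError(f"cannot read view definition {definition}: {exc}") from exc
        else:
            doc = definition
        for key in ("name", "columns", "members"):
            if key not in doc:
                raise ParseError(f"view definition missing key {key!r}", element=key)
        columns = []
        for c in doc["columns"]:
            if isinstance(c, str):
                columns.append([c, "text"])
            else:
                columns.append([c["name"], c.get("type", "text")])
        col_names = [c[0] for c in columns]
        members = []
        for md in doc["members"]:
            rid = md["resource"]
            cmap = _normalize_map(md.get("map", {}))
            prod_schema = self.versions.production_schema(rid)
            if prod_schema is None:
                raise ValidationError(
                    f"member {rid!r} has no production version", location=rid
                )
            schema_fields = {name for name, _ in prod_schema}
            for col in col_names:
                if col not in cmap:
                    raise ValidationError(
                        f"member {rid!r} does not map view column {col!r}",
                        location=f"{rid}/{col}",
                    )
                spec = cmap[col]
                if "field" in spec and spec["field"] not in schema_fields:
                    raise ValidationError(
                        f"member {rid!r} maps column {col!r} to unknown field"
                        f" {spec['field']!r}",
                        location=f"{rid}/{col}",
                    )
            members.append(ViewMember(rid, cmap))
        view = ViewDef(doc["name"], columns, members)
        self.store.conn.execute(
            "INSERT OR REPLACE INTO views (view_name, definition, beta_mat,"
            " beta_at, prod_mat, prod_at, failed)"
            " VALUES (?, ?, 0, NULL, 0, NULL, 0)",
            (view.view_name, json.dumps(view.to_json())),
        )
        self.store.conn.commit()
        return view

    def _load(self, view_name: str) -> ViewDef:
        row = self.store.conn.execute(
            "SELECT * FROM views WHERE view_name = ?", (view_name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"view {view_name!r} is not defined")
        doc = json.loads(row["definition"])
        return ViewDef(
            view_name=doc["name"],
            view_columns=doc["columns"],
            members=[ViewMember(m["resource"], m["map"]) for m in doc["members"]],
            beta_mat=row["beta_mat"], beta_at=row["beta_at"],
            prod_mat=row["prod_mat"], prod_at=row["prod_at"],
            failed=bool(row["failed"]),
        )

    def list_views(self) -> list[ViewDef]:
        rows = self.store.conn.execute(
            "SELECT view_name FROM views ORDER BY view_name"
        ).fetchall()
        return [self._load(r["view_name"]) for r in rows]

    def views_referencing(self, resource_id: str) -> list[str]:
        return [
            v.view_name for v in self.list_views()
            if any(m.resource_id == resource_id for m in v.members)
        ]

    def flag_failed(self, view_name: str, _reason: str) -> None:
        self.store.conn.execute(
            "UPDATE views SET failed = 1 WHERE view_name = ?", (view_name,)
        )
        self.store.conn.commit()

    # -- materialization -----------------------------------------------

    @staticmethod
    def channel_relation(view_name: str, channel: str) -> str:
        return f"view__{view_name}__{channel}"

    def materialize_view(self, view_name: str, channel: str = "beta") -> list[dict]:
        """Rebuild the channel relation from member production data."""
        if channel not in ("beta", "production"):
            raise UsageError(f"unknown channel {channel!r}")
        view = self._load(view_name)
        col_names = [c[0] for c in view.view_columns]
        rows_out: list[dict] = []
        for member in view.members:
            prod = self.versions.production_row(member.resource_id)
            if prod is None:
                raise ValidationError(
                    f"member {member.resource_id!r} has no production version",
                    location=member.resource_id,
                )
            script = script_from_dict(json.loads(prod["script"]))
            schema_fields = {name for name, _ in json.loads(prod["schema"])}
            for col in col_names:
                spec = member.column_map.get(col)
                if spec is None:
                    raise ValidationError(
                        f"member {member.resource_id!r} no longer maps column {col!r}",
                        location=f"{member.resource_id}/{col}",
                    )
                if "field" in spec and spec["field"] not in schema_fields:
                    raise ValidationError(
                        f"member {member.resource_id!r}: field {spec['field']!r}"
                        f" vanished from its schema (drift)",
                        location=f"{member.resource_id}/{col}",
                    )
            for rec in self.store.read_rows(prod["relation"]):
                key = record_key(script, rec)
                out = {
                    "source_resource": member.resource_id,
                    "source_key": json.dumps(key.to_json()),
                }
                for col in col_names:
                    spec = member.column_map[col]
                    if "const" in spec:
                        out[col] = str(spec["const"])
                    else:
                        value = rec.get(spec["field"])
                        if value is not None:
                            out[col] = value
                rows_out.append(out)
        relation = self.channel_relation(view_name, channel)
        self.store.create_relation(relation, PROVENANCE_COLUMNS + col_names)
        # keep member-concatenation order: append without canonical resort
        for i, rec in enumerate(rows_out):
            self.store.conn.execute(
                "INSERT INTO relation_rows (relation, idx, data) VALUES (?, ?, ?)",
                (relation, i, canonical_row_key(rec)),
            )
        now = self.clock().isoformat()
        if channel == "beta":
            self.store.conn.execute(
                "UPDATE views SET beta_mat = beta_mat + 1, beta_at = ?, failed = 0"
                " WHERE view_name = ?",
                (now, view_name),
            )
        else:
            self.store.conn.execute(
                "UPDATE views SET prod_mat = prod_mat + 1, prod_at = ?"
                " WHERE view_name = ?",
                (now, view_name),
            )
        self.store.conn.commit()
        return rows_out

    def read_channel(self, view_name: str, channel: str) -> list[dict]:
        return self.store.read_rows(self.channel_relation(view_name, channel))

    # -- deployment ----------------------------------------------------

    def approve_view(self, view_name: str) -> None:
        """Copy the beta channel to production, atomically."""
        view = self._load(view_name)
        if view.beta_mat <= view.prod_mat:
            raise UsageError(
                f"view {view_name!r}: beta channel is not newer than production"
            )
        beta_rel = self.channel_relation(view_name, "beta")
        prod_rel = self.channel_relation(view_name, "production")
        rows = self.store.read_rows(beta_rel)
        columns = self.store.relation_columns(beta_rel)
        conn = self.store.conn
        conn.commit()
        try:
            self.store.create_relation(prod_rel, columns)
            for i, rec in enumerate(rows):
                conn.execute(
                    "INSERT INTO relation_rows (relation, idx, data) VALUES (?, ?, ?)",
                    (prod_rel, i, canonical_row_key(rec)),
                )
            now = self.clock().isoformat()
            conn.execute(
                "UPDATE views SET prod_mat = ?, prod_at = ? WHERE view_name = ?",
                (view.beta_mat, now, view_name),
            )
            conn.commit()
        except BaseException:
            conn.rollback()
            raise
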