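"""Catalog of participating resources.

A resource is described by a small XML information file::

    <resource id="nif-0000-0001" name="ToyNeuronDB">
      <contact name="Jo" email="jo@example.org"/>
      <service type="interop" script="scripts/toy.json"/>
      <description>free text</description>
    </resource>

Registration imports that file; re-registering the same id updates the
catalog entry in place and logs the change.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

from .errors import ConflictError, NotFoundError, ParseError, UsageError, ValidationError
from .store import Store

VALID_SERVICES = {"interop", "linkout", "news"}
NIF_ID_PATTERN = re.compile(r"^[A-Za-z]+-\d{4}-\d{5}$")

SORTABLE_FIELDS = {"nif_id", "name", "script_location", "active"}


@dataclass
class Resource:
    """A registered data source and the services it participates in."""

    nif_id: str
    name: str
    services: set[str]
    script_location: str          # "local" | "remote"
    script_locator: str
    info_file: str
    contacts: list[tuple[str, str]] = field(default_factory=list)
    description: str = ""
    active: bool = True

    def __post_init__(self) -> None:
        if not self.nif_id:
            raise ValidationError("resource id must be non-empty")
        unknown = self.services - VALID_SERVICES
        if unknown:
            raise ValidationError(f"unknown services: {sorted(unknown)}")
        if self.active and not self.services:
            raise ValidationError(
                f"active resource {self.nif_id!r} must declare at least one service"
            )

    @property
    def id_matches_pattern(self) -> bool:
        return NIF_ID_PATTERN.match(self.nif_id) is not None


def parse_info_file(path: str | Path) -> dict:
    """Parse a resource-information XML file into a plain dict."""
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML in {path}: {exc}", element="resource") from exc
    root = tree.getroot()
    if root.tag != "resource":
        raise ParseError(
            f"expected root element <resource>, got <{root.tag}>", element=root.tag
        )
    nif_id = root.get("id")
    if not nif_id:
        raise ParseError("missing required attribute 'id' on <resource>", element="id")
    name = root.get("name")
    if not name:
        raise ParseError("missing required attribute 'name' on <resource>", element="name")
    contacts = []
    for c in root.findall("contact"):
        contacts.append((c.get("name", ""), c.get("email", "")))
    services = {}
    for s in root.findall("service"):
        stype = s.get("type")
        if stype not in VALID_SERVICES:
            raise ParseError(f"unknown service type {stype!r}", element="service")
        services[stype] = s.get("script", "")
    desc = root.findtext("description") or ""
    return {
        "nif_id": nif_id,
        "name": name,
        "contacts": contacts,
        "services": services,
        "description": desc.strip(),
    }


@dataclass
class ResourcePage:
    items: list[Resource]
    total: int
    offset: int
    limit: int | None


class Registry:
    def __init__(self, store: Store, clock: Callable[[], datetime] | None = None):
        self.store = store
        self.clock = clock or (lambda: datetime.now(timezone.utc))

    # -- persistence helpers ------------------------------------------

    @staticmethod
    def _row_to_resource(row) -> Resource:
        return Resource(
            nif_id=row["nif_id"],
            name=row["name"],
            services=set(json.loads(row["services"])),
            script_location=row["script_location"],
            script_locator=row["script_locator"],
            info_file=row["info_file"],
            contacts=[tuple(c) for c in json.loads(row["contacts"])],
            description=row["description"],
            active=bool(row["active"]),
        )

    def _persist(self, res: Resource) -> None:
        self.store.conn.execute(
            "INSERT OR REPLACE INTO resources"
            " (nif_id, name, services, script_location, script_locator,"
            "  info_file, contacts, description, active, registered_at)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (
                res.nif_id, res.name, json.dumps(sorted(res.services)),
                res.script_location, res.script_locator, res.info_file,
                json.dumps([list(c) for c in res.contacts]), res.description,
                int(res.active), self.clock().isoformat(),
            ),
        )
        self.store.conn.commit()

    # -- operations ----------------------------------------------------

    def register_resource(
        self,
        info_file: str | Path,
        script_locator: str | Path | None = None,
        services: set[str] | None = None,
    ) -> Resource:
        """Import (or idempotently update) a resource from its info file.

        ``script_locator`` defaults to the interop service script declared
        in the info file, resolved relative to the info file's directory.
        """
        info = parse_info_file(info_file)
        if services is None:
            services = set(info["services"])
        needs_script = "interop" in services
        if script_locator is None:
            declared = info["services"].get("interop", "")
            if not declared and needs_script:
                raise ValidationError(
                    f"no script locator given and none declared for {info['nif_id']!r}"
                )
            script_locator = Path(info_file).parent / declared if declared else ""
        locator = str(script_locator)
        if "://" in locator:
            location = "remote"
        else:
            location = "local"
            if needs_script and not Path(locator).is_file():
                raise ValidationError(
                    f"harvest script {locator!r} is not readable", location=locator
                )
        existing = self._get_or_none(info["nif_id"])
        if existing is not None and existing.name != info["name"]:
            raise ConflictError(
                f"resource {info['nif_id']!r} already registered as"
                f" {existing.name!r}, conflicting name {info['name']!r}"
            )
        res = Resource(
            nif_id=info["nif_id"],
            name=info["name"],
            services=set(services),
            script_location=location,
            script_locator=locator,
            info_file=str(info_file),
            contacts=info["contacts"],
            description=info["description"],
        )
        self._persist(res)
        now = self.clock().isoformat()
        event = "resource_updated" if existing else "resource_registered"
        self.store.audit(now, res.nif_id, event, {"name": res.name,
                                                  "services": sorted(res.services)})
        self.store.conn.commit()
        return res

    def _get_or_none(self, nif_id: str) -> Resource | None:
        cur = self.store.conn.execute(
            "SELECT * FROM resources WHERE nif_id = ?", (nif_id,)
        )
        row = cur.fetchone()
        return self._row_to_resource(row) if row else None

    def get(self, nif_id: str) -> Resource:
        res = self._get_or_none(nif_id)
        if res is None:
            raise NotFoundError(f"resource {nif_id!r} is not registered")
        return res

    def list_resources(
        self,
        query: str | None = None,
        sort_key: str = "nif_id",
        offset: int = 0,
        limit: int | None = None,
    ) -> ResourcePage:
        if sort_key not in SORTABLE_FIELDS:
            raise UsageError(
                f"unknown sort key {sort_key!r}; expected one of {sorted(SORTABLE_FIELDS)}"
            )
        rows = self.store.conn.execute("SELECT * FROM resources").fetchall()
        resources = [self._row_to_resource(r) for r in rows]
        if query:
            q = query.lower()
            resources = [
                r for r in resources
                if q in r.nif_id.lower() or q in r.name.lower()
            ]
        resources.sort(key=lambda r: (str(getattr(r, sort_key)), r.nif_id))
        total = len(resources)
        window = resources[offset: (offset + limit) if limit is not None else None]
        return ResourcePage(items=window, total=total, offset=offset, limit=limit)

    def resource_detail(self, nif_id: str) -> dict:
        res = self.get(nif_id)
        info = parse_info_file(res.info_file)
        script_pointers = {}
        for svc in sorted(res.services):
            if svc == "interop":
                script_pointers[svc] = res.script_locator
            else:
                declared = info["services"].get(svc, "")
                script_pointers[svc] = (
                    str(Path(res.info_file).parent / declared) if declared else ""
                )
        return {
            "nif_id": res.nif_id,
            "name": res.name,
            "services": sorted(res.services),
            "script_location": res.script_location,
            "scripts": script_pointers,
            "contacts": res.contacts,
            "description": info["description"],
            "active": res.active,
        }

    # -- serialization round-trip -------------------------------------

    def export_registry(self) -> list[dict]:
        page = self.list_resources()
        return [
            {
                "nif_id": r.nif_id,
                "name": r.name,
                "services": sorted(r.services),
                "script_location": r.script_location,
                "script_locator": r.script_locator,
                "info_file": r.info_file,
                "contacts": [list(c) for c in r.contacts],
                "description": r.description,
                "active": r.active,
            }
            for r in page.items
        ]

    def import_registry(self, dump: list[dict]) -> None:
        for entry in dump:
            res = Resource(
                nif_id=entry["nif_id"],
                name=entry["name"],
                services=set(entry["services"]),
                script_location=entry["script_location"],
                script_locator=entry["script_locator"],
                info_file=entry["info_file"],
                contacts=[tuple(c) for c in entry["contacts"]],
                description=entry["description"],
                active=entry["active"],
            )
            self._persist(res)
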