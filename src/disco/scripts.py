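"""Harvest scripts: declarative templates that drive extraction.

A script is a structured key/value document (JSON or YAML) telling the
crawler where each source lives, how to pull records out of it, which
fields exist with what declared types, and which fields form the primary
key.  Raw values stay untrimmed strings; typing happens in
:func:`coerce_records` and never mutates the raw record.
"""

from __future__ import annotations

import csv
import io
import json
import re
import urllib.error
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import yaml

from .errors import ExtractionError, FetchError, ParseError, ValidationError

FORMATS = {"csv", "tsv", "xml", "json"}
DECLARED_TYPES = {"integer", "real", "text", "date", "url"}
CONTENT_KINDS = {"value", "term", "object"}

_PLACEHOLDER_RE = re.compile(r"\{(\w+)\}")
_INT_RE = re.compile(r"^[+-]?\d+$")
_REAL_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_MDY_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{2}|\d{4})$")


@dataclass
class FieldSpec:
    name: str
    declared_type: str = "text"
    max_length: int | None = None
    content_kind: str = "value"
    relationship: str | None = None
    renamed_from: str | None = None   # declared rename, consumed at promotion

    def __post_init__(self) -> None:
        if self.declared_type not in DECLARED_TYPES:
            raise ValidationError(
                f"field {self.name!r}: unknown type {self.declared_type!r}",
                location=f"fields/{self.name}",
            )
        if self.content_kind not in CONTENT_KINDS:
            raise ValidationError(
                f"field {self.name!r}: unknown content kind {self.content_kind!r}",
                location=f"fields/{self.name}",
            )
        if self.max_length is not None:
            if self.declared_type != "text":
                raise ValidationError(
                    f"field {self.name!r}: max_length only applies to text fields",
                    location=f"fields/{self.name}",
                )
            if self.max_length <= 0:
                raise ValidationError(
                    f"field {self.name!r}: max_length must be positive",
                    location=f"fields/{self.name}",
                )


@dataclass
class SourceSpec:
    locator: str
    format: str
    record_selector: str = ""
    field_extractors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValidationError(
                f"unknown source format {self.format!r}", location=self.locator
            )


@dataclass
class HarvestScript:
    resource_id: str
    table_name: str
    sources: list[SourceSpec]
    fields: list[FieldSpec]
    primary_key: list[str] = field(default_factory=list)
    link_template: str | None = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate field names: {sorted(dupes)}", location="fields"
            )
        declared = set(names)
        for pk in self.primary_key:
            if pk not in declared:
                raise ValidationError(
                    f"primary key names undeclared field {pk!r}",
                    location="primary_key",
                )
        if self.link_template:
            for ph in _PLACEHOLDER_RE.findall(self.link_template):
                if ph not in declared:
                    raise ValidationError(
                        f"link template placeholder {{{ph}}} names undeclared field",
                        location="link_template",
                    )
        for src in self.sources:
            for fname in src.field_extractors:
                if fname not in declared:
                    raise ValidationError(
                        f"source {src.locator!r} extracts undeclared field {fname!r}",
                        location=f"sources/{src.locator}",
                    )

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    @property
    def digest_mode(self) -> bool:
        return not self.primary_key

    def schema(self) -> list[list[str]]:
        """Ordered (name, declared type) pairs — the relation schema."""
        return [[f.name, f.declared_type] for f in self.fields]

    def renames(self) -> dict[str, str]:
        return {f.renamed_from: f.name for f in self.fields if f.renamed_from}

    def to_dict(self) -> dict:
        doc: dict = {
            "resource": self.resource_id,
            "table": self.table_name,
            "sources": [
                {
                    "locator": s.locator,
                    "format": s.format,
                    "record_selector": s.record_selector,
                    "fields": dict(s.field_extractors),
                }
                for s in self.sources
            ],
            "fields": [],
            "primary_key": list(self.primary_key),
        }
        for f in self.fields:
            fd: dict = {"name": f.name, "type": f.declared_type}
            if f.max_length is not None:
                fd["max_length"] = f.max_length
            if f.content_kind != "value":
                fd["kind"] = f.content_kind
            if f.relationship:
                fd["relationship"] = f.relationship
            if f.renamed_from:
                fd["renamed_from"] = f.renamed_from
            doc["fields"].append(fd)
        if self.link_template:
            doc["link_template"] = self.link_template
        return doc


def script_from_dict(doc: dict, base_dir: Path | None = None) -> HarvestScript:
    for key in ("resource", "table", "sources", "fields"):
        if key not in doc:
            raise ParseError(f"harvest script missing required key {key!r}", element=key)
    fields = []
    for fd in doc["fields"]:
        if "name" not in fd:
            raise ParseError("field entry missing 'name'", element="fields")
        fields.append(
            FieldSpec(
                name=fd["name"],
                declared_type=fd.get("type", "text"),
                max_length=fd.get("max_length"),
                content_kind=fd.get("kind", "value"),
                relationship=fd.get("relationship"),
                renamed_from=fd.get("renamed_from"),
            )
        )
    sources = []
    for sd in doc["sources"]:
        if "locator" not in sd or "format" not in sd:
            raise ParseError(
                "source entry requires 'locator' and 'format'", element="sources"
            )
        locator = sd["locator"]
        if base_dir is not None and "://" not in locator and not Path(locator).is_absolute():
            locator = str(base_dir / locator)
        sources.append(
            SourceSpec(
                locator=locator,
                format=sd["format"],
                record_selector=sd.get("record_selector", ""),
                field_extractors=dict(sd.get("fields", {})),
            )
        )
    return HarvestScript(
        resource_id=doc["resource"],
        table_name=doc["table"],
        sources=sources,
        fields=fields,
        primary_key=list(doc.get("primary_key", [])),
        link_template=doc.get("link_template"),
    )


def parse_script(document: str | Path) -> HarvestScript:
    """Parse and fully validate a harvest-script file (JSON or YAML)."""
    path = Path(document)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read harvest script {document}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"harvest script {document} is not valid JSON/YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("harvest script must be a mapping at top level")
    return script_from_dict(doc, base_dir=path.parent)


# -- fetching ----------------------------------------------------------


@dataclass
class FetchResult:
    locator: str
    content: bytes
    fetched_at: datetime
    size: int
    mtime: float | None = None


def fetch_source(spec: SourceSpec, timeout: float = 30.0) -> FetchResult:
    """Retrieve source bytes unmodified, recording metadata for probing."""
    now = datetime.now(timezone.utc)
    if "://" in spec.locator:
        try:
            with urllib.request.urlopen(spec.locator, timeout=timeout) as resp:
                data = resp.read()
        except urllib.error.HTTPError as exc:
            reason = "not_found" if exc.code == 404 else "other"
            raise FetchError(
                f"fetch of {spec.locator!r} failed: HTTP {exc.code}",
                locator=spec.locator, reason=reason,
            ) from exc
        except TimeoutError as exc:
            raise FetchError(
                f"fetch of {spec.locator!r} timed out", locator=spec.locator,
                reason="timeout",
            ) from exc
        except urllib.error.URLError as exc:
            reason = "timeout" if isinstance(exc.reason, TimeoutError) else "other"
            raise FetchError(
                f"fetch of {spec.locator!r} failed: {exc.reason}",
                locator=spec.locator, reason=reason,
            ) from exc
        return FetchResult(spec.locator, data, now, len(data))
    path = Path(spec.locator)
    if not path.is_file():
        raise FetchError(
            f"source file {spec.locator!r} not found", locator=spec.locator,
            reason="not_found",
        )
    data = path.read_bytes()
    return FetchResult(spec.locator, data, now, len(data), mtime=path.stat().st_mtime)


# -- extraction --------------------------------------------------------

Record = dict  # ordered map field name -> raw string value; missing keys allowed


def _extract_csv(spec: SourceSpec, data: bytes, delimiter: str) -> list[Record]:
    text = data.decode("utf-8")
    if delimiter == ",":
        reader = csv.reader(io.StringIO(text, newline=""))
    else:
        reader = csv.reader(io.StringIO(text, newline=""),
                            delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)
    rows = list(reader)
    if not rows:
        raise ExtractionError(
            f"source {spec.locator!r} is empty (no header row)",
            locator=spec.locator, selector="header",
        )
    header = rows[0]
    col_index = {name: i for i, name in enumerate(header)}
    for fname, col in spec.field_extractors.items():
        if col not in col_index:
            raise ExtractionError(
                f"source {spec.locator!r} is missing column {col!r}"
                f" needed for field {fname!r}",
                locator=spec.locator, selector=col,
            )
    records: list[Record] = []
    for raw in rows[1:]:
        rec: Record = {}
        for fname, col in spec.field_extractors.items():
            i = col_index[col]
            if i < len(raw):
                rec[fname] = raw[i]
        records.append(rec)
    return records


def _json_scalar_to_str(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return json.dumps(value)
    return str(value)


def _json_pointer(doc, pointer: str):
    node = doc
    for step in [s for s in pointer.split("/") if s]:
        if isinstance(node, list):
            node = node[int(step)]
        elif isinstance(node, dict):
            node = node[step]
        else:
            raise KeyError(step)
    return node


def _extract_json(spec: SourceSpec, data: bytes) -> list[Record]:
    try:
        doc = json.loads(data.decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise ExtractionError(
            f"source {spec.locator!r} is not valid JSON: {exc}", locator=spec.locator
        ) from exc
    try:
        array = _json_pointer(doc, spec.record_selector)
    except (KeyError, IndexError, ValueError) as exc:
        raise ExtractionError(
            f"record selector {spec.record_selector!r} not found in {spec.locator!r}",
            locator=spec.locator, selector=spec.record_selector,
        ) from exc
    if not isinstance(array, list):
        raise ExtractionError(
            f"record selector {spec.record_selector!r} does not point at an array",
            locator=spec.locator, selector=spec.record_selector,
        )
    records: list[Record] = []
    for item in array:
        rec: Record = {}
        for fname, pointer in spec.field_extractors.items():
            try:
                value = _json_pointer(item, pointer)
            except (KeyError, IndexError, ValueError):
                continue
            if value is None:
                continue
            rec[fname] = _json_scalar_to_str(value)
        records.append(rec)
    return records


def _extract_xml(spec: SourceSpec, data: bytes) -> list[Record]:
    # Restricted path syntax: child steps separated by "/", attribute
    # access with a leading "@" on the final step.
    try:
        root = ET.fromstring(data.decode("utf-8"))
    except ET.ParseError as exc:
        raise ExtractionError(
            f"source {spec.locator!r} is not well-formed XML: {exc}",
            locator=spec.locator,
        ) from exc
    selector = spec.record_selector or "."
    if any(tok in selector for tok in ("//", "..", "[", "*")):
        raise ExtractionError(
            f"record selector {selector!r} uses unsupported path syntax",
            locator=spec.locator, selector=selector,
        )
    elements = root.findall(selector) if selector != "." else [root]
    records: list[Record] = []
    for el in elements:
        rec: Record = {}
        for fname, path in spec.field_extractors.items():
            if path.startswith("@"):
                value = el.get(path[1:])
            elif "/@" in path:
                child_path, attr = path.rsplit("/@", 1)
                child = el.find(child_path)
                value = child.get(attr) if child is not None else None
            else:
                value = el.findtext(path)
            if value is not None:
                rec[fname] = value
        records.append(rec)
    return records


def extract_records(script: HarvestScript,
                    documents: list[bytes] | dict[str, bytes]) -> list[Record]:
    """Extract one record per selected unit, sources concatenated in order.

    ``documents`` is either a list parallel to ``script.sources`` or a map
    keyed by locator.
    """
    if isinstance(documents, dict):
        docs = []
        for src in script.sources:
            if src.locator not in documents:
                raise ExtractionError(
                    f"no document supplied for source {src.locator!r}",
                    locator=src.locator,
                )
            docs.append(documents[src.locator])
    else:
        if len(documents) != len(script.sources):
            raise ExtractionError(
                f"expected {len(script.sources)} documents, got {len(documents)}"
            )
        docs = list(documents)
    records: list[Record] = []
    for src, data in zip(script.sources, docs):
        if src.format == "csv":
            records.extend(_extract_csv(src, data, ","))
        elif src.format == "tsv":
            records.extend(_extract_csv(src, data, "\t"))
        elif src.format == "json":
            records.extend(_extract_json(src, data))
        elif src.format == "xml":
            records.extend(_extract_xml(src, data))
    return records


# -- typed coercion ----------------------------------------------------


@dataclass
class CoercionIssue:
    kind: str                      # data_type_error | field_overflow
    record_locator: str
    field: str
    message: str


def parse_date_value(raw: str) -> date:
    """ISO-8601 dates plus M/D/YY and M/D/YYYY (two-digit pivot at 1970)."""
    m = _MDY_RE.match(raw)
    if m:
        month, day, year = int(m.group(1)), int(m.group(2)), int(m.group(3))
        if year < 100:
            year += 2000 if year < 70 else 1900
        return date(year, month, day)
    return date.fromisoformat(raw)


def coerce_value(raw: str, spec: FieldSpec):
    if spec.declared_type == "integer":
        if not _INT_RE.match(raw):
            raise ValueError(f"{raw!r} is not an integer")
        return int(raw)
    if spec.declared_type == "real":
        if not _REAL_RE.match(raw):
            raise ValueError(f"{raw!r} is not a real number")
        return float(raw)
    if spec.declared_type == "date":
        return parse_date_value(raw)
    if spec.declared_type == "url":
        if "://" not in raw:
            raise ValueError(f"{raw!r} is not a URL")
        return raw
    return raw


def coerce_records(
    script: HarvestScript, records: list[Record]
) -> tuple[list[dict], list[CoercionIssue]]:
    """Produce a typed view of each record plus per-cell issues.

    Values are never truncated or modified; overflow and type failures
    become issues for the lifecycle to adjudicate, not exceptions.
    """
    specs = {f.name: f for f in script.fields}
    typed_records: list[dict] = []
    issues: list[CoercionIssue] = []
    for i, rec in enumerate(records):
        locator = f"record[{i}]"
        typed: dict = {}
        for fname, raw in rec.items():
            spec = specs[fname]
            if raw == "":
                typed[fname] = None
                continue
            try:
                typed[fname] = coerce_value(raw, spec)
            except ValueError as exc:
                typed[fname] = None
                issues.append(CoercionIssue("data_type_error", locator, fname, str(exc)))
                continue
            if (
                spec.declared_type == "text"
                and spec.max_length is not None
                and len(raw) > spec.max_length
            ):
                issues.append(
                    CoercionIssue(
                        "field_overflow", locator, fname,
                        f"value of length {len(raw)} exceeds max_length {spec.max_length}",
                    )
                )
        typed_records.append(typed)
    return typed_records, issues
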