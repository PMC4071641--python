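"""Deterministic mock resources that evolve with known ground truth.

Every pipeline stage can be exercised offline: a bundle is a source file,
a harvest script, and an info file on disk; ``evolve`` applies explicit
events (row add/edit/delete, column add/drop/rename) and derives the
expected changeset *constructively from the events* — rows are tracked by
an internal identity column, never matched by the diff engine's keys — so
the generator and the diff engine cannot share a bug.
"""

from __future__ import annotations

import copy
import csv
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GenerationError, ValidationError
from .staging import ChangeSet, RecordKey, content_digest
from .store import canonical_row_key

UID_FIELD = "uid"

_WORDS = [
    "pyramidal", "granule", "Purkinje", "stellate", "basket", "mitral",
    "chandelier", "Golgi", "medium spiny", "motor",
]
_REGIONS = [
    "CA1", "CA3", "dentate gyrus", "cerebellum", "neocortex", "thalamus",
    "striatum", "olfactory bulb",
]
_PATHOLOGICAL = [
    "value,with,commas",
    'he said "hello"',
    "naïve—µm² ünïcode",
    "",
    "  leading and trailing  ",
]


@dataclass
class SynthField:
    name: str
    declared_type: str = "text"
    content_kind: str = "value"
    max_length: int | None = None


def default_schema() -> list[SynthField]:
    return [
        SynthField(UID_FIELD, "integer"),
        SynthField("neuron_name", "text", content_kind="term"),
        SynthField("brain_region", "text", content_kind="term"),
        SynthField("notes", "text"),
    ]


@dataclass
class EvolutionEvent:
    kind: str
    params: dict = field(default_factory=dict)

    KINDS = ("add_rows", "edit_cells", "delete_rows",
             "add_column", "drop_column", "rename_column")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown evolution event kind {self.kind!r}")


@dataclass
class GroundTruthStep:
    """Expected outcome of one version transition."""

    changeset: ChangeSet
    schema_deltas: list[tuple]          # (op, [payload...]) in emission order
    snapshot_rows: list[dict]           # canonical rows after the transition
    schema: list[list[str]]             # [name, type] pairs after the transition


@dataclass
class Bundle:
    out_dir: Path
    nif_id: str
    name: str
    table: str
    schema: list[SynthField]
    rows: list[dict]                    # every field present, values are str
    digest_mode: bool
    next_uid: int
    version: int = 1
    pathological: bool = False
    renames: dict[str, str] = field(default_factory=dict)  # pending, for next script

    @property
    def source_path(self) -> Path:
        return self.out_dir / f"{self.table}.csv"

    @property
    def script_path(self) -> Path:
        return self.out_dir / "script.json"

    @property
    def info_path(self) -> Path:
        return self.out_dir / "info.xml"

    def primary_key(self) -> list[str]:
        return [] if self.digest_mode else [UID_FIELD]

    def script_dict(self) -> dict:
        fields = []
        for f in self.schema:
            fd: dict = {"name": f.name, "type": f.declared_type}
            if f.content_kind != "value":
                fd["kind"] = f.content_kind
            if f.max_length is not None:
                fd["max_length"] = f.max_length
            old = self.renames.get(f.name)
            if old:
                fd["renamed_from"] = old
            fields.append(fd)
        return {
            "resource": self.nif_id,
            "table": self.table,
            "sources": [
                {
                    "locator": self.source_path.name,
                    "format": "csv",
                    "fields": {f.name: f.name for f in self.schema},
                }
            ],
            "fields": fields,
            "primary_key": self.primary_key(),
            "link_template": f"http://example.org/{self.table}/{{{UID_FIELD}}}",
        }

    def schema_pairs(self) -> list[list[str]]:
        return [[f.name, f.declared_type] for f in self.schema]

    def write(self, write_script: bool = True) -> None:
        import json as _json

        self.out_dir.mkdir(parents=True, exist_ok=True)
        header = [f.name for f in self.schema]
        with open(self.source_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for row in self.rows:
                writer.writerow([row.get(name, "") for name in header])
        if write_script:
            self.script_path.write_text(
                _json.dumps(self.script_dict(), indent=2), encoding="utf-8"
            )
        if not self.info_path.exists():
            self.info_path.write_text(
                f'<resource id="{self.nif_id}" name="{self.name}">\n'
                f'  <contact name="Synthetic Curator" email="curator@example.org"/>\n'
                f'  <service type="interop" script="script.json"/>\n'
                f"  <description>Synthetic evolving resource.</description>\n"
                f"</resource>\n",
                encoding="utf-8",
            )

    def canonical_rows(self) -> list[dict]:
        return sorted((dict(r) for r in self.rows), key=canonical_row_key)


def _value_for(spec: SynthField, rng: random.Random, pathological: bool) -> str:
    if spec.name == UID_FIELD:
        raise AssertionError("uid values are assigned, never drawn")
    if spec.declared_type == "integer":
        return str(rng.randint(0, 999999))
    if spec.declared_type == "real":
        return f"{rng.uniform(0, 1000):.3f}"
    if spec.declared_type == "date":
        y, m, d = rng.randint(1990, 2024), rng.randint(1, 12), rng.randint(1, 28)
        return f"{y:04d}-{m:02d}-{d:02d}"
    if spec.declared_type == "url":
        return f"http://example.org/item/{rng.randint(1, 99999)}"
    pool = list(_WORDS) if "neuron" in spec.name else list(_REGIONS)
    if spec.name not in ("neuron_name", "brain_region"):
        pool = [f"{w} note {rng.randint(0, 99)}" for w in _WORDS[:5]]
    if pathological:
        pool = pool + _PATHOLOGICAL
        if spec.max_length is not None:
            pool.append("x" * (spec.max_length + rng.randint(1, 10)))
    return rng.choice(pool)


def _new_row(schema: list[SynthField], uid: int, rng: random.Random,
             pathological: bool) -> dict:
    row = {UID_FIELD: str(uid)}
    for spec in schema:
        if spec.name != UID_FIELD:
            row[spec.name] = _value_for(spec, rng, pathological)
    return row


def generate_resource(
    seed: int,
    n_records: int,
    out_dir: str | Path,
    nif_id: str = "nif-9000-00001",
    name: str = "SynthNeuronDB",
    table: str = "neurons",
    schema: list[SynthField] | None = None,
    digest_mode: bool = False,
    pathological: bool = False,
) -> Bundle:
    """Write a deterministic bundle (source csv + script + info file)."""
    if n_records < 0:
        raise ValidationError("n_records must be >= 0")
    schema = copy.deepcopy(schema) if schema is not None else default_schema()
    names = [f.name for f in schema]
    if UID_FIELD not in names:
        raise ValidationError(f"schema must include the {UID_FIELD!r} identity field")
    if len(set(names)) != len(names):
        raise ValidationError("schema field names must be unique")
    rng = random.Random(seed)
    rows = [_new_row(schema, uid, rng, pathological) for uid in range(1, n_records + 1)]
    bundle = Bundle(
        out_dir=Path(out_dir), nif_id=nif_id, name=name, table=table,
        schema=schema, rows=rows, digest_mode=digest_mode,
        next_uid=n_records + 1, pathological=pathological,
    )
    bundle.write()
    return bundle


# -- ground-truth changesets ------------------------------------------


def _row_key(bundle: Bundle, row: dict) -> RecordKey:
    if bundle.digest_mode:
        return RecordKey.from_digest(content_digest(row))
    return RecordKey.from_pk((row[UID_FIELD],))


def _constructive_changeset(
    bundle: Bundle, old_by_uid: dict[str, dict], new_by_uid: dict[str, dict]
) -> ChangeSet:
    """Build the expected changeset from row identity, not key matching."""
    cs = ChangeSet()
    added_uids = [u for u in new_by_uid if u not in old_by_uid]
    deleted_uids = [u for u in old_by_uid if u not in new_by_uid]
    surviving = [u for u in old_by_uid if u in new_by_uid]
    if bundle.digest_mode:
        for uid in added_uids:
            cs.added.add(RecordKey.from_digest(content_digest(new_by_uid[uid])))
        for uid in deleted_uids:
            cs.deleted.add(RecordKey.from_digest(content_digest(old_by_uid[uid])))
        for uid in surviving:
            if old_by_uid[uid] == new_by_uid[uid]:
                cs.unchanged_count += 1
            else:
                cs.deleted.add(RecordKey.from_digest(content_digest(old_by_uid[uid])))
                cs.added.add(RecordKey.from_digest(content_digest(new_by_uid[uid])))
        return cs
    for uid in added_uids:
        cs.added.add(RecordKey.from_pk((uid,)))
    for uid in deleted_uids:
        cs.deleted.add(RecordKey.from_pk((uid,)))
    for uid in surviving:
        old_row, new_row = old_by_uid[uid], new_by_uid[uid]
        entries = []
        for fname in sorted(set(old_row) | set(new_row)):
            if old_row.get(fname) != new_row.get(fname):
                entries.append((fname, old_row.get(fname), new_row.get(fname)))
        if entries:
            cs.modified[RecordKey.from_pk((uid,))] = entries
        else:
            cs.unchanged_count += 1
    return cs


# -- evolution ---------------------------------------------------------


def _apply_event(bundle: Bundle, event: EvolutionEvent, rng: random.Random) -> None:
    rows, schema = bundle.rows, bundle.schema
    protected = {UID_FIELD}
    if event.kind == "add_rows":
        for _ in range(event.params.get("n", 1)):
            rows.append(_new_row(schema, bundle.next_uid, rng, bundle.pathological))
            bundle.next_uid += 1
    elif event.kind == "delete_rows":
        n = event.params.get("n", 1)
        if n > len(rows):
            raise GenerationError(f"cannot delete {n} of {len(rows)} rows")
        for _ in range(n):
            rows.pop(rng.randrange(len(rows)))
    elif event.kind == "edit_cells":
        n = event.params.get("n", 1)
        editable = [f for f in schema if f.name not in protected]
        if not rows or not editable:
            raise GenerationError("no editable cells")
        targets = rng.sample(range(len(rows)), min(n, len(rows)))
        for i in targets:
            spec = rng.choice(editable)
            old = rows[i].get(spec.name, "")
            for _ in range(64):
                new = _value_for(spec, rng, bundle.pathological)
                if new != old:
                    break
            else:  # pragma: no cover - pools always have >1 value
                raise GenerationError("value pool exhausted")
            rows[i][spec.name] = new
    elif event.kind == "add_column":
        name = event.params["name"]
        dtype = event.params.get("type", "text")
        if any(f.name == name for f in schema):
            raise GenerationError(f"column {name!r} already exists")
        spec = SynthField(name, dtype)
        schema.append(spec)
        for row in rows:
            row[name] = _value_for(spec, rng, bundle.pathological)
    elif event.kind == "drop_column":
        name = event.params["name"]
        if name in protected:
            raise GenerationError(f"cannot drop identity column {name!r}")
        if not any(f.name == name for f in schema):
            raise GenerationError(f"no such column {name!r}")
        bundle.schema = [f for f in schema if f.name != name]
        for row in rows:
            row.pop(name, None)
    elif event.kind == "rename_column":
        old, new = event.params["old"], event.params["new"]
        if old in protected:
            raise GenerationError(f"cannot rename identity column {old!r}")
        if not any(f.name == old for f in schema):
            raise GenerationError(f"no such column {old!r}")
        if any(f.name == new for f in schema):
            raise GenerationError(f"column {new!r} already exists")
        for f in schema:
            if f.name == old:
                f.name = new
        for row in rows:
            if old in row:
                row[new] = row.pop(old)
        bundle.renames[new] = old


_SCHEMA_OP_ORDER = {"rename_column": 0, "drop_column": 1, "add_column": 2}


def _expected_schema_deltas(events: list[EvolutionEvent]) -> list[tuple]:
    structural = [e for e in events if e.kind in _SCHEMA_OP_ORDER]
    structural.sort(key=lambda e: _SCHEMA_OP_ORDER[e.kind])
    out = []
    for e in structural:
        if e.kind == "rename_column":
            out.append(("rename_column", [e.params["old"], e.params["new"]]))
        elif e.kind == "drop_column":
            out.append(("drop_column", [e.params["name"]]))
        else:
            out.append(("add_column", [e.params["name"], e.params.get("type", "text")]))
    return out


def evolve(
    bundle: Bundle,
    events: list[EvolutionEvent],
    seed: int,
    break_mode: bool = False,
) -> tuple[Bundle, GroundTruthStep]:
    """Apply events in order, rewrite the bundle files, and return the
    constructive ground truth for the transition.

    In ``break_mode`` the harvest script is deliberately NOT rewritten
    after structural events, so extraction against the stale script
    fails — reproducing a broken ingestion procedure.
    """
    rng = random.Random(seed)
    old_by_uid = {r[UID_FIELD]: copy.deepcopy(r) for r in bundle.rows}
    new_bundle = copy.deepcopy(bundle)
    new_bundle.renames = {}
    new_bundle.version += 1
    for event in events:
        _apply_event(new_bundle, event, rng)
    new_by_uid = {r[UID_FIELD]: dict(r) for r in new_bundle.rows}
    changeset = _constructive_changeset(new_bundle, old_by_uid, new_by_uid)
    step = GroundTruthStep(
        changeset=changeset,
        schema_deltas=_expected_schema_deltas(events),
        snapshot_rows=new_bundle.canonical_rows(),
        schema=new_bundle.schema_pairs(),
    )
    new_bundle.write(write_script=not break_mode)
    return new_bundle, step


# -- random histories --------------------------------------------------

DEFAULT_WEIGHTS = {
    "add_rows": 0.35,
    "edit_cells": 0.35,
    "delete_rows": 0.14,
    "add_column": 0.06,
    "drop_column": 0.05,
    "rename_column": 0.05,
}


@dataclass
class History:
    """All version states of one synthetic resource, plus ground truth.

    ``steps[i]`` describes the transition from version i+1 to i+2;
    ``snapshots[v]`` is the canonical row list at version v (1-based).
    """

    bundle: Bundle
    snapshots: dict[int, list[dict]]
    schemas: dict[int, list[list[str]]]
    steps: list[GroundTruthStep]
    _states: list[Bundle] = field(default_factory=list)

    @property
    def n_versions(self) -> int:
        return len(self.snapshots)

    def write_version(self, v: int) -> None:
        """Overwrite the bundle directory with version v's files."""
        self._states[v - 1].write()


def _random_events(
    bundle: Bundle, rng: random.Random, weights: dict[str, float], churn: float
) -> list[EvolutionEvent]:
    kinds = list(weights)
    w = [weights[k] for k in kinds]
    n_events = rng.randint(1, 3)
    chosen = []
    extra_counter = bundle.next_uid
    for _ in range(n_events):
        kind = rng.choices(kinds, weights=w, k=1)[0]
        n_rows = len(bundle.rows)
        extra_cols = [
            f.name for f in bundle.schema
            if f.name not in (UID_FIELD, "neuron_name", "brain_region")
        ]
        magnitude = max(1, round(churn * n_rows / n_events))
        if kind == "add_rows":
            chosen.append(EvolutionEvent("add_rows", {"n": magnitude}))
        elif kind == "edit_cells":
            if n_rows == 0:
                chosen.append(EvolutionEvent("add_rows", {"n": magnitude}))
            else:
                chosen.append(EvolutionEvent("edit_cells", {"n": magnitude}))
        elif kind == "delete_rows":
            if n_rows <= 2:
                chosen.append(EvolutionEvent("add_rows", {"n": magnitude}))
            else:
                chosen.append(
                    EvolutionEvent("delete_rows", {"n": min(magnitude, n_rows - 2)})
                )
        elif kind == "add_column":
            name = f"col_{extra_counter}"
            extra_counter += 1
            if any(f.name == name for f in bundle.schema):
                continue
            chosen.append(EvolutionEvent("add_column", {"name": name, "type": "text"}))
        elif kind == "drop_column":
            candidates = [c for c in extra_cols if c != "notes"]
            if not candidates:
                chosen.append(EvolutionEvent("edit_cells", {"n": max(1, magnitude)})
                              if n_rows else EvolutionEvent("add_rows", {"n": 1}))
            else:
                chosen.append(
                    EvolutionEvent("drop_column", {"name": rng.choice(candidates)})
                )
        elif kind == "rename_column":
            candidates = [f.name for f in bundle.schema if f.name != UID_FIELD]
            if not candidates:
                chosen.append(EvolutionEvent("add_rows", {"n": 1}))
            else:
                old = rng.choice(candidates)
                chosen.append(
                    EvolutionEvent("rename_column",
                                   {"old": old, "new": f"{old}_r{extra_counter}"})
                )
                extra_counter += 1
    # at most one structural event per transition keeps the expected
    # schema-delta ordering trivially well-defined
    deduped, structural_seen = [], False
    for e in chosen:
        if e.kind in _SCHEMA_OP_ORDER:
            if structural_seen:
                continue
            structural_seen = True
        deduped.append(e)
    return deduped


def generate_history(
    seed: int,
    n_versions: int,
    out_dir: str | Path,
    weights: dict[str, float] | None = None,
    n_records: int = 8,
    churn: float = 0.25,
    digest_mode: bool = False,
    pathological: bool = False,
    **bundle_kwargs,
) -> History:
    """Chain ``evolve`` into a deterministic multi-version history."""
    if n_versions < 1:
        raise ValidationError("n_versions must be >= 1")
    weights = dict(weights or DEFAULT_WEIGHTS)
    rng = random.Random(seed)
    bundle = generate_resource(
        seed, n_records, out_dir, digest_mode=digest_mode,
        pathological=pathological, **bundle_kwargs,
    )
    history = History(
        bundle=bundle,
        snapshots={1: bundle.canonical_rows()},
        schemas={1: bundle.schema_pairs()},
        steps=[],
        _states=[copy.deepcopy(bundle)],
    )
    for v in range(2, n_versions + 1):
        for _attempt in range(20):
            events = _random_events(bundle, rng, weights, churn)
            try:
                candidate, step = evolve(bundle, events, seed=rng.randrange(2**31))
            except GenerationError:
                continue
            if not step.changeset.is_empty:
                break
        else:  # pragma: no cover
            raise GenerationError("could not produce a non-empty transition")
        bundle = candidate
        history.bundle = bundle
        history.snapshots[v] = bundle.canonical_rows()
        history.schemas[v] = bundle.schema_pairs()
        history.steps.append(step)
        history._states.append(copy.deepcopy(bundle))
    return history
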