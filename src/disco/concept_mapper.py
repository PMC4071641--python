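"""Lexical term mapping against a loaded vocabulary.

Matching is tiered and purely lexical — exact label, normalized label,
exact synonym, normalized synonym — with no fuzzy matching: uncertain
cases stay unmapped for curators.  Normalization lowercases, trims,
collapses internal whitespace, and strips surrounding punctuation.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .errors import NotFoundError, ParseError, UsageError, ValidationError
from .store import Store

TIERS = ("exact", "normalized", "synonym", "synonym_normalized")

_WS_RE = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    collapsed = _WS_RE.sub(" ", raw.strip())
    return collapsed.strip(string.punctuation + " ").lower()


@dataclass
class VocabularyEntry:
    term_id: str
    label: str
    synonyms: list[str] = field(default_factory=list)
    category: str = ""


class Vocabulary:
    """Term index loaded from a delimited text file:

    ``term_id <TAB> label <TAB> syn1|syn2 <TAB> category``
    """

    def __init__(self, entries: list[VocabularyEntry]):
        seen = set()
        for e in entries:
            if not e.label:
                raise ValidationError(f"term {e.term_id!r} has an empty label")
            if e.term_id in seen:
                raise ValidationError(f"duplicate term id {e.term_id!r}")
            seen.add(e.term_id)
        self.entries = entries
        self._exact: dict[str, list[str]] = {}
        self._norm: dict[str, list[str]] = {}
        self._syn_exact: dict[str, list[str]] = {}
        self._syn_norm: dict[str, list[str]] = {}
        for e in entries:
            self._exact.setdefault(e.label, []).append(e.term_id)
            self._norm.setdefault(normalize_term(e.label), []).append(e.term_id)
            for syn in e.synonyms:
                self._syn_exact.setdefault(syn, []).append(e.term_id)
                self._syn_norm.setdefault(normalize_term(syn), []).append(e.term_id)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        entries = []
        try:
            lines = Path(path).read_text(encoding="utf-8").splitlines()
        except OSError as exc:
            raise ParseError(f"cannot read vocabulary {path}: {exc}") from exc
        for n, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(
                    f"vocabulary line {n}: expected at least term_id and label"
                )
            term_id, label = parts[0], parts[1]
            synonyms = [s for s in parts[2].split("|") if s] if len(parts) > 2 else []
            category = parts[3] if len(parts) > 3 else ""
            entries.append(VocabularyEntry(term_id, label, synonyms, category))
        return cls(entries)


@dataclass
class MapResult:
    raw: str
    tier: str                   # one of TIERS or "unmapped"
    candidates: list[str]       # term ids at the best achieved tier, sorted


def map_term(raw: str, vocabulary: Vocabulary) -> MapResult:
    """Rank candidate term ids for a raw string; pure and deterministic."""
    tiers = (
        ("exact", vocabulary._exact.get(raw)),
        ("normalized", vocabulary._norm.get(normalize_term(raw))),
        ("synonym", vocabulary._syn_exact.get(raw)),
        ("synonym_normalized", vocabulary._syn_norm.get(normalize_term(raw))),
    )
    for tier, hits in tiers:
        if hits:
            return MapResult(raw, tier, sorted(set(hits)))
    return MapResult(raw, "unmapped", [])


@dataclass
class TermMapping:
    resource_id: str
    field: str
    raw_term: str
    term_id: str | None
    tier: str
    version: int


class ConceptMapper:
    def __init__(self, store: Store, versions):
        self.store = store
        self.versions = versions

    def map_resource_terms(
        self, resource_id: str, vocabulary: Vocabulary
    ) -> tuple[list[TermMapping], list[tuple[str, int]]]:
        """Map distinct values of every term-kind column of the production
        version; persist mappings keyed to that version.

        Returns the mappings plus the unmapped report: distinct unmapped
        terms, most frequent first, ties broken by term ascending.
        """
        script = self.versions.production_script(resource_id)
        if script is None:
            raise NotFoundError(f"resource {resource_id!r} has no production version")
        term_fields = [f.name for f in script.fields if f.content_kind == "term"]
        if not term_fields:
            raise UsageError(
                f"resource {resource_id!r} declares no term-valued fields"
            )
        version = self.versions.current_version(resource_id)
        rows = self.versions.production_rows(resource_id)
        self.store.conn.execute(
            "DELETE FROM term_mappings WHERE resource_id = ? AND version = ?",
            (resource_id, version),
        )
        mappings: list[TermMapping] = []
        unmapped_counts: Counter = Counter()
        for fname in term_fields:
            counts: Counter = Counter()
            for rec in rows:
                value = rec.get(fname)
                if value:
                    counts[value] += 1
            for raw in sorted(counts):
                result = map_term(raw, vocabulary)
                term_id = result.candidates[0] if result.candidates else None
                mappings.append(
                    TermMapping(resource_id, fname, raw, term_id, result.tier, version)
                )
                if term_id is None:
                    unmapped_counts[raw] += counts[raw]
        self.store.conn.executemany(
            "INSERT INTO term_mappings (resource_id, field, raw_term, term_id,"
            " tier, version) VALUES (?, ?, ?, ?, ?, ?)",
            [
                (m.resource_id, m.field, m.raw_term, m.term_id, m.tier, m.version)
                for m in mappings
            ],
        )
        self.store.conn.commit()
        unmapped = sorted(unmapped_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return mappings, unmapped

    def mapping_report(self, resource_id: str) -> dict:
        rows = self.store.conn.execute(
            "SELECT * FROM term_mappings WHERE resource_id = ?"
            " ORDER BY version, field, raw_term",
            (resource_id,),
        ).fetchall()
        if not rows:
            raise NotFoundError(f"no term mappings recorded for {resource_id!r}")
        total = len(rows)
        mapped = sum(1 for r in rows if r["term_id"] is not None)
        return {
            "resource_id": resource_id,
            "total_terms": total,
            "mapped": mapped,
            "coverage": mapped / total if total else 0.0,
            "mappings": [
                {
                    "field": r["field"], "raw": r["raw_term"],
                    "term_id": r["term_id"], "tier": r["tier"],
                    "version": r["version"],
                }
                for r in rows
            ],
        }
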