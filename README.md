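# disco-aggregator

A data-aggregation engine for federating tabular resources into a curated
warehouse. Resources are registered from XML information files, harvested on
a schedule via declarative extraction scripts (CSV/TSV/XML/JSON sources),
diffed against the current production version, and released through a
curator-gated pending → production lifecycle. History is kept with a
reverse-delta store (an entity–attribute–value layout plus full snapshots
for large rewrites) so any previous version of any resource can be
reconstructed exactly. Materialized multi-resource views with beta and
production channels, lexical concept mapping of term-valued columns, and
CLI dashboards sit on top.

## Layout

| Module | Responsibility |
| --- | --- |
| `disco.registry` | Catalog of resources, services, contacts (XML info files) |
| `disco.scripts` | Harvest scripts: parse, fetch, extract, type-coerce |
| `disco.staging` | Record identity (PK or content digest), temporary ingest relations, changeset computation |
| `disco.version_store` | Reverse data deltas, forward schema deltas, snapshot policy, version reconstruction |
| `disco.lifecycle` | Update runs, pending/approve/problem workflow, batch promotion, view cascade |
| `disco.views` | Materialized union views with provenance columns and beta/production channels |
| `disco.scheduler` | Weekly/biweekly/monthly/ad-hoc schedules, due queue, source probing |
| `disco.concept_mapper` | Tiered lexical term → vocabulary-id mapping |
| `disco.synth` | Deterministic evolving mock resources with constructive ground truth |
| `disco.dashboards` | Main / data-source / views dashboards and frequency/growth reports |
| `disco.cli` | `disco` command-line umbrella |

All state lives in one SQLite file; harvested relations are stored
generically (one JSON row per record) and named `<resource_id>_<table>`,
with staging relations suffixed `_v<k>_tmp`.

## CLI quick tour

```sh
disco --db warehouse.sqlite register path/to/info.xml
disco --db warehouse.sqlite harvest nif-0000-00001      # fetch → diff → pending
disco --db warehouse.sqlite review nif-0000-00001       # change summary + issues
disco --db warehouse.sqlite approve nif-0000-00001      # promote to production
disco --db warehouse.sqlite schedule set nif-0000-00001 --monthly 19 --at 14:00
disco --db warehouse.sqlite tick                        # run everything due
disco --db warehouse.sqlite reconstruct nif-0000-00001 -v 3 --out v3.csv
disco --db warehouse.sqlite view define view.json
disco --db warehouse.sqlite dashboard sources --json
disco synth --seed 7 --versions 5 --out bundle/         # mock evolving resource
```

An update run that finds no changes is recorded as `unchanged` (`[=]` in
the dashboards) and creates no version. A pending version with import
issues (type errors, duplicate keys, field overflows, incomplete import)
refuses promotion unless `--override` is given; the override is audited.

## Notes

- Deterministic by construction: extraction order, diff classification,
  sample selection, and all synthetic generation are seed-stable.
- The synthetic generator derives expected changesets from its own
  evolution events (row identity, not key matching), so it serves as an
  independent oracle for the diff engine and the version store.
- Dependencies are deliberately small: `click` and `PyYAML`; everything
  else is the standard library.
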