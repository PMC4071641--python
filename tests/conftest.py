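import csv
import json
from pathlib import Path

import pytest

from disco import Disco

TOY_FIELDS = [
    {"name": "id", "type": "integer"},
    {"name": "neuron_name", "type": "text", "kind": "term"},
    {"name": "brain_region", "type": "text", "kind": "term"},
]

V1_ROWS = [
    {"id": "1", "neuron_name": "pyramidal cell", "brain_region": "CA1"},
    {"id": "2", "neuron_name": "granule cell", "brain_region": "dentate gyrus"},
    {"id": "3", "neuron_name": "Purkinje cell", "brain_region": "cerebellum"},
]

# v1 -> v2: record 2 edited, record 3 deleted, record 4 added
V2_ROWS = [
    {"id": "1", "neuron_name": "pyramidal cell", "brain_region": "CA1"},
    {"id": "2", "neuron_name": "granule cell", "brain_region": "DG"},
    {"id": "4", "neuron_name": "stellate cell", "brain_region": "neocortex"},
]


def write_source_csv(path: Path, rows: list[dict], fields=None) -> None:
    fields = fields or TOY_FIELDS
    header = [f["name"] for f in fields]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in rows:
            writer.writerow([row.get(c, "") for c in header])


def write_script(path: Path, source_name: str, fields=None, primary_key=("id",),
                 link_template=None, fmt="csv", record_selector="", **extra) -> None:
    fields = fields or TOY_FIELDS
    doc = {
        "resource": extra.get("resource", "nif-0000-00001"),
        "table": extra.get("table", "neurons"),
        "sources": [
            {
                "locator": source_name,
                "format": fmt,
                "record_selector": record_selector,
                "fields": {f["name"]: f["name"] for f in fields},
            }
        ],
        "fields": fields,
        "primary_key": list(primary_key),
    }
    if link_template:
        doc["link_template"] = link_template
    path.write_text(json.dumps(doc, indent=2), encoding="utf-8")


def write_info(path: Path, nif_id="nif-0000-00001", name="ToyNeuronDB",
               script="script.json", services=("interop",)) -> None:
    service_lines = "\n".join(
        f'  <service type="{s}" script="{script}"/>' for s in services
    )
    path.write_text(
        f'<resource id="{nif_id}" name="{name}">\n'
        f'  <contact name="Jo Curator" email="jo@example.org"/>\n'
        f"{service_lines}\n"
        f"  <description>A toy neuron database.</description>\n"
        f"</resource>\n",
        encoding="utf-8",
    )


def make_toy_resource(root: Path, rows=None, nif_id="nif-0000-00001",
                      name="ToyNeuronDB", fields=None, primary_key=("id",),
                      services=("interop",)) -> Path:
    """Write a complete bundle (csv + script + info) and return the info path."""
    root.mkdir(parents=True, exist_ok=True)
    write_source_csv(root / "data.csv", rows if rows is not None else V1_ROWS, fields)
    write_script(root / "script.json", "data.csv", fields, primary_key,
                 resource=nif_id)
    write_info(root / "info.xml", nif_id=nif_id, name=name, services=services)
    return root / "info.xml"


@pytest.fixture
def engine():
    eng = Disco()
    yield eng
    eng.close()


@pytest.fixture
def toy_resource(tmp_path):
    """A registered 3-row resource at version-1 source state."""
    info = make_toy_resource(tmp_path / "toy")
    return info


@pytest.fixture
def registered(engine, toy_resource):
    engine.registry.register_resource(toy_resource)
    return engine


def advance_source(info_path: Path, rows) -> None:
    write_source_csv(info_path.parent / "data.csv", rows)


def promote_toy(engine, info_path: Path, rows=None) -> None:
    """Run one update (optionally rewriting the source first) and approve it."""
    if rows is not None:
        advance_source(info_path, rows)
    run = engine.lifecycle.run_update("nif-0000-00001")
    assert run.outcome == "new_pending", run.error
    engine.lifecycle.approve("nif-0000-00001")
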