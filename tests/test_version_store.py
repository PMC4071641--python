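import pytest

from disco.errors import ConflictError, NotFoundError, UsageError
from disco.staging import ChangeSet
from disco.store import canonical_row_key
from disco.synth import generate_history
from disco.version_store import SchemaDelta, apply_schema_deltas, record_schema_change

from .conftest import V1_ROWS, V2_ROWS, make_toy_resource, promote_toy


RID = "nif-0000-00001"


def run_history(engine, history, approve=True):
    """Drive the real pipeline over every version of a synthetic history."""
    history.write_version(1)
    engine.registry.register_resource(history.bundle.info_path)
    rid = history.bundle.nif_id
    for v in range(1, history.n_versions + 1):
        history.write_version(v)
        run = engine.lifecycle.run_update(rid)
        assert run.outcome == "new_pending", run.error
        if approve:
            engine.lifecycle.approve(rid)
    return rid


class TestPromote:
    def test_fixture_v1_v2_triggers_snapshot(self, registered, toy_resource):
        # 1 add + 1 delete + 1 modify over 3 production rows: fraction 1.0
        promote_toy(registered, toy_resource)
        promote_toy(registered, toy_resource, V2_ROWS)
        report = registered.versions.storage_report(RID)
        assert report[0]["snapshot"] is True
        assert report[0]["delta_rows"] == 0

    def test_small_edit_stores_single_set_field_delta(self, engine, tmp_path):
        rows = [{"id": str(i), "neuron_name": "cell", "brain_region": "CA1"}
                for i in range(100)]
        info = make_toy_resource(tmp_path / "big", rows=rows)
        engine.registry.register_resource(info)
        promote_toy(engine, info)
        edited = [dict(r) for r in rows]
        edited[7]["brain_region"] = "CA3"
        promote_toy(engine, info, edited)
        report = engine.versions.storage_report(RID)
        assert report[0] == {
            "version": 1, "delta_rows": 1, "snapshot": False,
            "is_production": False, "byte_estimate": report[0]["byte_estimate"],
        }
        row = engine.store.conn.execute("SELECT * FROM data_deltas").fetchone()
        assert row["op"] == "set_field"
        assert row["attribute"] == "brain_region"

    def test_empty_changeset_refused(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        staged = registered.staging
        with pytest.raises(UsageError):
            registered.versions.promote(
                type("S", (), {"base_version": 1, "resource_id": RID,
                               "relation": "x"})(),
                ChangeSet(unchanged_count=3), None,
            )

    def test_stale_changeset_conflict(self, registered, toy_resource):
        from disco.scripts import parse_script

        promote_toy(registered, toy_resource)
        script = parse_script(toy_resource.parent / "script.json")
        stale = type("S", (), {"base_version": 0, "resource_id": RID,
                               "relation": "nonexistent"})()
        with pytest.raises(ConflictError):
            registered.versions.promote(
                stale, ChangeSet(added={1}), script
            )

    def test_version_increments_by_one(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        assert registered.versions.current_version(RID) == 1
        promote_toy(registered, toy_resource, V2_ROWS)
        assert registered.versions.current_version(RID) == 2

    def test_failed_promotion_leaves_store_unchanged(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        before = registered.store.checksum()
        stale = type("S", (), {"base_version": 5, "resource_id": RID,
                               "relation": "x"})()
        with pytest.raises(ConflictError):
            registered.versions.promote(stale, ChangeSet(added={1}), None)
        assert registered.store.checksum() == before


class TestReconstruct:
    def test_current_version_is_production(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        rows, schema = registered.versions.reconstruct_version(RID, 1)
        assert rows == sorted(
            registered.versions.production_rows(RID), key=canonical_row_key
        )
        assert [c[0] for c in schema] == ["id", "neuron_name", "brain_region"]

    def test_fixture_v1_recovered_after_v2(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        promote_toy(registered, toy_resource, V2_ROWS)
        rows, _ = registered.versions.reconstruct_version(RID, 1)
        assert rows == sorted(V1_ROWS, key=canonical_row_key)

    def test_out_of_range_not_found(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        with pytest.raises(NotFoundError):
            registered.versions.reconstruct_version(RID, 0)
        with pytest.raises(NotFoundError):
            registered.versions.reconstruct_version(RID, 2)

    def test_five_version_random_history_round_trips(self, engine, tmp_path):
        history = generate_history(23, 5, tmp_path / "h")
        rid = run_history(engine, history)
        for v in range(1, 6):
            rows, schema = engine.versions.reconstruct_version(rid, v)
            assert rows == history.snapshots[v], f"version {v}"
            assert schema == history.schemas[v]

    def test_digest_mode_history_round_trips(self, engine, tmp_path):
        history = generate_history(29, 5, tmp_path / "h", digest_mode=True)
        rid = run_history(engine, history)
        for v in range(1, 6):
            rows, _ = engine.versions.reconstruct_version(rid, v)
            assert rows == history.snapshots[v], f"version {v}"


class TestSchemaDeltas:
    OLD = [["id", "integer"], ["brain_region", "text"]]

    def test_add_column(self):
        new = self.OLD + [["species", "text"]]
        deltas = record_schema_change(self.OLD, new)
        assert [(d.op, d.payload) for d in deltas] == [
            ("add_column", ("species", "text"))
        ]

    def test_identity_empty(self):
        assert record_schema_change(self.OLD, [list(c) for c in self.OLD]) == []

    def test_declared_rename(self):
        new = [["id", "integer"], ["region", "text"]]
        deltas = record_schema_change(self.OLD, new, {"brain_region": "region"})
        assert [(d.op, d.payload) for d in deltas] == [
            ("rename_column", ("brain_region", "region"))
        ]

    def test_undeclared_rename_is_drop_plus_add(self):
        new = [["id", "integer"], ["region", "text"]]
        deltas = record_schema_change(self.OLD, new)
        assert [(d.op, d.payload) for d in deltas] == [
            ("drop_column", ("brain_region",)),
            ("add_column", ("region", "text")),
        ]

    def test_change_type(self):
        new = [["id", "text"], ["brain_region", "text"]]
        deltas = record_schema_change(self.OLD, new)
        assert [(d.op, d.payload) for d in deltas] == [
            ("change_type", ("id", "integer", "text"))
        ]

    def test_forward_replay_reproduces_new_schema(self):
        new = [["id", "integer"], ["region", "text"], ["species", "text"]]
        deltas = record_schema_change(self.OLD, new, {"brain_region": "region"})
        assert apply_schema_deltas(self.OLD, deltas) == new

    def test_replay_invariant_on_random_histories(self, engine, tmp_path):
        weights = {"add_rows": 0.3, "edit_cells": 0.2, "add_column": 0.2,
                   "drop_column": 0.15, "rename_column": 0.15}
        history = generate_history(31, 6, tmp_path / "h", weights=weights)
        rid = run_history(engine, history)
        for v in range(1, 7):
            assert engine.versions.schema_at(rid, v) == history.schemas[v]


class TestStorageReport:
    def test_single_version_zero_deltas(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        report = registered.versions.storage_report(RID)
        assert len(report) == 1
        assert report[0]["delta_rows"] == 0
        assert report[0]["is_production"]

    def test_counts_sum_to_total_delta_rows(self, engine, tmp_path):
        history = generate_history(37, 6, tmp_path / "h")
        rid = run_history(engine, history)
        report = engine.versions.storage_report(rid)
        total = engine.store.conn.execute(
            "SELECT COUNT(*) FROM data_deltas"
        ).fetchone()[0]
        assert sum(r["delta_rows"] for r in report) == total

    def test_unknown_resource_not_found(self, engine):
        with pytest.raises(NotFoundError):
            engine.versions.storage_report("nif-9999-99999")


class TestDeltaEconomy:
    def test_delta_rows_equal_change_magnitude_below_threshold(self, engine, tmp_path):
        rows = [{"id": str(i), "neuron_name": "cell", "brain_region": "CA1"}
                for i in range(40)]
        info = make_toy_resource(tmp_path / "r", rows=rows)
        engine.registry.register_resource(info)
        promote_toy(engine, info)
        evolved = [dict(r) for r in rows]
        evolved[0]["brain_region"] = "CA3"       # 1 field change
        evolved[1]["neuron_name"] = "basket"     # 1 field change
        del evolved[2]                           # 1 delete
        evolved.append({"id": "100", "neuron_name": "new", "brain_region": "DG"})
        promote_toy(engine, info, evolved)       # fraction 4/40 <= 0.5
        report = engine.versions.storage_report(RID)
        assert report[0]["snapshot"] is False
        assert report[0]["delta_rows"] == 2 + 1 + 1
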