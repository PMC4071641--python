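import random

import pytest

from disco import Disco
from disco.errors import ConflictError, NotFoundError, UsageError

from .conftest import (
    V1_ROWS,
    V2_ROWS,
    advance_source,
    make_toy_resource,
    promote_toy,
    write_source_csv,
)

RID = "nif-0000-00001"


class TestRunUpdate:
    def test_first_run_pends_with_all_added(self, registered):
        run = registered.lifecycle.run_update(RID)
        assert run.outcome == "new_pending"
        summary = registered.lifecycle.review(RID)
        assert summary["changes"]["added"] == 3

    def test_rerun_identical_source_is_unchanged(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        run = registered.lifecycle.run_update(RID)
        assert run.outcome == "unchanged"
        assert registered.staging.in_flight(RID) is None
        assert registered.versions.current_version(RID) == 1

    def test_missing_source_fails(self, registered, toy_resource):
        (toy_resource.parent / "data.csv").unlink()
        run = registered.lifecycle.run_update(RID)
        assert run.outcome == "failed"
        assert "not found" in run.error

    def test_run_refused_while_pending(self, registered):
        registered.lifecycle.run_update(RID)
        with pytest.raises(ConflictError):
            registered.lifecycle.run_update(RID)

    def test_unchanged_creates_no_versions_or_deltas(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        before = registered.store.conn.execute(
            "SELECT COUNT(*) FROM data_deltas"
        ).fetchone()[0]
        registered.lifecycle.run_update(RID)
        after = registered.store.conn.execute(
            "SELECT COUNT(*) FROM data_deltas"
        ).fetchone()[0]
        assert before == after
        assert registered.versions.current_version(RID) == 1

    def test_run_record_always_appended(self, registered, toy_resource):
        registered.lifecycle.run_update(RID)
        registered.lifecycle.approve(RID)
        registered.lifecycle.run_update(RID)
        (toy_resource.parent / "data.csv").unlink()
        registered.lifecycle.run_update(RID)
        outcomes = [r.outcome for r in registered.lifecycle.runs(RID)]
        assert outcomes == ["failed", "unchanged", "new_pending"]


class TestReview:
    def test_pending_fixture_summary(self, registered, toy_resource):
        promote_toy(registered, toy_resource)
        advance_source(toy_resource, V2_ROWS)
        registered.lifecycle.run_update(RID)
        summary = registered.lifecycle.review(RID)
        changes = summary["changes"]
        assert (changes["added"], changes["deleted"], changes["modified"]) == (1, 1, 1)
        assert len(changes["samples"]["modified"]) == 1

    def test_duplicate_key_issues_reported(self, registered, toy_resource):
        rows = list(V1_ROWS) + [dict(V1_ROWS[0]), dict(V1_ROWS[1])]
        advance_source(toy_resource, rows)
        registered.lifecycle.run_update(RID)
        summary = registered.lifecycle.review(RID)
        assert summary["issues"]["duplicate_key"] == 2

    def test_nothing_pending_not_found(self, registered):
        with pytest.raises(NotFoundError):
            registered.lifecycle.review(RID)


class TestApprove:
    def test_clean_immediate_promotes(self, registered):
        registered.lifecycle.run_update(RID)
        assert registered.lifecycle.approve(RID) == "production"
        assert registered.versions.current_version(RID) == 1

    def test_blocking_issue_refused_without_override(self, registered, toy_resource):
        advance_source(toy_resource, list(V1_ROWS) + [dict(V1_ROWS[0])])
        registered.lifecycle.run_update(RID)
        with pytest.raises(UsageError) as exc:
            registered.lifecycle.approve(RID)
        assert "duplicate_key" in str(exc.value)
        assert registered.versions.current_version(RID) == 0

    def test_override_promotes_and_is_logged(self, registered, toy_resource):
        advance_source(toy_resource, list(V1_ROWS) + [dict(V1_ROWS[0])])
        registered.lifecycle.run_update(RID)
        registered.lifecycle.approve(RID, override=True)
        assert registered.versions.current_version(RID) == 1
        events = [r["event"] for r in registered.store.conn.execute(
            "SELECT event FROM audit_log")]
        assert "approve_override" in events

    def test_batch_then_flush_promotes_exactly_once(self, registered):
        registered.lifecycle.run_update(RID)
        assert registered.lifecycle.approve(RID, mode="batch") == "scheduled"
        assert registered.versions.current_version(RID) == 0
        assert registered.lifecycle.flush_batch() == [RID]
        assert registered.versions.current_version(RID) == 1
        assert registered.lifecycle.flush_batch() == []
        assert registered.versions.current_version(RID) == 1


class TestMarkProblem:
    def test_problem_records_note(self, registered):
        registered.lifecycle.run_update(RID)
        registered.lifecycle.mark_problem(RID, "values look shifted")
        staged = registered.store.conn.execute(
            "SELECT status, note FROM staged_versions ORDER BY id DESC LIMIT 1"
        ).fetchone()
        assert staged["status"] == "problem"
        assert staged["note"] == "values look shifted"

    def test_problem_version_never_promotes(self, registered):
        registered.lifecycle.run_update(RID)
        registered.lifecycle.mark_problem(RID, "bad")
        assert registered.lifecycle.flush_batch() == []
        with pytest.raises(NotFoundError):
            registered.lifecycle.approve(RID)
        assert registered.versions.current_version(RID) == 0

    def test_new_run_allowed_after_problem(self, registered):
        registered.lifecycle.run_update(RID)
        registered.lifecycle.mark_problem(RID, "bad")
        run = registered.lifecycle.run_update(RID)
        assert run.outcome == "new_pending"

    def test_problem_staged_relation_retained(self, registered):
        registered.lifecycle.run_update(RID)
        staged = registered.staging.in_flight(RID)
        registered.lifecycle.mark_problem(RID, "bad")
        assert registered.store.relation_exists(staged.relation)


class TestCascadeViews:
    def _two_resources(self, engine, tmp_path):
        info1 = make_toy_resource(tmp_path / "r1")
        info2 = make_toy_resource(tmp_path / "r2", nif_id="nif-0000-00002",
                                  name="OtherDB")
        engine.registry.register_resource(info1)
        engine.registry.register_resource(info2)
        promote_toy(engine, info1)
        engine.lifecycle.run_update("nif-0000-00002")
        engine.lifecycle.approve("nif-0000-00002")
        return info1, info2

    def _define(self, engine, name, members):
        engine.views.define_view({
            "name": name,
            "columns": ["cell", "region"],
            "members": [
                {"resource": rid,
                 "map": {"cell": "neuron_name", "region": "brain_region"}}
                for rid in members
            ],
        })

    def test_only_referencing_views_regenerate(self, engine, tmp_path):
        info1, _ = self._two_resources(engine, tmp_path)
        self._define(engine, "v_both", [RID, "nif-0000-00002"])
        self._define(engine, "v_other", ["nif-0000-00002"])
        regenerated = engine.lifecycle.cascade_views(RID)
        assert regenerated == ["v_both"]

    def test_no_views_empty_list(self, engine, tmp_path):
        self._two_resources(engine, tmp_path)
        assert engine.lifecycle.cascade_views(RID) == []

    def test_cascade_updates_beta_not_production(self, engine, tmp_path):
        info1, _ = self._two_resources(engine, tmp_path)
        self._define(engine, "v1", [RID])
        self._define(engine, "v2", [RID])
        for name in ("v1", "v2"):
            engine.views.materialize_view(name, "beta")
            engine.views.approve_view(name)
        promote_toy(engine, info1, V2_ROWS)   # approve() cascades
        for v in engine.views.list_views():
            assert v.beta_mat > v.prod_mat


def lifecycle_invariants(engine, rid):
    """Invariants checked after every operation of a random sequence."""
    in_flight = engine.store.conn.execute(
        "SELECT COUNT(*) FROM staged_versions WHERE resource_id = ?"
        " AND status IN ('pending', 'approved', 'scheduled')",
        (rid,),
    ).fetchone()[0]
    assert in_flight <= 1, "single-pending invariant violated"


class TestLifecycleStateMachine:
    """Random operation sequences preserve the state-machine invariants."""

    OPS = ("run", "approve", "approve_batch", "approve_override", "flush",
           "problem", "evolve", "revert")

    def _sequence(self, tmp_path, seed, n_ops=20):
        rng = random.Random(seed)
        engine = Disco()
        info = make_toy_resource(tmp_path / f"seq{seed}")
        engine.registry.register_resource(info)
        prev_version = 0
        rows = [dict(r) for r in V1_ROWS]
        for _step in range(n_ops):
            op = rng.choice(self.OPS)
            had_blocking = False
            staged = engine.staging.in_flight(RID)
            if staged is not None:
                had_blocking = bool(staged.issues)
            try:
                if op == "run":
                    run = engine.lifecycle.run_update(RID)
                    if run.outcome == "unchanged":
                        assert engine.versions.current_version(RID) == prev_version
                elif op == "approve":
                    engine.lifecycle.approve(RID)
                    assert not had_blocking, "blocking issues promoted w/o override"
                elif op == "approve_batch":
                    engine.lifecycle.approve(RID, mode="batch")
                    assert not had_blocking
                elif op == "approve_override":
                    engine.lifecycle.approve(RID, override=True)
                elif op == "flush":
                    engine.lifecycle.flush_batch()
                elif op == "problem":
                    engine.lifecycle.mark_problem(RID, "suspicious")
                elif op == "evolve":
                    i = rng.randrange(len(rows))
                    rows[i] = dict(rows[i], brain_region=f"R{rng.randrange(99)}")
                    if rng.random() < 0.3:
                        rows.append({"id": str(10 + len(rows)),
                                     "neuron_name": "x", "brain_region": "y"})
                    if rng.random() < 0.2:   # duplicate key -> blocking issue
                        rows.append(dict(rows[0]))
                    write_source_csv(info.parent / "data.csv", rows)
                elif op == "revert":
                    rows = [dict(r) for r in V1_ROWS]
                    write_source_csv(info.parent / "data.csv", rows)
            except (ConflictError, NotFoundError, UsageError):
                pass
            lifecycle_invariants(engine, RID)
            version = engine.versions.current_version(RID)
            assert version >= prev_version, "production version decreased"
            prev_version = version
        engine.close()

    @pytest.mark.parametrize("seed", range(30))
    def test_random_sequences(self, tmp_path, seed):
        self._sequence(tmp_path, seed)


class TestAuditLog:
    def test_every_transition_audited(self, registered, toy_resource):
        registered.lifecycle.run_update(RID)
        registered.lifecycle.approve(RID)
        events = [r["event"] for r in registered.store.conn.execute(
            "SELECT event FROM audit_log ORDER BY id")]
        assert "resource_registered" in events
        assert "run_new_pending" in events
        assert "approved" in events
        assert "promoted" in events

    def test_audit_log_append_only_ids(self, registered):
        registered.lifecycle.run_update(RID)
        ids = [r["id"] for r in registered.store.conn.execute(
            "SELECT id FROM audit_log ORDER BY id")]
        assert ids == sorted(ids)
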