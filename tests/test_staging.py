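import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disco.errors import ConflictError
from disco.scripts import script_from_dict
from disco.staging import (
    ChangeSet,
    MissingKeyValue,
    RecordKey,
    content_digest,
    diff_records,
    record_key,
    summarize_changes,
)

from .conftest import TOY_FIELDS, V1_ROWS, V2_ROWS


def toy_script(primary_key=("id",)):
    return script_from_dict({
        "resource": "nif-0000-00001", "table": "neurons",
        "sources": [{"locator": "d.csv", "format": "csv",
                     "fields": {f["name"]: f["name"] for f in TOY_FIELDS}}],
        "fields": TOY_FIELDS,
        "primary_key": list(primary_key),
    })


def brute_force_diff(staged_rows, production_rows, pk):
    """Independent nested-loop diff oracle over raw records."""
    cs = ChangeSet()

    def key_of(row):
        return tuple(row[f] for f in pk) if pk else content_digest(row)

    for new in staged_rows:
        match = None
        for old in production_rows:
            if key_of(old) == key_of(new):
                match = old
                break
        if match is None:
            cs.added.add(RecordKey.from_pk(key_of(new)) if pk
                         else RecordKey.from_digest(key_of(new)))
            continue
        entries = []
        for fname in sorted(set(match) | set(new)):
            if match.get(fname) != new.get(fname):
                entries.append((fname, match.get(fname), new.get(fname)))
        if entries:
            cs.modified[RecordKey.from_pk(key_of(new)) if pk
                        else RecordKey.from_digest(key_of(new))] = entries
        else:
            cs.unchanged_count += 1
    for old in production_rows:
        if not any(key_of(new) == key_of(old) for new in staged_rows):
            cs.deleted.add(RecordKey.from_pk(key_of(old)) if pk
                           else RecordKey.from_digest(key_of(old)))
    return cs


class TestRecordKey:
    def test_pk_tuple(self):
        key = record_key(toy_script(), V1_ROWS[1])
        assert key == RecordKey.from_pk(("2",))

    def test_digest_invariant_under_field_order(self):
        rec = {"a": "1", "b": "2", "c": "3"}
        permuted = {"c": "3", "a": "1", "b": "2"}
        assert content_digest(rec) == content_digest(permuted)

    def test_digest_sensitive_to_single_character(self):
        # oracle: direct hash comparison of two one-character-apart records
        a = {"id": "1", "name": "granule cell"}
        b = {"id": "1", "name": "granule celL"}
        assert content_digest(a) != content_digest(b)

    def test_missing_pk_value_raises(self):
        with pytest.raises(MissingKeyValue):
            record_key(toy_script(), {"neuron_name": "x"})
        with pytest.raises(MissingKeyValue):
            record_key(toy_script(), {"id": "", "neuron_name": "x"})

    def test_missing_field_distinct_from_empty_string(self):
        assert content_digest({"a": "", "b": "x"}) != content_digest({"b": "x"})


class TestStageIngest:
    def test_clean_ingest(self, registered):
        staged = registered.staging.stage_ingest(
            "nif-0000-00001", toy_script(), list(V1_ROWS)
        )
        assert staged.record_count == 3
        assert staged.issues == []
        assert staged.version_number == 1
        assert staged.relation.endswith("_v1_tmp")

    def test_duplicate_keys_quarantined_first_kept(self, registered):
        rows = list(V1_ROWS) + [dict(V1_ROWS[1], neuron_name="imposter")]
        staged = registered.staging.stage_ingest(
            "nif-0000-00001", toy_script(), rows
        )
        assert staged.record_count == 3
        assert [i.kind for i in staged.issues] == ["duplicate_key"]
        kept = registered.store.read_rows(staged.relation)
        assert any(r["neuron_name"] == "granule cell" for r in kept)
        assert not any(r["neuron_name"] == "imposter" for r in kept)

    def test_interrupted_write_marked_incomplete(self, registered):
        staged = registered.staging.stage_ingest(
            "nif-0000-00001", toy_script(), list(V1_ROWS), _fail_after_rows=1
        )
        assert staged.record_count == 1
        assert "incomplete_import" in [i.kind for i in staged.issues]

    def test_concurrent_staged_version_conflict(self, registered):
        registered.staging.stage_ingest("nif-0000-00001", toy_script(), list(V1_ROWS))
        with pytest.raises(ConflictError):
            registered.staging.stage_ingest(
                "nif-0000-00001", toy_script(), list(V1_ROWS)
            )


class TestComputeChanges:
    def _diff(self, staged_rows, production_rows, pk=("id",)):
        script = toy_script(pk)
        staged = {record_key(script, r): r for r in staged_rows}
        prod = {record_key(script, r): r for r in production_rows}
        return diff_records(staged, prod)

    def test_identity(self):
        cs = self._diff(V1_ROWS, V1_ROWS)
        assert cs.is_empty
        assert cs.unchanged_count == 3

    def test_fixture_v1_v2_matches_brute_force_oracle(self):
        cs = self._diff(V2_ROWS, V1_ROWS)
        oracle = brute_force_diff(V2_ROWS, V1_ROWS, ["id"])
        assert cs == oracle
        assert cs.added == {RecordKey.from_pk(("4",))}
        assert cs.deleted == {RecordKey.from_pk(("3",))}
        assert cs.modified == {
            RecordKey.from_pk(("2",)): [("brain_region", "dentate gyrus", "DG")]
        }
        assert cs.unchanged_count == 1

    def test_digest_mode_edit_is_add_plus_delete(self):
        edited = [dict(V1_ROWS[0]), dict(V1_ROWS[1], brain_region="DG"),
                  dict(V1_ROWS[2])]
        cs = self._diff(edited, V1_ROWS, pk=())
        oracle = brute_force_diff(edited, V1_ROWS, [])
        assert cs == oracle
        assert len(cs.added) == 1 and len(cs.deleted) == 1
        assert cs.modified == {}

    def test_first_version_all_added(self):
        cs = self._diff(V1_ROWS, [])
        assert len(cs.added) == 3
        assert not cs.deleted and not cs.modified

    def test_cardinality_invariants(self):
        cs = self._diff(V2_ROWS, V1_ROWS)
        assert len(V2_ROWS) == len(cs.added) + len(cs.modified) + cs.unchanged_count
        assert len(V1_ROWS) == len(cs.deleted) + len(cs.modified) + cs.unchanged_count

    def test_symmetry(self):
        fwd = self._diff(V2_ROWS, V1_ROWS)
        back = self._diff(V1_ROWS, V2_ROWS)
        assert fwd.added == back.deleted
        assert fwd.deleted == back.added
        assert set(fwd.modified) == set(back.modified)
        for key, entries in fwd.modified.items():
            assert back.modified[key] == [(f, n, o) for f, o, n in entries]
        assert fwd.unchanged_count == back.unchanged_count


record_strategy = st.dictionaries(
    st.sampled_from(["id", "a", "b", "c"]),
    st.text(min_size=0, max_size=6),
    min_size=1,
)


@st.composite
def keyed_relations(draw):
    n_old = draw(st.integers(0, 6))
    n_new = draw(st.integers(0, 6))

    def rows(n, salt):
        out = []
        for i in range(n):
            rec = {"id": str(i)}
            rec.update(draw(st.dictionaries(
                st.sampled_from(["a", "b"]), st.text(max_size=4), max_size=2)))
            out.append(rec)
        return out

    return rows(n_new, "n"), rows(n_old, "o")


class TestDiffProperties:
    @settings(max_examples=100, deadline=None)
    @given(keyed_relations())
    def test_matches_brute_force_oracle(self, relations):
        staged_rows, prod_rows = relations
        script = toy_script(("id",))
        staged = {record_key(script, r): r for r in staged_rows}
        prod = {record_key(script, r): r for r in prod_rows}
        assert diff_records(staged, prod) == brute_force_diff(
            list(staged.values()), list(prod.values()), ["id"]
        )

    @settings(max_examples=60, deadline=None)
    @given(keyed_relations())
    def test_key_sets_pairwise_disjoint_and_conserved(self, relations):
        staged_rows, prod_rows = relations
        script = toy_script(("id",))
        staged = {record_key(script, r): r for r in staged_rows}
        prod = {record_key(script, r): r for r in prod_rows}
        cs = diff_records(staged, prod)
        assert not (cs.added & cs.deleted)
        assert not (cs.added & set(cs.modified))
        assert not (cs.deleted & set(cs.modified))
        assert len(staged) == len(cs.added) + len(cs.modified) + cs.unchanged_count
        assert len(prod) == len(cs.deleted) + len(cs.modified) + cs.unchanged_count

    @settings(max_examples=60, deadline=None)
    @given(st.lists(record_strategy, max_size=6))
    def test_self_diff_empty_in_digest_mode(self, rows):
        keyed = {RecordKey.from_digest(content_digest(r)): r for r in rows}
        cs = diff_records(keyed, dict(keyed))
        assert cs.is_empty
        assert cs.unchanged_count == len(keyed)


class TestSummarizeChanges:
    def test_empty_changeset(self):
        summary = summarize_changes(ChangeSet(unchanged_count=3))
        assert summary["is_unchanged"]
        assert (summary["added"], summary["deleted"], summary["modified"]) == (0, 0, 0)

    def test_fixture_counts(self):
        script = toy_script()
        staged = {record_key(script, r): r for r in V2_ROWS}
        prod = {record_key(script, r): r for r in V1_ROWS}
        summary = summarize_changes(diff_records(staged, prod))
        assert (summary["added"], summary["deleted"], summary["modified"]) == (1, 1, 1)
        assert len(summary["samples"]["modified"]) == 1

    def test_sample_truncation_deterministic(self):
        cs = ChangeSet(added={RecordKey.from_pk((str(i),)) for i in range(100)})
        summary = summarize_changes(cs, max_samples=5)
        assert summary["added"] == 100
        assert len(summary["samples"]["added"]) == 5
        assert summary["samples"]["added"] == sorted(summary["samples"]["added"])
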