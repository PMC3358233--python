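import pytest
from hypothesis import given, strategies as st

from immunomart.errors import LinkageError
from immunomart.linkage import (LinkSession, commit, map_equals, map_pair,
                                open_session, replay_transforms,
                                strip_phrase)
from immunomart.warehouse import (AliquotFact, AnalyteRecord, PersonRecord,
                                  SampleRecord, SourceRecord)


@pytest.fixture()
def linked_setup(mem_store):
    """Store with 3 decorated aliquot IDs, 3 samples, 2 persons."""
    akey = mem_store.upsert_analyte(AnalyteRecord("IL-6", "luminex"))
    skey = mem_store.insert_source(SourceRecord(
        "lum.csv", "h1", "2011-01-01", "Human Luminex 51plex"))
    facts = [AliquotFact(f"HIMC-S00{i}_A", akey, skey, float(i), "MFI")
             for i in range(1, 4)]
    mem_store.insert_facts(facts)
    for i in range(1, 4):
        mem_store.upsert_sample(SampleRecord(f"S00{i}", day=0))
    for i in range(1, 3):
        mem_store.upsert_person(PersonRecord(f"P00{i}"))
    return mem_store


class TestOpenSession:
    def test_children_are_unmapped_aliquots(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        assert set(sess.children) == {"HIMC-S001_A", "HIMC-S002_A",
                                      "HIMC-S003_A"}
        assert len(sess.parents) == 3
        # working strings start verbatim
        assert all(ext == w for ext, w in sess.children.values())

    def test_source_filter_limits_children(self, linked_setup):
        akey = linked_setup.upsert_analyte(AnalyteRecord("TNF", "msd"))
        s2 = linked_setup.insert_source(SourceRecord(
            "msd.csv", "h2", "2011-01-02", "MSD 4plex"))
        linked_setup.insert_facts(
            [AliquotFact("OTHER-1", akey, s2, 5.0, "pg/ml")])
        sess = open_session(linked_setup, "aliquot_sample",
                            {"assay": "MSD 4plex"})
        assert set(sess.children) == {"OTHER-1"}

    def test_empty_filter_result_gives_empty_session(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample",
                            {"assay": "no-such-assay"})
        assert sess.children == {}

    def test_fully_mapped_store_gives_empty_session(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        strip_phrase(sess, "child", "HIMC-")
        strip_phrase(sess, "child", "_A")
        map_equals(sess)
        commit(sess, linked_setup)
        assert open_session(linked_setup, "aliquot_sample").children == {}


class TestTransforms:
    def test_strip_prefix_and_suffix(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        strip_phrase(sess, "child", "HIMC-")
        strip_phrase(sess, "child", "_A")
        assert {w for _, w in sess.children.values()} == {"S001", "S002",
                                                          "S003"}
        # external IDs untouched
        assert {e for e, _ in sess.children.values()} == {
            "HIMC-S001_A", "HIMC-S002_A", "HIMC-S003_A"}

    def test_empty_phrase_rejected(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        with pytest.raises(LinkageError):
            strip_phrase(sess, "child", "")

    def test_absent_phrase_is_identity(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        before = {k: list(v) for k, v in sess.children.items()}
        strip_phrase(sess, "child", "ZZZ")
        assert {k: list(v) for k, v in sess.children.items()} == before

    def test_strip_is_per_occurrence(self):
        sess = LinkSession(level="aliquot_sample",
                           children={"AB-AB-1": ["AB-AB-1", "AB-AB-1"]})
        strip_phrase(sess, "child", "AB-")
        assert sess.children["AB-AB-1"][1] == "1"

    @given(st.text(min_size=1, max_size=20),
           st.lists(st.text(min_size=1, max_size=3), max_size=4))
    def test_working_strings_replayable_from_transform_log(self, ext,
                                                           phrases):
        sess = LinkSession(level="aliquot_sample",
                           children={"k": [ext, ext]})
        for p in phrases:
            strip_phrase(sess, "child", p)
        replayed = replay_transforms(ext, sess.transforms, "child")
        assert replayed == sess.children["k"][1]

    def test_transforms_are_per_side(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        strip_phrase(sess, "parent", "S0")
        assert {w for _, w in sess.parents.values()} == {"01", "02", "03"}
        assert all(w.startswith("HIMC-") for _, w in sess.children.values())


class TestMapEquals:
    def test_single_match_proposed(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        strip_phrase(sess, "child", "HIMC-")
        strip_phrase(sess, "child", "_A")
        map_equals(sess)
        assert len(sess.proposed) == 3
        assert not sess.ambiguous

    def test_duplicate_parent_working_string_left_unproposed(self):
        sess = LinkSession(level="aliquot_sample",
                           children={"c1": ["c1", "S001"]},
                           parents={1: ["S001a", "S001"],
                                    2: ["S001b", "S001"]})
        map_equals(sess)
        assert sess.proposed == {}
        assert sess.ambiguous == {"c1": [1, 2]}

    def test_no_match_left_unproposed(self):
        sess = LinkSession(level="aliquot_sample",
                           children={"c1": ["c1", "XYZ"]},
                           parents={1: ["S001", "S001"]})
        map_equals(sess)
        assert sess.proposed == {}


class TestMapPair:
    def test_manual_pair(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        map_pair(sess, "HIMC-S001_A", 1)
        assert sess.proposed["HIMC-S001_A"] == 1

    def test_remap_requires_override(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        map_pair(sess, "HIMC-S001_A", 1)
        with pytest.raises(LinkageError, match="override"):
            map_pair(sess, "HIMC-S001_A", 2)
        map_pair(sess, "HIMC-S001_A", 2, override=True)
        assert sess.proposed["HIMC-S001_A"] == 2

    def test_unknown_keys_rejected(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        with pytest.raises(LinkageError):
            map_pair(sess, "nope", 1)
        with pytest.raises(LinkageError):
            map_pair(sess, "HIMC-S001_A", 999)


class TestCommit:
    def _prepared(self, store):
        sess = open_session(store, "aliquot_sample")
        strip_phrase(sess, "child", "HIMC-")
        strip_phrase(sess, "child", "_A")
        return map_equals(sess)

    def test_commit_updates_fks_and_audits(self, linked_setup):
        sess = self._prepared(linked_setup)
        summary = commit(sess, linked_setup)
        assert summary.pairs_committed == 3
        assert linked_setup.integrity_report().facts_unmapped == 0
        audits = linked_setup.execute(
            "SELECT action FROM audit WHERE action LIKE 'link_commit%'"
        ).fetchall()
        assert audits

    def test_commit_empty_session_rejected(self, linked_setup):
        sess = open_session(linked_setup, "aliquot_sample")
        with pytest.raises(LinkageError, match="no proposed pairs"):
            commit(sess, linked_setup)

    def test_concurrent_mapping_aborts_whole_commit(self, linked_setup):
        sess = self._prepared(linked_setup)
        other = self._prepared(linked_setup)
        commit(other, linked_setup)  # simulate a concurrent session
        with pytest.raises(LinkageError, match="concurrently"):
            commit(sess, linked_setup)
        # atomicity: counts unchanged by the failed commit
        assert linked_setup.integrity_report().facts_unmapped == 0

    def test_sample_person_level(self, linked_setup):
        # samples S001..S003 -> persons P001, P002 by explicit pairs
        sess = open_session(linked_setup, "sample_person")
        assert len(sess.children) == 3
        pkeys = [k for k in sess.parents]
        for ckey in list(sess.children):
            map_pair(sess, ckey, pkeys[0])
        summary = commit(sess, linked_setup)
        assert summary.pairs_committed == 3
        assert linked_setup.integrity_report().samples_unmapped == 0


class TestSessionPersistence:
    def test_json_round_trip(self, linked_setup, tmp_path):
        sess = open_session(linked_setup, "aliquot_sample")
        strip_phrase(sess, "child", "HIMC-")
        strip_phrase(sess, "child", "_A")
        map_equals(sess)
        p = tmp_path / "session.json"
        sess.save(p)
        loaded = LinkSession.load(p)
        assert loaded.level == sess.level
        assert loaded.children == sess.children
        assert loaded.proposed == sess.proposed
        assert loaded.transforms == sess.transforms
        # a loaded session commits identically
        summary = commit(loaded, linked_setup)
        assert summary.pairs_committed == 3
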