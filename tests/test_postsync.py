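"""Post lifecycle: generation, release sync, archive and comment safety."""

from dataclasses import replace

import pytest

from pathatlas import postsync
from pathatlas.model import Entity, EntityClass
from pathatlas.postsync import (
    Comment,
    PostStatus,
    PostStore,
    StoreIntegrityError,
    UnknownKeyError,
    add_comment,
    generate_post,
    load_store,
    post_keys_for,
    save_store,
    sync_store,
)


class TestGeneratePost:
    def test_roles_listed_per_reaction(self, worked_example_doc):
        content = generate_post("entity-pr1", worked_example_doc)
        # Cdc25 is reactant (s1) and product (s2) of re1
        assert "REACTANT" in content and "PRODUCT" in content
        assert "re1" in content

    def test_catalyst_role_carries_subtype(self, worked_example_doc):
        content = generate_post("entity-pr3", worked_example_doc)
        assert "MODIFIER (CATALYSIS)" in content

    def test_entity_without_reactions_has_empty_section(self, worked_example_doc):
        doc = worked_example_doc
        doc.entities["lonely"] = Entity("lonely", EntityClass.PROTEIN, "Lonely")
        content = generate_post("entity-lonely", doc)
        assert "<h3>Reactions</h3><ul></ul>" in content

    def test_complex_forms_include_phospho_canonical_name(self, worked_example_doc):
        content = generate_post("entity-pr3", worked_example_doc)
        assert "Cdc13:Cdc2|Thr167_pho@cytoplasm" in content

    def test_map_link_per_state_and_reaction(self, worked_example_doc):
        content = generate_post("entity-pr1", worked_example_doc)
        assert content.count("map-link") >= 3  # two forms + one reaction

    def test_unknown_key(self, worked_example_doc):
        with pytest.raises(UnknownKeyError):
            generate_post("entity-nope", worked_example_doc)
        with pytest.raises(UnknownKeyError):
            generate_post("garbage", worked_example_doc)


def _store_for(doc):
    store, report = sync_store(PostStore(), doc)
    return store, report


class TestSync:
    def test_first_sync_creates_version1_active(self, worked_example_doc):
        store, report = _store_for(worked_example_doc)
        assert not report.updated and not report.archived
        for r in store.records:
            assert r.version == 1 and r.status is PostStatus.ACTIVE

    def test_identical_resync_changes_nothing(self, worked_example_doc, tmp_path):
        store, _ = _store_for(worked_example_doc)
        store2, report = sync_store(store, worked_example_doc)
        assert report.empty
        save_store(store, tmp_path / "a.json")
        save_store(store2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_removed_entity_archived_not_deleted(self, worked_example_doc):
        store, _ = _store_for(worked_example_doc)
        doc2 = worked_example_doc
        del doc2.entities["rn1"]
        del doc2.species_states["s5"]
        del doc2.aliases["a5"]
        del doc2.reactions["re2"]  # referenced s5
        store2, report = sync_store(store, doc2)
        assert "entity-rn1" in report.archived
        hist = store2.history("entity-rn1")
        assert len(hist) == 1 and hist[0].status is PostStatus.ARCHIVED

    def test_edited_annotation_archives_old_version_with_comments(
        self, worked_example_doc
    ):
        store, _ = _store_for(worked_example_doc)
        store = add_comment(
            store, "entity-pr1", Comment("reader", "2013-05-01", "missing ref")
        )
        doc2 = worked_example_doc
        doc2.entities["pr1"] = replace(
            doc2.entities["pr1"], annotation_text="References:\nPMID:23531408"
        )
        store2, report = sync_store(store, doc2)
        assert "entity-pr1" in report.updated
        hist = store2.history("entity-pr1")
        assert [r.version for r in hist] == [1, 2]
        assert hist[0].status is PostStatus.ARCHIVED
        assert hist[0].comments[0].text == "missing ref"
        assert hist[1].status is PostStatus.ACTIVE
        assert hist[1].comments == ()

    def test_layout_only_change_does_not_version(self, worked_example_doc):
        store, _ = _store_for(worked_example_doc)
        doc2 = worked_example_doc
        a1 = doc2.aliases["a1"]
        doc2.aliases["a1"] = replace(a1, bbox=(999.0, 999.0, 90.0, 36.0))
        _store2, report = sync_store(store, doc2)
        assert report.empty

    def test_corrupt_store_detected(self, worked_example_doc):
        store, _ = _store_for(worked_example_doc)
        store.records.append(store.records[0])  # duplicate ACTIVE
        with pytest.raises(StoreIntegrityError):
            sync_store(store, worked_example_doc)


class TestInvariants:
    def _releases(self, doc):
        """Three successive releases: edit pr1, remove rn1, re-add nothing."""
        import copy

        r1 = copy.deepcopy(doc)
        r2 = copy.deepcopy(r1)
        r2.entities["pr1"] = replace(
            r2.entities["pr1"], annotation_text="References:\nPMID:23531408"
        )
        r3 = copy.deepcopy(r2)
        del r3.entities["rn1"]
        del r3.species_states["s5"]
        del r3.aliases["a5"]
        del r3.reactions["re2"]
        return [r1, r2, r3]

    def test_monotone_history_and_comment_conservation(self, worked_example_doc):
        releases = self._releases(worked_example_doc)
        store = PostStore()
        store, _ = sync_store(store, releases[0])
        store = add_comment(store, "entity-pr1", Comment("u1", "t1", "c1"))
        store = add_comment(store, "entity-rn1", Comment("u2", "t2", "c2"))
        counts = [len(store.records)]
        for rel in releases[1:]:
            store, _ = sync_store(store, rel)
            counts.append(len(store.records))
        assert counts == sorted(counts)  # records never disappear
        all_comments = [
            c.text for r in store.records for c in r.comments
        ]
        assert sorted(all_comments) == ["c1", "c2"]

    def test_sync_idempotent(self, worked_example_doc):
        store, _ = sync_store(PostStore(), worked_example_doc)
        once, _ = sync_store(store, worked_example_doc)
        twice, _ = sync_store(once, worked_example_doc)
        assert once == twice


class TestPersistenceAndRender:
    def test_json_round_trip(self, worked_example_doc, tmp_path):
        store, _ = _store_for(worked_example_doc)
        store = add_comment(store, "entity-pr1", Comment("u", "t", "hello"))
        save_store(store, tmp_path / "store.json")
        assert load_store(tmp_path / "store.json") == store

    def test_missing_store_file_loads_empty(self, tmp_path):
        assert load_store(tmp_path / "absent.json") == PostStore()

    def test_render_active_and_archive_pages(self, worked_example_doc, tmp_path):
        store, _ = _store_for(worked_example_doc)
        doc2 = worked_example_doc
        doc2.entities["pr1"] = replace(
            doc2.entities["pr1"], annotation_text="changed"
        )
        store, _ = sync_store(store, doc2)
        written = postsync.render_posts(store, tmp_path / "posts")
        assert (tmp_path / "posts" / "entity-pr1.html").exists()
        assert (tmp_path / "posts" / "archive" / "entity-pr1-v1.html").exists()
        assert (tmp_path / "posts" / "archive" / "index.html").exists()
        assert "posts/archive/index.html" in written

    def test_all_doc_keys_covered(self, worked_example_doc):
        keys = post_keys_for(worked_example_doc)
        assert {"entity-pr1", "reaction-re1"} <= set(keys)

    def test_null_adapter_records_calls(self, worked_example_doc):
        adapter = postsync.NullBlogAdapter()
        store, _ = _store_for(worked_example_doc)
        for r in store.records:
            adapter.create_post(r)
        assert len(adapter.calls) == len(store.records)
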