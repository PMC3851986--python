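"""Atlas bundle assembly: pages, panel, callouts, search, link closure."""

import json
import re

import pytest

from pathatlas import fixtures, postsync, sitegen, zoomtiles
from pathatlas.sitegen import SiteBuildError, build_search_index, build_site, search


@pytest.fixture(scope="module")
def built(tmp_path_factory):
    """Fixture map built into a complete on-disk bundle (pages + posts)."""
    spec = fixtures.FixtureSpec(seed=1)
    doc, _xml = fixtures.make_map(spec)
    module_defs = sitegen.collect_modules(doc)
    modules = {
        m.module_name: fixtures.make_module_submap(doc, m.module_name,
                                                   m.member_states)
        for m in module_defs
    }
    views = fixtures.render_views(doc, k_levels=3, canvas=spec.canvas)
    pyramid = zoomtiles.build_pyramid(views)
    bundle = build_site(doc, modules, pyramid)
    out = tmp_path_factory.mktemp("bundle")
    sitegen.write_bundle(bundle, out)
    store, _report = postsync.sync_store(postsync.PostStore(), doc, modules)
    postsync.render_posts(store, out / "posts")
    return doc, modules, bundle, out


class TestBuildSite:
    def test_master_plus_modules_page_count(self, built):
        _doc, modules, bundle, _out = built
        assert set(bundle.pages) == {"index"} | {
            f"module-{m}" for m in modules
        }

    def test_no_modules_single_page(self, fixture_map):
        _spec, doc, _xml = fixture_map
        bundle = build_site(doc, {}, None)
        assert list(bundle.pages) == ["index"]
        assert bundle.pages["index"].module_names == []

    def test_entity_in_two_modules_gets_two_links(self, worked_example_doc):
        doc = worked_example_doc
        modules = {
            m.module_name: fixtures.make_module_submap(doc, m.module_name,
                                                       m.member_states)
            for m in sitegen.collect_modules(doc)
        }
        bundle = build_site(doc, modules, None)
        # Cdc2 declares membership of both CellCycle and Checkpoint
        cdc2_callouts = [
            c for c in bundle.pages["index"].callouts if c.canonical_name == "Cdc2"
        ]
        assert cdc2_callouts
        assert sorted(cdc2_callouts[0].module_links) == ["CellCycle", "Checkpoint"]

    def test_dangling_module_assignment_is_build_error(self, worked_example_doc):
        with pytest.raises(SiteBuildError, match="CellCycle"):
            build_site(worked_example_doc, {"OtherModule": worked_example_doc}, None)

    def test_every_alias_has_exactly_one_callout(self, built):
        doc, _modules, bundle, _out = built
        callout_aliases = [c.alias_id for c in bundle.pages["index"].callouts]
        assert sorted(callout_aliases) == sorted(doc.aliases)

    def test_module_panel_lists_only_member_entities(self, built):
        _doc, modules, bundle, _out = built
        for name, sub in modules.items():
            page = bundle.pages[f"module-{name}"]
            panel_names = {
                n for g, names in page.panel.items() if g != "COMPLEX"
                for n in names
            }
            assert panel_names == {
                e.display_name for e in sub.entities.values()
            }

    def test_panel_union_equals_entity_set(self, built):
        doc, _modules, bundle, _out = built
        page = bundle.pages["index"]
        panel_names = {
            n for g, names in page.panel.items() if g != "COMPLEX" for n in names
        }
        assert panel_names == {e.display_name for e in doc.entities.values()}


class TestLinkClosure:
    def test_no_dangling_internal_links(self, built):
        _doc, _modules, _bundle, out = built
        html_files = list(out.rglob("*.html"))
        assert html_files
        missing = []
        for page in html_files:
            text = page.read_text()
            refs = re.findall(r'(?:href|src)="([^"]+)"', text)
            island = re.search(
                r'<script type="application/json" id="atlas-data">(.*?)</script>',
                text, re.S,
            )
            if island:
                data = json.loads(island.group(1))
                if data.get("tiles"):
                    lv = data["pyramid"]["levels"][-1]
                    refs.append(f"{data['tiles']}/{lv['level']}/0_0.png")
                    refs.append(f"{data['tiles']}/pyramid.json")
                for c in data.get("callouts", []):
                    refs.append(c["post"])
                    refs += [f"module-{m}.html" for m in c["modules"]]
            for ref in refs:
                if ref.startswith(("http:", "https:", "#", "mailto:")):
                    continue
                target = (page.parent / ref.split("#")[0]).resolve()
                if not target.exists():
                    missing.append(f"{page.name} -> {ref}")
        assert missing == []

    def test_cross_links_both_directions(self, built):
        _doc, modules, _bundle, out = built
        index_html = (out / "index.html").read_text()
        for name in modules:
            assert f"module-{name}.html" in index_html
            assert "index.html" in (out / f"module-{name}.html").read_text()


class TestSearch:
    @pytest.fixture
    def index(self, worked_example_doc):
        return build_search_index(worked_example_doc)

    def test_substring_matches_all_cdc_entries(self, index):
        names = {r.name for r in search(index, "cdc")}
        assert names == {"Cdc25", "Cdc13", "Cdc2"}

    def test_empty_query_matches_nothing(self, index):
        assert search(index, "") == []

    def test_no_match(self, index):
        assert search(index, "zzz") == []

    def test_annotation_words_searchable(self, index):
        assert {r.name for r in search(index, "18319725")} == {"Cdc25"}

    def test_deterministic_order_by_position_then_name(self, index):
        results = search(index, "cdc")
        assert [r.name for r in results] == sorted(
            [r.name for r in results],
            key=lambda n: (next(x.haystack.find("cdc") for x in results
                                if x.name == n), n),
        )

    def test_longer_query_narrows_hits(self, index):
        broad = {r.name for r in search(index, "cdc")}
        narrow = {r.name for r in search(index, "cdc2")}
        assert narrow <= broad
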