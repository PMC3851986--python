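"""Assemble the static atlas bundle.

``build_site`` turns a parsed master map, its module submaps and a tile
pyramid into a self-contained directory of HTML/JS/JSON/PNG files that
opens from local disk: one page for the master map plus one per module,
each carrying a pan/zoom tile viewer, a selection panel grouped by entity
class, substring search, per-alias callouts and per-entity annotation
pages.  Module pages list only the entities contained in that module, and
master and module pages cross-link both ways.

The interactive viewer itself is a fixed JS/CSS asset bundled verbatim;
generation only fills a JSON data island per page, so all map-specific
logic stays on the generator side.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as ann
from . import naming
from .model import CLASS_ORDER, EntityClass, MapDocument, ModuleDef
from .zoomtiles import TilePyramid, write_pyramid


class SiteBuildError(ValueError):
    pass


@dataclass(frozen=True)
class SearchRecord:
    entity_id: str
    name: str
    haystack: str  # lowercased name + synonyms + annotation words


@dataclass(frozen=True)
class CalloutRecord:
    alias_id: str
    canonical_name: str
    short_description: str
    identifiers_html: str
    module_links: tuple[str, ...]  # module names
    post_key: str
    anchor: tuple[float, float]  # bbox center at the most-detailed level


@dataclass
class PageData:
    page_name: str  # file stem, e.g. "index" or "module-M1"
    title: str
    doc: MapDocument
    panel: dict[str, list[str]]
    callouts: list[CalloutRecord]
    module_names: list[str]
    pyramid: TilePyramid | None


@dataclass
class SiteBundle:
    pages: dict[str, PageData]
    search_index: list[SearchRecord]
    post_keys: list[str]
    manifest: list[str] = field(default_factory=list)


def collect_modules(master: MapDocument) -> list[ModuleDef]:
    """Derive module membership from each entity's Maps_Modules section."""
    members: dict[str, set[str]] = {}
    for entity in master.entities.values():
        doc = ann.parse_annotation(entity.annotation_text)
        for mod_name in ann.extract_module_membership(doc):
            bucket = members.setdefault(mod_name, set())
            for state in master.states_of_entity(entity.entity_id):
                bucket.add(state.state_id)
    return [
        ModuleDef(module_name=n, member_states=members[n])
        for n in sorted(members)
    ]


def build_site(
    master: MapDocument,
    modules: dict[str, MapDocument],
    pyramid: TilePyramid | None,
    config: dict | None = None,
    module_pyramids: dict[str, TilePyramid] | None = None,
) -> SiteBundle:
    """Assemble all pages, callouts and the search index in memory.

    *modules* maps module name to its submap document.  When modules are
    supplied, every module an entity claims membership of must exist —
    a dangling assignment is a build error, not a silent omission.
    """
    config = config or {}
    module_pyramids = module_pyramids or {}
    registry = ann.TagRegistry().extend(config.get("tags", {}))

    module_defs = collect_modules(master)
    if modules:
        known = set(modules)
        offenders = [m.module_name for m in module_defs if m.module_name not in known]
        if offenders:
            raise SiteBuildError(
                "entities assigned to nonexistent modules: " + ", ".join(offenders)
            )
    else:
        module_defs = []

    membership: dict[str, list[str]] = {}  # state_id -> module names
    for mdef in module_defs:
        for sid in mdef.member_states:
            membership.setdefault(sid, []).append(mdef.module_name)

    post_keys = (
        [f"entity-{eid}" for eid in master.entities]
        + [f"module-{name}" for name in modules]
        + [f"reaction-{rid}" for rid in master.reactions]
    )

    pages: dict[str, PageData] = {}
    pages["index"] = _build_page(
        "index", master.name, master, pyramid, membership, registry,
        module_names=sorted(modules),
    )
    for mod_name in sorted(modules):
        sub = modules[mod_name]
        pages[f"module-{mod_name}"] = _build_page(
            f"module-{mod_name}",
            f"{master.name} — module {mod_name}",
            sub,
            module_pyramids.get(mod_name),
            membership,
            registry,
            module_names=sorted(modules),
        )

    search_index = build_search_index(master)
    return SiteBundle(pages=pages, search_index=search_index, post_keys=post_keys)


def _build_page(
    page_name: str,
    title: str,
    doc: MapDocument,
    pyramid: TilePyramid | None,
    membership: dict[str, list[str]],
    registry: ann.TagRegistry,
    module_names: list[str],
) -> PageData:
    panel = _panel_groups(doc)
    callouts = []
    for alias in doc.aliases.values():
        state = doc.species_states[alias.state_id]
        entity = doc.entities[state.components[0][0]]
        adoc = ann.parse_annotation(entity.annotation_text)
        callouts.append(
            CalloutRecord(
                alias_id=alias.alias_id,
                canonical_name=naming.format_name(state, doc),
                short_description=_short_description(adoc),
                identifiers_html=_identifiers_html(adoc, registry),
                module_links=tuple(membership.get(state.state_id, ())),
                post_key=f"entity-{entity.entity_id}",
                anchor=alias.center,
            )
        )
    return PageData(
        page_name=page_name,
        title=title,
        doc=doc,
        panel=panel,
        callouts=callouts,
        module_names=module_names,
        pyramid=pyramid,
    )


def _panel_groups(doc: MapDocument) -> dict[str, list[str]]:
    """Selection-panel groups in fixed class order; complex species get
    their own trailing group keyed by canonical name."""
    groups: dict[str, list[str]] = {}
    for ecls in CLASS_ORDER:
        if ecls is EntityClass.COMPLEX:
            continue
        names = sorted(
            e.display_name for e in doc.entities.values() if e.entity_class is ecls
        )
        if names:
            groups[ecls.value] = names
    complexes = sorted(
        naming.format_name(s, doc)
        for s in doc.species_states.values()
        if s.is_complex
    )
    if complexes:
        groups[EntityClass.COMPLEX.value] = complexes
    return groups


def _short_description(adoc: ann.AnnotationDoc) -> str:
    for section in adoc.sections:
        for line in section.body.split("\n"):
            line = line.strip()
            if line:
                return line[:200]
    return ""


def _identifiers_html(adoc: ann.AnnotationDoc, registry: ann.TagRegistry) -> str:
    sec = adoc.section("Identifiers")
    if sec is None:
        return ""
    return ann.expand_tags(sec.body, registry)


# ---------------------------------------------------------------------------
# search


def build_search_index(doc: MapDocument) -> list[SearchRecord]:
    """One record per entity: display name, canonical names of all its
    states, and the words of its annotation."""
    records = []
    for entity in doc.entities.values():
        state_names = " ".join(
            naming.format_name(s, doc) for s in doc.states_of_entity(entity.entity_id)
        )
        haystack = " ".join(
            [entity.display_name, state_names, entity.annotation_text]
        ).lower()
        records.append(
            SearchRecord(
                entity_id=entity.entity_id,
                name=entity.display_name,
                haystack=haystack,
            )
        )
    return sorted(records, key=lambda r: r.name)


def search(index: list[SearchRecord], query: str) -> list[SearchRecord]:
    """Case-insensitive substring search over names, canonical state names
    and annotation text; empty query matches nothing.  Results are ordered
    by match position, then name."""
    q = query.lower()
    if not q:
        return []
    hits = [(r.haystack.find(q), r) for r in index]
    return [r for pos, r in sorted(
        ((p, r) for p, r in hits if p >= 0), key=lambda t: (t[0], t[1].name)
    )]


# ---------------------------------------------------------------------------
# writing


def write_bundle(bundle: SiteBundle, out_dir: Path) -> list[str]:
    """Write the bundle to disk; returns the manifest of relative paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    (out_dir / "assets").mkdir(exist_ok=True)
    (out_dir / "assets" / "viewer.js").write_text(VIEWER_JS)
    (out_dir / "assets" / "style.css").write_text(STYLE_CSS)
    manifest += ["assets/viewer.js", "assets/style.css"]

    for page in bundle.pages.values():
        tiles_rel = None
        if page.pyramid is not None:
            tiles_dir = out_dir / "tiles" / page.page_name
            write_pyramid(page.pyramid, tiles_dir)
            tiles_rel = f"tiles/{page.page_name}"
            for (level, tx, ty) in page.pyramid.tiles:
                manifest.append(f"{tiles_rel}/{level}/{tx}_{ty}.png")
            manifest.append(f"{tiles_rel}/pyramid.json")
        html_text = _render_page(page, bundle, tiles_rel)
        (out_dir / f"{page.page_name}.html").write_text(html_text)
        manifest.append(f"{page.page_name}.html")

    bundle.manifest = manifest
    return manifest


def _render_page(page: PageData, bundle: SiteBundle, tiles_rel: str | None) -> str:
    data = {
        "title": page.title,
        "tiles": tiles_rel,
        "pyramid": page.pyramid.descriptor if page.pyramid else None,
        "panel": page.panel,
        "callouts": [
            {
                "alias": c.alias_id,
                "name": c.canonical_name,
                "description": c.short_description,
                "identifiers": c.identifiers_html,
                "modules": list(c.module_links),
                "post": f"posts/{c.post_key}.html",
                "anchor": list(c.anchor),
            }
            for c in page.callouts
        ],
        "search": [
            {"id": r.entity_id, "name": r.name, "text": r.haystack}
            for r in bundle.search_index
        ],
    }
    module_nav = "".join(
        f'<li><a href="module-{html.escape(m)}.html">{html.escape(m)}</a></li>'
        for m in page.module_names
    )
    module_section = (
        f'<nav class="modules"><h3>Modules</h3><ul>{module_nav}</ul></nav>'
        if page.module_names
        else ""
    )
    back = (
        '<p><a href="index.html">&larr; master map</a></p>'
        if page.page_name != "index"
        else ""
    )
    panel_html = []
    for group, names in page.panel.items():
        items = "".join(f"<li>{html.escape(n)}</li>" for n in names)
        panel_html.append(
            f'<section class="panel-group"><h4>{html.escape(group)}</h4>'
            f"<ul>{items}</ul></section>"
        )
    return PAGE_TEMPLATE.format(
        title=html.escape(page.title),
        back=back,
        module_section=module_section,
        panel="".join(panel_html),
        data=json.dumps(data),
    )


PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<link rel="stylesheet" href="assets/style.css">
</head>
<body>
<header><h1>{title}</h1>{back}</header>
<main>
<div id="map-viewport"></div>
<aside id="selection-panel">
<input id="search-box" type="search" placeholder="search entities">
<div id="search-results"></div>
{module_section}
{panel}
</aside>
</main>
<script type="application/json" id="atlas-data">{data}</script>
<script src="assets/viewer.js"></script>
</body>
</html>
"""

VIEWER_JS = r"""// minimal static tile viewer: pan, level switching, markers, callouts
(function () {
  var data = JSON.parse(document.getElementById('atlas-data').textContent);
  var vp = document.getElementById('map-viewport');
  if (data.pyramid) {
    var levels = data.pyramid.levels;
    var edge = data.pyramid.tile_edge;
    var cur = levels.length - 1;
    var ox = 0, oy = 0;
    var layer = document.createElement('div');
    layer.className = 'tile-layer';
    vp.appendChild(layer);
    function detailLevel() { return levels[levels.length - 1].level; }
    function scale(p, from, to) {
      var f = Math.pow(2, to - from);
      return [p[0] * f, p[1] * f];
    }
    function render() {
      layer.innerHTML = '';
      var lv = levels[cur];
      var nx = Math.ceil(lv.width / edge), ny = Math.ceil(lv.height / edge);
      for (var ty = 0; ty < ny; ty++)
        for (var tx = 0; tx < nx; tx++) {
          var img = document.createElement('img');
          img.src = data.tiles + '/' + lv.level + '/' + tx + '_' + ty + '.png';
          img.style.left = (tx * edge + ox) + 'px';
          img.style.top = (ty * edge + oy) + 'px';
          layer.appendChild(img);
        }
      data.callouts.forEach(function (c) {
        var p = scale(c.anchor, detailLevel(), lv.level);
        var marker = document.createElement('div');
        marker.className = 'marker';
        marker.style.left = (p[0] + ox) + 'px';
        marker.style.top = (p[1] + oy) + 'px';
        marker.title = c.name;
        marker.onclick = function () { showCallout(c); };
        layer.appendChild(marker);
      });
    }
    function showCallout(c) {
      var el = document.createElement('div');
      el.className = 'callout';
      el.innerHTML = '<b>' + c.name + '</b><p>' + c.description + '</p>' +
        '<p>' + c.identifiers + '</p>' +
        c.modules.map(function (m) {
          return '<a href="module-' + m + '.html">' + m + '</a> ';
        }).join('') +
        '<p><a href="' + c.post + '">annotation post</a></p>';
      vp.appendChild(el);
      el.onclick = function () { el.remove(); };
    }
    vp.addEventListener('wheel', function (e) {
      e.preventDefault();
      var next = cur + (e.deltaY < 0 ? 1 : -1);
      if (next >= 0 && next < levels.length) { cur = next; render(); }
    });
    var drag = null;
    vp.addEventListener('mousedown', function (e) { drag = [e.clientX, e.clientY]; });
    window.addEventListener('mouseup', function () { drag = null; });
    window.addEventListener('mousemove', function (e) {
      if (!drag) return;
      ox += e.clientX - drag[0]; oy += e.clientY - drag[1];
      drag = [e.clientX, e.clientY];
      render();
    });
    render();
  }
  // substring search over names and annotation text
  var box = document.getElementById('search-box');
  var out = document.getElementById('search-results');
  if (box) box.addEventListener('input', function () {
    var q = box.value.toLowerCase();
    out.innerHTML = '';
    if (!q) return;
    data.search
      .map(function (r) { return [r.text.indexOf(q), r]; })
      .filter(function (t) { return t[0] >= 0; })
      .sort(function (a, b) { return a[0] - b[0] || (a[1].name < b[1].name ? -1 : 1); })
      .forEach(function (t) {
        var d = document.createElement('div');
        d.textContent = t[1].name;
        out.appendChild(d);
      });
  });
})();
"""

STYLE_CSS = """body { font-family: sans-serif; margin: 0; }
header { padding: 0.5em 1em; background: #28426b; color: #fff; }
header a { color: #cdd9ef; }
main { display: flex; }
#map-viewport { position: relative; overflow: hidden; flex: 1; height: 80vh;
  background: #eee; }
.tile-layer img { position: absolute; }
.marker { position: absolute; width: 12px; height: 12px; border-radius: 50%;
  background: #d33; border: 2px solid #fff; cursor: pointer; }
.callout { position: absolute; left: 20%; top: 20%; background: #fff;
  border: 1px solid #888; padding: 0.8em; max-width: 24em; z-index: 10; }
#selection-panel { width: 22em; padding: 0 1em; overflow-y: auto;
  height: 80vh; }
.panel-group h4 { margin-bottom: 0.2em; }
.ann-section { padding: 0.4em; margin: 0.3em 0; }
"""
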