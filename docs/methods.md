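# Methods

## What the factory computes

`pathatlas` turns three curator-supplied inputs — a CellDesigner map file
(SBML Level 2 with the CellDesigner extension namespace), a chain of
semantic-zoom view images, and a JSON configuration — into a static web
atlas. The computation has four largely independent parts: parsing the
CellDesigner dialect into a typed map model; serializing species states
with the canonical naming grammar; validating and tiling the zoom views;
and generating the site bundle together with the versioned annotation-post
store. Rendering of the map imagery itself is deliberately *not* part of
the factory: semantic-zoom views are curated artwork (which molecular
detail survives at a coarse level is an editorial decision), so the tool
only validates, completes and tiles what the map manager provides.

## CellDesigner parsing

Only the CellDesigner 4.x dialect is accepted (`speciesAlias` /
`complexSpeciesAlias` layout elements). Files without the extension
namespace are rejected outright rather than partially parsed: every
downstream product (names, callouts, posts) depends on modification and
compartment detail that plain SBML does not carry, so a silent fallback
would corrupt the atlas rather than degrade it.

Parsing decisions worth knowing:

- Coordinates are taken verbatim from the file — pixels, top-left origin,
  y increasing downward — matching the canvas the zoom views are exported
  from. No unit conversion anywhere.
- Complex components keep the file's declaration order. The canonical name
  of a complex depends on component order, so determinism here matters.
- A species whose compartment is the SBML `default` pseudo-compartment is
  treated as having *no* compartment, and its canonical name carries no
  `@…` suffix.
- CellDesigner spells modification states in full (`phosphorylated`); the
  parser maps the known long forms to the short labels used in canonical
  names (`pho`, `ubi`, …) and passes unknown labels through verbatim, so
  the writer/parser pair round-trips exactly. State-label case is
  preserved as found; `Pho` and `pho` are distinct labels by design.
- An alias attached to a species that only exists inside a complex is
  recorded as a parser warning and skipped: components are drawn inside
  their complex alias, and a free-standing alias for one is ambiguous.
  Synthetic maps never generate this case.
- Entities of classes without reference entries in the file (small
  molecules, ions, phenotypes…) get deterministic synthesized ids of the
  form `<class>__<name>`.

The writer emits the same dialect. It exists for fixtures and round-trip
testing; `parse_map(write_map(doc))` reproduces `doc` up to element order,
which the test suite checks structurally.

## Naming grammar

`format_name` joins complex components with `:`, appends modifications
with `|` and the compartment with `@`. Within a modification token the
*last* `_`-separated field is the state label and everything before it the
residue label — this single rule covers both `Pho` (no residue) and
`Thr167_pho`. The residue position is the first maximal digit run in the
residue label. Reserved characters inside entity or compartment names are
an error, not escaped: escaping would silently produce names that no other
tool in this convention could parse back.

Multiple modifications on one component are emitted ordered by residue
position, then lexically. The grammar itself does not constrain order, so
formatting canonicalizes; `parse_name` preserves textual order, which makes
`format ∘ parse` the identity exactly on canonically ordered names. The
property test generates names through the formatter, which enforces that
canonical order.

## Annotations and identifier tags

The original structured-annotation convention's delimiter syntax is not
publicly specified, so one unambiguous convention is fixed and documented:
a section header is a line `NAME:` alone on a line; all text up to the next
header is the section body, kept verbatim (the section split provably
loses no characters). Text containing no header at all becomes a single
unsectioned block, so maps annotated in any other style still render.

Tag expansion recognizes `PREFIX:ID` for registered prefixes (`PMID`,
`HUGO`, `UNIPROT` ship by default; the config can add more) and
`@resource:id` for any resource of the MIRIAM identifier registry,
resolved through identifiers.org. The `@resource` form splits at the
*first* colon after the resource name, so identifiers that themselves
contain colons (`YEAST:G3O-30431`) stay intact. Unknown resources are left
as plain text with a logged warning — a dead link is worse than an
unexpanded tag. Expansion is idempotent: existing anchors are copied
verbatim and already-escaped entities are never re-escaped.

## Zoom views and tiles

The tiled-viewer contract imposes three checks on a view chain: exact
factor-2 size steps between consecutive levels (error), aspect-ratio
conservation (error — a pixel-level proxy for "objects must not move
between levels", which cannot be verified from rasters), and divisibility
of each level's dimensions by the 256-px tile edge. Divisibility is a
preference, not a requirement: violations are warnings and edge tiles are
padded with opaque white (CellDesigner exports have white canvases; the
fill is configurable). Dimensions smaller than one tile are exempt from
the warning — any half-size chain ends below 256 px and those levels are
simply padded into a single tile.

Level numbering is 0 = coarsest, increasing toward detail, matching slippy
map conventions. Intermediate levels are synthesized with Pillow's `BOX`
(area-average) filter, which is deterministic and alias-free for exact
factor-2 reductions; synthesized views carry `semantic=False` since no
content was re-drawn for them, and manager-supplied views are never
replaced. Marker anchors are alias bounding-box centers recorded once at
the most-detailed level; all other levels obtain positions by pure
scaling (`2^Δlevel`), so a marker never drifts when zooming.

## Site bundle

The generator emits plain HTML pages with one JSON data island each; the
interactive viewer is a fixed JS/CSS asset bundled verbatim. This keeps
all map-specific computation in Python and makes the bundle fully
self-contained (openable from `file://`, no server, no external API).
The selection panel lists every entity of the page's own document exactly
once, grouped in a fixed class order (proteins, genes, RNAs, antisense
RNAs, then the remaining classes, complexes last); module pages therefore
list only module members. Search is case-insensitive substring matching
over display names, canonical state names and annotation text, ordered by
match position then name; the empty query matches nothing. The master
map's source XML is copied into the bundle only when the config sets
`include_source_link` — publishing the source is the map manager's policy
decision, not the tool's.

## Post store

Change detection hashes the *generated* post content (annotation + forms +
reactions), not the raw XML, so releases that only move glyphs do not
create archive noise — and, symmetrically, editing only a species'
position never bumps a post version. Sync is a pure function from (store,
release) to (store, report): records are only added or flipped
ACTIVE→ARCHIVED, never deleted or edited, which gives the three store
invariants the tests enforce — idempotence, monotone record count, and
conservation of the comment multiset. Reactions get standalone posts
keyed by reaction id, since posts link reactions as first-class map
objects. Remote blog hosting is out of scope: the lifecycle runs on the
local JSON store and rendered static pages, and a remote-adapter interface
(`create/update/archive`) is defined with only a no-op implementation.

## Synthetic data

The fixture generator emulates the *structure* of a curated map: all four
primary entity classes plus small molecules, 2–3-component complexes,
residue-level phosphorylation (`Thr167_pho`-style) and residue-less
states (`Pho`), two compartments, catalyzed reactions, and sectioned
annotations with `PMID`, `HUGO`, `UNIPROT` and `@biocyc` tags. Defaults —
18 entities, 2 modules, 6 reactions, modification rate 0.4, a 2048×1024
canvas giving an exact four-level chain down to 256×128 — are sized like a
single pathway module of a published map rather than a full atlas, which
keeps every test and the end-to-end build fast while exercising each
structural feature at least once. Networks are wired uniformly at random:
no degree structure, no mass-action semantics, no biological meaning.
Rendering is schematic (colored rectangles and labels, not process-
description glyphs). Consequently, passing tests demonstrate structural
correctness of parsing, naming, tiling, linking and synchronization — they
say nothing about glyph-level fidelity on real curated artwork, about
maps drawn with CellDesigner versions other than the 4.x dialect, or
about performance on atlas-scale maps with thousands of species.

## Known limitations

- One dialect: CellDesigner 4.x only; older `speciesAlias`-less files and
  BioPAX are rejected (conversion is delegated to external tools).
- Gene/RNA region modifications are modeled with the same residue
  mechanism as proteins, a simplification of the dialect.
- The viewer asset is intentionally minimal (tile swap, drag, wheel zoom,
  markers, callouts); it is a stand-in for a full map-engine integration
  and carries no analytical tooling (no data overlay, no route finding).
- Posts and comments are trusted hypertext rendered as-is; moderation and
  authentication belong to the hosting platform, not the factory.
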