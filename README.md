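# pathatlas

Comprehensive maps of molecular interactions — hundreds of species, reactions
and complexes drawn in [CellDesigner](http://www.celldesigner.org/) — are
effectively unreadable as a single static image. `pathatlas` is a "map
factory" for curators of such maps: it converts a CellDesigner XML file plus
a set of semantic-zoom view images into a self-contained, navigable static
web atlas, in the style of a geographical slippy map. The atlas offers
tile-based pan/zoom over several semantic zoom levels, a selection panel
grouping every map element by entity class, substring search, persistent
markers with annotation callouts, per-module submaps cross-linked with the
master map, and a versioned store of per-entity annotation posts with an
archive that preserves superseded versions and their reader comments.

It is aimed at systems-biology map managers (curators who build and release
pathway maps) and, through the generated atlas, at the researchers who read
and comment on them.

## The core conventions

**Species naming.** Every species state is serialized with the
BiNoM-style grammar

```
name         := component (":" component)* ("@" compartment)?
component    := entity_name ("|" modification)*
modification := (residue_label "_")? state_label
```

so `Cdc25|Pho@cytoplasm` is phosphorylated Cdc25 in the cytoplasm, and
`Cdc13:Cdc2|Thr167_pho@cytoplasm` is the Cdc13:Cdc2 complex whose Cdc2
component is phosphorylated on threonine 167. `naming.format_name` and
`naming.parse_name` are exact inverses on conformant names.

**Semantic zooming.** A chain of views, level 0 the least detailed, where
level *L+1* is exactly twice the pixel size of level *L* and relative object
positions never move. Each level is cut into 256-px square tiles
(`ceil(w/256) × ceil(h/256)` per level, edges padded white); marker
coordinates move between levels by pure scaling, `(x,y) ↦ (x,y)·2^(Δlevel)`.
Missing intermediate levels are synthesized by factor-2 area-average
downscaling of the most detailed view.

**Annotations.** Entity annotations are structured in named sections
(`Identifiers`, `Maps_Modules`, `References`, or any user-defined name);
tokens such as `PMID:18319725`, `UNIPROT:P30304` or the registry form
`@biocyc:YEAST:G3O-30431` are expanded into hyperlinks. The `Maps_Modules`
section assigns entities to module submaps.

**Post lifecycle.** Each entity, module and reaction gets a generated post
(annotation, modification forms, reactions with roles, map links). Syncing
against a new map release archives posts for removed objects, versions
posts whose generated content changed (old version and its comments move to
the immutable archive), and leaves everything else untouched.

## Worked example

Everything below runs offline from a generated synthetic map:

```sh
pathatlas fixture --out fx --seed 1
pathatlas validate --config fx/config.json
pathatlas build --config fx/config.json --out fx/atlas
```

which prints

```
fixture written to fx (2 modules, 4 view levels)
OK: 4 view level(s), 18 entities
bundle written to fx/atlas (84 files)
```

The fixture is a map of 18 entities (proteins, genes, RNAs, an antisense
RNA, small molecules), 23 species states including 2 complexes, 6 reactions
and 2 modules on a 2048×1024 canvas with a 4-level zoom chain
(256×128 … 2048×1024). The build log reports
`3 pages, 43 tiles, 26 posts (26 added, 0 updated, 0 archived)`: one master
page plus two module pages; 43 tiles because the four levels contribute
1+2+8+32 tiles; and one post per entity (18), module (2) and reaction (6).
Open `fx/atlas/index.html` in a browser to pan, zoom, search and click
markers.

From Python:

```python
>>> from pathatlas import parse_name
>>> parse_name("Cdc13:Cdc2|Thr167_pho@cytoplasm").components[1].modifications[0]
ModificationState(state_label='pho', residue_label='Thr167', residue_position=167)
```

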