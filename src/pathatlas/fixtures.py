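"""Synthetic CellDesigner maps and rendered zoom views.

Everything the pipeline consumes — map XML, structured annotations, module
submaps, zoom-view rasters — can be generated deterministically from a
seed, so the whole factory is testable offline with no curated map.  The
generated networks are random (no biological realism is attempted) but
exercise every structural feature the parser and site generator handle:
all four primary entity classes plus small molecules, multi-component
complexes, residue-level modifications, compartments, reactions with
catalysts, and sectioned annotations carrying identifier tags.

Rendering is schematic — colored rectangles with labels, not proper
process-description glyphs — because the tiling and site layers only care
about raster geometry.  Coarser levels drop labels and then small glyphs,
emulating how a curated semantic-zoom chain sheds detail.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from PIL import Image, ImageDraw

from . import celldesigner
from .model import (
    Alias,
    Entity,
    EntityClass,
    MapDocument,
    ModificationState,
    Reaction,
    Role,
    SpeciesState,
)
from .zoomtiles import ZoomView

_CLASS_COLORS = {
    EntityClass.PROTEIN: (116, 160, 216),
    EntityClass.GENE: (232, 215, 110),
    EntityClass.RNA: (140, 200, 140),
    EntityClass.ANTISENSE_RNA: (200, 150, 200),
    EntityClass.SIMPLE_MOLECULE: (220, 220, 220),
}
_COMPLEX_COLOR = (180, 190, 230)
_COMPARTMENTS = ("cytoplasm", "nucleus")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic map.

    Defaults give a small but structurally complete map: a couple of dozen
    entities over two modules on a 2048x1024 canvas whose dimensions are
    powers of two times the 256 px tile edge, so a four-level zoom chain
    ending at a 256x128 top view is exact.
    """

    n_proteins: int = 8
    n_genes: int = 4
    n_rnas: int = 3
    n_antisense: int = 1
    n_simple_molecules: int = 2
    n_complexes: int = 2
    n_reactions: int = 6
    n_modules: int = 2
    modification_rate: float = 0.4
    canvas: tuple[int, int] = (2048, 1024)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_proteins", "n_genes", "n_rnas", "n_antisense",
            "n_simple_molecules", "n_complexes", "n_reactions", "n_modules",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.modification_rate <= 1.0):
            raise ValueError("modification_rate must be in [0, 1]")


def make_map(spec: FixtureSpec) -> tuple[MapDocument, bytes]:
    """Build a synthetic map and its CellDesigner XML serialization.

    Deterministic: the same spec (including seed) yields byte-identical
    XML.  Generated maps always reparse without warnings.
    """
    rng = random.Random(spec.seed)
    doc = MapDocument(name=f"synthetic_map_{spec.seed}")
    module_names = [f"M{i + 1}" for i in range(spec.n_modules)]

    entity_plan = (
        [(EntityClass.PROTEIN, f"Prot{i + 1}") for i in range(spec.n_proteins)]
        + [(EntityClass.GENE, f"Gene{i + 1}") for i in range(spec.n_genes)]
        + [(EntityClass.RNA, f"Rna{i + 1}") for i in range(spec.n_rnas)]
        + [(EntityClass.ANTISENSE_RNA, f"Asr{i + 1}") for i in range(spec.n_antisense)]
        + [
            (EntityClass.SIMPLE_MOLECULE, f"Mol{i + 1}")
            for i in range(spec.n_simple_molecules)
        ]
    )

    counters = {EntityClass.PROTEIN: 0, EntityClass.GENE: 0, EntityClass.RNA: 0,
                EntityClass.ANTISENSE_RNA: 0}
    prefix = {EntityClass.PROTEIN: "pr", EntityClass.GENE: "gn",
              EntityClass.RNA: "rn", EntityClass.ANTISENSE_RNA: "ar"}
    for i, (ecls, name) in enumerate(entity_plan):
        if ecls in counters:
            counters[ecls] += 1
            eid = f"{prefix[ecls]}{counters[ecls]}"
        else:
            eid = celldesigner.synth_entity_id(ecls, name)
        modules = _assign_modules(rng, module_names)
        doc.entities[eid] = Entity(
            entity_id=eid,
            entity_class=ecls,
            display_name=name,
            annotation_text=_make_annotation(rng, name, modules),
        )

    proteins = [e for e in doc.entities.values()
                if e.entity_class is EntityClass.PROTEIN]

    # one species state per entity; some entities get a modified second state
    sid = 0
    for entity in list(doc.entities.values()):
        sid += 1
        compartment = rng.choice(_COMPARTMENTS + (None,))
        doc.species_states[f"s{sid}"] = SpeciesState(
            state_id=f"s{sid}",
            components=((entity.entity_id, ()),),
            compartment=compartment,
        )
        if (
            entity.entity_class is EntityClass.PROTEIN
            and rng.random() < spec.modification_rate
        ):
            sid += 1
            mod = _random_modification(rng)
            doc.species_states[f"s{sid}"] = SpeciesState(
                state_id=f"s{sid}",
                components=((entity.entity_id, (mod,)),),
                compartment=compartment,
            )

    # complexes of 2-3 proteins, with an occasional modified component
    for _c in range(spec.n_complexes):
        if len(proteins) < 2:
            break
        members = rng.sample(proteins, k=min(len(proteins), rng.choice((2, 3))))
        components = []
        for m in members:
            mods = (
                (_random_modification(rng),)
                if rng.random() < spec.modification_rate
                else ()
            )
            components.append((m.entity_id, tuple(mods)))
        sid += 1
        doc.species_states[f"s{sid}"] = SpeciesState(
            state_id=f"s{sid}",
            components=tuple(components),
            compartment=rng.choice(_COMPARTMENTS),
        )

    _layout_aliases(doc, spec)

    state_ids = list(doc.species_states)
    for r in range(spec.n_reactions):
        if len(state_ids) < 2:
            break
        reactant, product = rng.sample(state_ids, k=2)
        participants = [(reactant, Role.REACTANT), (product, Role.PRODUCT)]
        subtypes = []
        if rng.random() < 0.5 and len(state_ids) > 2:
            modifier = rng.choice(
                [s for s in state_ids if s not in (reactant, product)]
            )
            participants.append((modifier, Role.MODIFIER))
            subtypes.append((modifier, "CATALYSIS"))
        doc.reactions[f"re{r + 1}"] = Reaction(
            reaction_id=f"re{r + 1}",
            participants=tuple(participants),
            modifier_subtypes=tuple(subtypes),
        )

    xml = celldesigner.write_map(doc)
    parsed = celldesigner.parse_map(xml, name=doc.name)
    return parsed, xml


def _assign_modules(rng: random.Random, module_names: list[str]) -> list[str]:
    if not module_names:
        return []
    # each entity belongs to >=1 module; occasional double membership
    picked = [rng.choice(module_names)]
    if len(module_names) > 1 and rng.random() < 0.25:
        other = rng.choice([m for m in module_names if m != picked[0]])
        picked.append(other)
    return picked


def _make_annotation(rng: random.Random, name: str, modules: list[str]) -> str:
    lines = [
        "Identifiers:",
        f"HUGO:{name.upper()} UNIPROT:P{rng.randrange(10000, 99999)} "
        f"@biocyc:YEAST:G3O-{rng.randrange(10000, 99999)}",
    ]
    if modules:
        lines += ["Maps_Modules:", ", ".join(modules)]
    lines += [
        "References:",
        f"PMID:{rng.randrange(10000000, 30000000)} described the role of "
        f"{name} in this pathway.",
    ]
    return "\n".join(lines)


def _random_modification(rng: random.Random) -> ModificationState:
    if rng.random() < 0.5:
        residue = f"{rng.choice(('Thr', 'Ser', 'Tyr'))}{rng.randrange(10, 999)}"
        return ModificationState(state_label="pho", residue_label=residue)
    return ModificationState(state_label="Pho")


def _layout_aliases(doc: MapDocument, spec: FixtureSpec) -> None:
    """Place one alias per species on a regular grid inside the canvas."""
    w, h = spec.canvas
    box_w, box_h = 90, 36
    margin = 30
    cols = max(1, (w - margin) // (box_w + margin))
    for i, state in enumerate(doc.species_states.values()):
        col, row = i % cols, i // cols
        x = margin + col * (box_w + margin)
        y = margin + row * (box_h + margin)
        if y + box_h > h:  # wrap around rather than overflow the canvas
            y = margin + (row % max(1, (h - margin) // (box_h + margin))) * (
                box_h + margin
            )
        doc.aliases[f"a{i + 1}"] = Alias(
            alias_id=f"a{i + 1}",
            state_id=state.state_id,
            bbox=(float(x), float(y), float(box_w), float(box_h)),
        )


def make_module_submap(doc: MapDocument, module_name: str,
                       member_states: set[str]) -> MapDocument:
    """A simplified standalone layout for one module: member species only,
    re-laid on a compact grid, keeping reactions internal to the module."""
    sub = MapDocument(name=f"{doc.name}__{module_name}")
    for stid in sorted(member_states):
        state = doc.species_states[stid]
        sub.species_states[stid] = state
        for eid in state.entity_ids:
            sub.entities[eid] = doc.entities[eid]
    for rx in doc.reactions.values():
        if all(s in member_states for s, _r in rx.participants):
            sub.reactions[rx.reaction_id] = rx
    box_w, box_h, margin = 90, 36, 20
    for i, stid in enumerate(sorted(sub.species_states)):
        col, row = i % 4, i // 4
        sub.aliases[f"ma{i + 1}"] = Alias(
            alias_id=f"ma{i + 1}",
            state_id=stid,
            bbox=(
                float(margin + col * (box_w + margin)),
                float(margin + row * (box_h + margin)),
                float(box_w),
                float(box_h),
            ),
        )
    return sub


def render_views(doc: MapDocument, k_levels: int,
                 canvas: tuple[int, int] | None = None) -> list[ZoomView]:
    """Render a factor-2 chain of schematic views, coarse to fine.

    The most-detailed level matches the canvas pixel-for-pixel, so rendered
    boxes coincide with alias bounding boxes; coarser levels drop text
    labels, and the coarsest drops boxes that would shrink below legibility
    — a stand-in for curated semantic-zoom imagery.
    """
    if k_levels < 1:
        raise ValueError("k_levels must be >= 1")
    if canvas is None:
        max_x = max((a.bbox[0] + a.bbox[2] for a in doc.aliases.values()), default=256)
        max_y = max((a.bbox[1] + a.bbox[3] for a in doc.aliases.values()), default=256)
        canvas = (int(max_x) + 30, int(max_y) + 30)
    w, h = canvas
    views: list[ZoomView] = []
    for level in range(k_levels):
        scale = 2.0 ** (level - (k_levels - 1))
        lw, lh = round(w * scale), round(h * scale)
        img = Image.new("RGB", (lw, lh), (255, 255, 255))
        draw = ImageDraw.Draw(img)
        detailed = level == k_levels - 1
        for alias in doc.aliases.values():
            x, y, bw, bh = alias.bbox
            if not detailed and bw * scale < 6:
                continue  # semantic pruning: tiny glyphs vanish when coarse
            state = doc.species_states[alias.state_id]
            color = (
                _COMPLEX_COLOR
                if state.is_complex
                else _CLASS_COLORS.get(
                    doc.entities[state.components[0][0]].entity_class,
                    (200, 200, 200),
                )
            )
            box = (x * scale, y * scale, (x + bw) * scale, (y + bh) * scale)
            draw.rectangle(box, fill=color, outline=(40, 40, 40))
            if detailed:
                label = doc.entities[state.components[0][0]].display_name
                draw.text((box[0] + 3, box[1] + 3), label, fill=(0, 0, 0))
        views.append(
            ZoomView(level=level, width=lw, height=lh, image=img, semantic=True)
        )
    return views
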