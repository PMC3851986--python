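"""Read and write CellDesigner map files (SBML Level 2 + the CellDesigner
extension namespace, 4.x dialect).

Only the CellDesigner 4.x dialect is supported (``speciesAlias`` /
``complexSpeciesAlias`` layout elements); files lacking the extension
namespace are rejected explicitly — a silent partial parse would corrupt
every canonical name derived downstream.

The writer emits the same dialect and exists so synthetic fixture maps can
be produced and round-tripped; ``parse_map(write_map(doc))`` reproduces
``doc`` up to element ordering.
"""

from __future__ import annotations

from lxml import etree

from .model import (
    REFERENCED_CLASSES,
    Alias,
    Entity,
    EntityClass,
    MapDocument,
    ModificationState,
    Reaction,
    Role,
    SpeciesState,
    content_digest,
)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
XHTML_NS = "http://www.w3.org/1999/xhtml"

NSMAP = {None: SBML_NS, "celldesigner": CD_NS}


def _q(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _cd(tag: str) -> str:
    return f"{{{CD_NS}}}{tag}"


class MapParseError(ValueError):
    """Malformed XML; message carries the reported line number."""


class UnsupportedDialectError(ValueError):
    """Input is XML but not a CellDesigner 4.x file."""


class MapIntegrityError(ValueError):
    """Internal references of the file do not resolve."""

    def __init__(self, dangling: list[str]):
        self.dangling = list(dangling)
        super().__init__("dangling references: " + "; ".join(dangling))


class MapValidationError(ValueError):
    """A MapDocument violates its invariants (raised before writing)."""


# CellDesigner spells modification states in full; canonical names use the
# short forms.  Unknown labels pass through verbatim in both directions.
STATE_LONG_TO_SHORT = {
    "phosphorylated": "pho",
    "acetylated": "ace",
    "ubiquitinated": "ubi",
    "methylated": "met",
    "hydroxylated": "hyd",
    "myristoylated": "myr",
    "sulfated": "sul",
    "prenylated": "pre",
    "glycosylated": "gly",
    "palmytoylated": "pal",
}
STATE_SHORT_TO_LONG = {v: k for k, v in STATE_LONG_TO_SHORT.items()}

_REF_TAGS = {
    EntityClass.PROTEIN: ("listOfProteins", "protein", "proteinReference"),
    EntityClass.GENE: ("listOfGenes", "gene", "geneReference"),
    EntityClass.RNA: ("listOfRNAs", "RNA", "rnaReference"),
    EntityClass.ANTISENSE_RNA: (
        "listOfAntisenseRNAs",
        "AntisenseRNA",
        "antisensernaReference",
    ),
}
_REF_BY_TAG = {v[2]: k for k, v in _REF_TAGS.items()}


def synth_entity_id(entity_class: EntityClass, name: str) -> str:
    """Deterministic entity id for classes that carry no reference entry
    in the file (small molecules, ions, phenotypes, ...)."""
    return f"{entity_class.value.lower()}__{name}"


# ---------------------------------------------------------------------------
# parsing


def parse_map(xml_bytes: bytes, name: str | None = None) -> MapDocument:
    """Parse a CellDesigner file into a :class:`MapDocument`.

    Raises :class:`MapParseError` for malformed XML,
    :class:`UnsupportedDialectError` when the CellDesigner namespace is
    absent, and :class:`MapIntegrityError` when internal references dangle.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise MapParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc

    model = root.find(_q("model"))
    if model is None or root.find(f".//{_cd('extension')}") is None:
        raise UnsupportedDialectError(
            "not a CellDesigner file: missing the CellDesigner extension "
            f"namespace ({CD_NS})"
        )
    ext = model.find(f"{_q('annotation')}/{_cd('extension')}")
    if ext is None:
        raise UnsupportedDialectError(
            "CellDesigner model-level extension element not found"
        )

    doc = MapDocument(
        name=name or model.get("id") or "map",
        source_digest=content_digest(xml_bytes),
    )

    compartments = {
        c.get("id"): c.get("name") or c.get("id")
        for c in model.findall(f"{_q('listOfCompartments')}/{_q('compartment')}")
    }

    # entity reference lists (proteins/genes/RNAs/antisense RNAs)
    residue_names: dict[str, str | None] = {}  # residue id -> label
    for ecls, (list_tag, item_tag, _ref) in _REF_TAGS.items():
        for el in ext.findall(f"{_cd(list_tag)}/{_cd(item_tag)}"):
            notes = el.find(_cd("notes"))
            ann = _read_notes(notes) if notes is not None else ""
            entity = Entity(
                entity_id=el.get("id"),
                entity_class=ecls,
                display_name=el.get("name") or "",
                annotation_text=ann,
            )
            doc.entities[entity.entity_id] = entity
            for res in el.findall(
                f"{_cd('listOfModificationResidues')}/{_cd('modificationResidue')}"
            ):
                residue_names[res.get("id")] = res.get("name") or None

    # species, including those nested inside complexes
    included_parent: dict[str, str] = {}  # included species id -> complex species id
    included_elems: dict[str, etree._Element] = {}
    for el in ext.findall(f"{_cd('listOfIncludedSpecies')}/{_cd('species')}"):
        cann = el.find(f"{_cd('annotation')}/{_cd('complexSpecies')}")
        if cann is None or not (cann.text or "").strip():
            raise MapIntegrityError(
                [f"included species {el.get('id')}: no containing complex"]
            )
        included_parent[el.get("id")] = cann.text.strip()
        included_elems[el.get("id")] = el

    dangling: list[str] = []
    complex_components: dict[str, list[tuple[str, tuple[ModificationState, ...]]]] = {}
    for sid, parent in included_parent.items():
        el = included_elems[sid]
        comp = _parse_identity(
            el, f"{_cd('annotation')}/{_cd('speciesIdentity')}", doc, residue_names,
            dangling,
        )
        if comp is not None:
            complex_components.setdefault(parent, []).append(comp)

    for el in model.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        sid = el.get("id")
        comp_id = el.get("compartment")
        compartment = compartments.get(comp_id) if comp_id else None
        if comp_id == "default":
            compartment = None
        ident = el.find(
            f"{_q('annotation')}/{_cd('extension')}/{_cd('speciesIdentity')}"
        )
        cls_el = ident.find(_cd("class")) if ident is not None else None
        cls_name = (cls_el.text or "").strip() if cls_el is not None else ""
        if cls_name == "COMPLEX":
            components = tuple(complex_components.get(sid, ()))
            if not components:
                dangling.append(f"complex species {sid}: no included components")
                continue
        else:
            comp = _parse_identity(
                el,
                f"{_q('annotation')}/{_cd('extension')}/{_cd('speciesIdentity')}",
                doc,
                residue_names,
                dangling,
                species_name=el.get("name") or sid,
                notes_el=el.find(_q("notes")),
            )
            if comp is None:
                continue
            components = (comp,)
        doc.species_states[sid] = SpeciesState(
            state_id=sid, components=components, compartment=compartment
        )

    # aliases (plain + complex)
    for tag in ("listOfSpeciesAliases", "listOfComplexSpeciesAliases"):
        item = "speciesAlias" if tag == "listOfSpeciesAliases" else "complexSpeciesAlias"
        for el in ext.findall(f"{_cd(tag)}/{_cd(item)}"):
            sid = el.get("species")
            if sid in included_parent:
                doc.warnings.append(
                    f"alias {el.get('id')} refers to included species {sid}; "
                    "ignored (components are drawn inside their complex alias)"
                )
                continue
            if sid not in doc.species_states:
                dangling.append(f"alias {el.get('id')}: species {sid}")
                continue
            b = el.find(_cd("bounds"))
            if b is None:
                dangling.append(f"alias {el.get('id')}: missing bounds")
                continue
            doc.aliases[el.get("id")] = Alias(
                alias_id=el.get("id"),
                state_id=sid,
                bbox=(
                    float(b.get("x")),
                    float(b.get("y")),
                    float(b.get("w")),
                    float(b.get("h")),
                ),
            )

    # reactions
    for el in model.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        rid = el.get("id")
        participants: list[tuple[str, Role]] = []
        for list_tag, ref_tag, role in (
            ("listOfReactants", "speciesReference", Role.REACTANT),
            ("listOfProducts", "speciesReference", Role.PRODUCT),
            ("listOfModifiers", "modifierSpeciesReference", Role.MODIFIER),
        ):
            for ref in el.findall(f"{_q(list_tag)}/{_q(ref_tag)}"):
                sid = ref.get("species")
                if sid not in doc.species_states:
                    dangling.append(f"reaction {rid}: species {sid}")
                    continue
                participants.append((sid, role))
        subtypes: list[tuple[str, str]] = []
        for mod in el.findall(
            f"{_q('annotation')}/{_cd('extension')}/"
            f"{_cd('listOfModification')}/{_cd('modification')}"
        ):
            subtypes.append((mod.get("modifiers"), mod.get("type")))
        if participants:
            doc.reactions[rid] = Reaction(
                reaction_id=rid,
                participants=tuple(participants),
                modifier_subtypes=tuple(subtypes),
            )

    if dangling:
        raise MapIntegrityError(dangling)
    leftovers = doc.validate_references()
    if leftovers:
        raise MapIntegrityError(leftovers)
    return doc


def _parse_identity(
    el,
    ident_path: str,
    doc: MapDocument,
    residue_names: dict[str, str | None],
    dangling: list[str],
    species_name: str | None = None,
    notes_el=None,
) -> tuple[str, tuple[ModificationState, ...]] | None:
    """One (entity_id, modifications) component from a speciesIdentity."""
    ident = el.find(ident_path)
    if ident is None:
        dangling.append(f"species {el.get('id')}: no speciesIdentity")
        return None
    cls_el = ident.find(_cd("class"))
    cls_name = (cls_el.text or "").strip() if cls_el is not None else "UNKNOWN"
    try:
        ecls = EntityClass(cls_name)
    except ValueError:
        ecls = EntityClass.UNKNOWN

    entity_id: str | None = None
    for ref_tag, ref_cls in _REF_BY_TAG.items():
        ref = ident.find(_cd(ref_tag))
        if ref is not None and (ref.text or "").strip():
            entity_id = ref.text.strip()
            if entity_id not in doc.entities:
                dangling.append(f"species {el.get('id')}: entity {entity_id}")
                return None
            break
    if entity_id is None:
        # non-referenced class: identity carried by class + name
        name_el = ident.find(_cd("name"))
        name = (name_el.text or "").strip() if name_el is not None else (
            species_name or el.get("id")
        )
        entity_id = synth_entity_id(ecls, name)
        if entity_id not in doc.entities:
            ann = _read_notes(notes_el) if notes_el is not None else ""
            doc.entities[entity_id] = Entity(
                entity_id=entity_id,
                entity_class=ecls,
                display_name=name,
                annotation_text=ann,
            )

    mods: list[ModificationState] = []
    for m in ident.findall(
        f"{_cd('state')}/{_cd('listOfModifications')}/{_cd('modification')}"
    ):
        state = m.get("state") or ""
        state = STATE_LONG_TO_SHORT.get(state, state)
        res_id = m.get("residue")
        residue = residue_names.get(res_id) if res_id else None
        if res_id and res_id not in residue_names:
            dangling.append(f"species {el.get('id')}: residue {res_id}")
            continue
        mods.append(ModificationState(state_label=state, residue_label=residue))
    return (entity_id, tuple(mods))


def _read_notes(notes_el) -> str:
    body = notes_el.find(f"{{{XHTML_NS}}}html/{{{XHTML_NS}}}body")
    if body is None:
        body = notes_el.find(f"{{{XHTML_NS}}}body")
    if body is None:
        return (notes_el.text or "").strip()
    return (body.text or "").strip()


# ---------------------------------------------------------------------------
# writing


def write_map(doc: MapDocument) -> bytes:
    """Serialize *doc* back to CellDesigner XML (fixture writer).

    Validates the document's referential closure first and refuses to emit
    anything for an inconsistent document.
    """
    dangling = doc.validate_references()
    if dangling:
        raise MapValidationError("cannot write inconsistent map: " + "; ".join(dangling))

    root = etree.Element(_q("sbml"), nsmap=NSMAP, level="2", version="4")
    model = etree.SubElement(root, _q("model"), id=_xml_id(doc.name))
    ann = etree.SubElement(model, _q("annotation"))
    ext = etree.SubElement(ann, _cd("extension"))
    etree.SubElement(ext, _cd("modelVersion")).text = "4.0"

    # compartments
    comp_names = sorted(
        {s.compartment for s in doc.species_states.values() if s.compartment}
    )
    comp_ids = {name: f"c{i + 1}" for i, name in enumerate(comp_names)}
    loc = etree.SubElement(model, _q("listOfCompartments"))
    etree.SubElement(loc, _q("compartment"), id="default")
    for name in comp_names:
        etree.SubElement(loc, _q("compartment"), id=comp_ids[name], name=name)

    # entity reference lists + residue declarations
    residue_ids: dict[tuple[str, str], str] = {}  # (entity_id, label) -> residue id
    res_counter = 0
    list_elems = {
        ecls: etree.SubElement(ext, _cd(tags[0]))
        for ecls, tags in _REF_TAGS.items()
    }
    for entity in doc.entities.values():
        if entity.entity_class not in REFERENCED_CLASSES:
            continue
        _list_tag, item_tag, _ref = _REF_TAGS[entity.entity_class]
        el = etree.SubElement(
            list_elems[entity.entity_class],
            _cd(item_tag),
            id=entity.entity_id,
            name=entity.display_name,
        )
        if entity.annotation_text:
            _write_cd_notes(el, entity.annotation_text)
        labels = sorted(
            {
                m.residue_label
                for s in doc.states_of_entity(entity.entity_id)
                for eid, mods in s.components
                if eid == entity.entity_id
                for m in mods
                if m.residue_label
            }
        )
        if labels:
            lomr = etree.SubElement(el, _cd("listOfModificationResidues"))
            for label in labels:
                res_counter += 1
                rid = f"rs{res_counter}"
                residue_ids[(entity.entity_id, label)] = rid
                etree.SubElement(lomr, _cd("modificationResidue"), id=rid, name=label)

    # included species for complexes
    lois = etree.SubElement(ext, _cd("listOfIncludedSpecies"))
    inc_counter = 0
    for state in doc.species_states.values():
        if not state.is_complex:
            continue
        for eid, mods in state.components:
            inc_counter += 1
            el = etree.SubElement(
                lois,
                _cd("species"),
                id=f"is{inc_counter}",
                name=doc.entities[eid].display_name,
            )
            iann = etree.SubElement(el, _cd("annotation"))
            etree.SubElement(iann, _cd("complexSpecies")).text = state.state_id
            _write_identity(iann, doc, eid, mods, residue_ids)

    # alias lists
    losa = etree.SubElement(ext, _cd("listOfSpeciesAliases"))
    locsa = etree.SubElement(ext, _cd("listOfComplexSpeciesAliases"))
    for alias in doc.aliases.values():
        state = doc.species_states[alias.state_id]
        parent = locsa if state.is_complex else losa
        tag = "complexSpeciesAlias" if state.is_complex else "speciesAlias"
        el = etree.SubElement(
            parent, _cd(tag), id=alias.alias_id, species=alias.state_id
        )
        x, y, w, h = alias.bbox
        etree.SubElement(
            el, _cd("bounds"), x=_num(x), y=_num(y), w=_num(w), h=_num(h)
        )

    # species
    los = etree.SubElement(model, _q("listOfSpecies"))
    for state in doc.species_states.values():
        comp_id = comp_ids.get(state.compartment, "default")
        first_entity = doc.entities[state.components[0][0]]
        sp = etree.SubElement(
            los,
            _q("species"),
            id=state.state_id,
            name=first_entity.display_name if not state.is_complex else state.state_id,
            compartment=comp_id,
        )
        if (
            not state.is_complex
            and first_entity.entity_class not in REFERENCED_CLASSES
            and first_entity.annotation_text
        ):
            _write_sbml_notes(sp, first_entity.annotation_text)
        sann = etree.SubElement(sp, _q("annotation"))
        sext = etree.SubElement(sann, _cd("extension"))
        if state.is_complex:
            ident = etree.SubElement(sext, _cd("speciesIdentity"))
            etree.SubElement(ident, _cd("class")).text = "COMPLEX"
        else:
            eid, mods = state.components[0]
            _write_identity(sext, doc, eid, mods, residue_ids)

    # reactions
    lor = etree.SubElement(model, _q("listOfReactions"))
    for rx in doc.reactions.values():
        rel = etree.SubElement(lor, _q("reaction"), id=rx.reaction_id)
        rann = etree.SubElement(rel, _q("annotation"))
        rext = etree.SubElement(rann, _cd("extension"))
        etree.SubElement(rext, _cd("reactionType")).text = "STATE_TRANSITION"
        if rx.modifier_subtypes:
            lom = etree.SubElement(rext, _cd("listOfModification"))
            for sid, subtype in rx.modifier_subtypes:
                etree.SubElement(
                    lom, _cd("modification"), modifiers=sid, type=subtype
                )
        groups = {
            Role.REACTANT: etree.SubElement(rel, _q("listOfReactants")),
            Role.PRODUCT: etree.SubElement(rel, _q("listOfProducts")),
            Role.MODIFIER: etree.SubElement(rel, _q("listOfModifiers")),
        }
        for sid, role in rx.participants:
            ref_tag = (
                "modifierSpeciesReference" if role is Role.MODIFIER
                else "speciesReference"
            )
            etree.SubElement(groups[role], _q(ref_tag), species=sid)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _write_identity(parent, doc, entity_id, mods, residue_ids) -> None:
    entity = doc.entities[entity_id]
    ident = etree.SubElement(parent, _cd("speciesIdentity"))
    etree.SubElement(ident, _cd("class")).text = entity.entity_class.value
    if entity.entity_class in REFERENCED_CLASSES:
        ref_tag = _REF_TAGS[entity.entity_class][2]
        etree.SubElement(ident, _cd(ref_tag)).text = entity_id
    else:
        etree.SubElement(ident, _cd("name")).text = entity.display_name
    if mods:
        state_el = etree.SubElement(ident, _cd("state"))
        lom = etree.SubElement(state_el, _cd("listOfModifications"))
        for m in mods:
            attrs = {"state": STATE_SHORT_TO_LONG.get(m.state_label, m.state_label)}
            if m.residue_label:
                attrs["residue"] = residue_ids[(entity_id, m.residue_label)]
            etree.SubElement(lom, _cd("modification"), **attrs)


def _write_cd_notes(el, text: str) -> None:
    notes = etree.SubElement(el, _cd("notes"))
    html_el = etree.SubElement(notes, f"{{{XHTML_NS}}}html")
    body = etree.SubElement(html_el, f"{{{XHTML_NS}}}body")
    body.text = text


def _write_sbml_notes(el, text: str) -> None:
    notes = etree.SubElement(el, _q("notes"))
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body")
    body.text = text


def _xml_id(name: str) -> str:
    cleaned = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)
    return cleaned or "map"


def _num(v: float) -> str:
    return f"{v:g}"


# ---------------------------------------------------------------------------


def documents_equivalent(a: MapDocument, b: MapDocument) -> bool:
    """Structural equality of two maps, ignoring element ordering and the
    source digest (used by round-trip checks)."""
    if set(a.entities) != set(b.entities):
        return False
    if any(a.entities[k] != b.entities[k] for k in a.entities):
        return False
    if set(a.species_states) != set(b.species_states):
        return False
    if any(a.species_states[k] != b.species_states[k] for k in a.species_states):
        return False
    if set(a.aliases) != set(b.aliases) or any(
        a.aliases[k] != b.aliases[k] for k in a.aliases
    ):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for k in a.reactions:
        ra, rb = a.reactions[k], b.reactions[k]
        if sorted(ra.participants) != sorted(rb.participants):
            return False
        if sorted(ra.modifier_subtypes) != sorted(rb.modifier_subtypes):
            return False
    return True


def group_entities_by_class(doc: MapDocument) -> dict[EntityClass, list[str]]:
    """Selection-panel grouping: every entity exactly once, groups in the
    fixed class order, names sorted within a group.  Classes with no
    entities are omitted."""
    groups: dict[EntityClass, list[str]] = {}
    from .model import CLASS_ORDER

    for ecls in CLASS_ORDER:
        names = sorted(
            e.display_name
            for e in doc.entities.values()
            if e.entity_class is ecls
        )
        if names:
            groups[ecls] = names
    return groups
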