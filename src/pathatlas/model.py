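"""Typed in-memory model of a CellDesigner molecular-interaction map.

The model mirrors the information an atlas needs from a CellDesigner file:
biological entities and their classes, species states (entity + modifications
+ compartment), drawn aliases with pixel bounding boxes, reactions with
participant roles, and functional modules.  Layout beyond alias bounding
boxes (glyph shapes, colors, fonts) is deliberately not modeled — rendering
is delegated to the supplied zoom-view images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class EntityClass(str, Enum):
    """Biological entity classes of the CellDesigner ontology."""

    PROTEIN = "PROTEIN"
    GENE = "GENE"
    RNA = "RNA"
    ANTISENSE_RNA = "ANTISENSE_RNA"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    ION = "ION"
    PHENOTYPE = "PHENOTYPE"
    DRUG = "DRUG"
    UNKNOWN = "UNKNOWN"
    DEGRADED = "DEGRADED"
    COMPLEX = "COMPLEX"


#: the four classes that carry an explicit reference entry in the file
REFERENCED_CLASSES = (
    EntityClass.PROTEIN,
    EntityClass.GENE,
    EntityClass.RNA,
    EntityClass.ANTISENSE_RNA,
)

#: fixed ordering of classes used by the selection panel and exports
CLASS_ORDER = tuple(EntityClass)


class Role(str, Enum):
    """Role of a species state in a reaction."""

    REACTANT = "REACTANT"
    PRODUCT = "PRODUCT"
    MODIFIER = "MODIFIER"


@dataclass(frozen=True)
class Entity:
    """One biological entity (protein, gene, small molecule, ...).

    ``annotation_text`` holds the raw annotation block from the file,
    possibly empty; the structured sections are parsed lazily by the
    annotation layer.
    """

    entity_id: str
    entity_class: EntityClass
    display_name: str
    annotation_text: str = ""

    def __post_init__(self) -> None:
        if self.entity_class in REFERENCED_CLASSES and not self.display_name:
            raise ValueError(
                f"entity {self.entity_id!r} of class {self.entity_class.value} "
                "must have a non-empty display name"
            )


@dataclass(frozen=True)
class ModificationState:
    """A single residue modification, e.g. phosphorylation at Thr167.

    ``residue_label`` is the residue as printed ("Thr167"); ``state_label``
    the short modification state ("pho").  ``residue_position`` is the
    integer embedded in the residue label, when there is one.
    """

    state_label: str
    residue_label: Optional[str] = None
    residue_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_label is not None:
            pos = _first_digit_run(self.residue_label)
            if self.residue_position is None:
                object.__setattr__(self, "residue_position", pos)
            elif pos is not None and pos != self.residue_position:
                raise ValueError(
                    f"residue_position {self.residue_position} contradicts "
                    f"residue_label {self.residue_label!r}"
                )


def _first_digit_run(text: str) -> Optional[int]:
    """First maximal run of digits in *text*, as an int (None if no digits)."""
    run = ""
    for ch in text:
        if ch.isdigit():
            run += ch
        elif run:
            break
    return int(run) if run else None


@dataclass(frozen=True)
class SpeciesState:
    """An entity (or complex of entities) in a definite modification state
    and compartment.  The unit the canonical naming grammar serializes."""

    state_id: str
    components: tuple[tuple[str, tuple[ModificationState, ...]], ...]
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"species state {self.state_id!r} has no components")

    @property
    def is_complex(self) -> bool:
        return len(self.components) > 1

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return tuple(eid for eid, _mods in self.components)


@dataclass(frozen=True)
class Alias:
    """One drawn occurrence of a species state on the most-detailed canvas.

    Coordinates are pixels, origin top-left, y increasing downward, exactly
    as stored by the drawing canvas the zoom views were exported from.
    """

    alias_id: str
    state_id: str
    bbox: tuple[float, float, float, float]  # x, y, width, height

    def __post_init__(self) -> None:
        _x, _y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"alias {self.alias_id!r} has empty bbox {self.bbox}")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    participants: tuple[tuple[str, Role], ...]  # (state_id, role)
    modifier_subtypes: tuple[tuple[str, str], ...] = ()  # (state_id, subtype)

    def __post_init__(self) -> None:
        if not any(r in (Role.REACTANT, Role.PRODUCT) for _s, r in self.participants):
            raise ValueError(
                f"reaction {self.reaction_id!r} needs at least one reactant or product"
            )

    def roles_of(self, state_id: str) -> tuple[Role, ...]:
        return tuple(r for s, r in self.participants if s == state_id)


@dataclass
class ModuleDef:
    """A functional submap: a named subset of the master map's species,
    optionally with its own simplified layout."""

    module_name: str
    member_states: set[str] = field(default_factory=set)
    submap: Optional["MapDocument"] = None


@dataclass
class MapDocument:
    """Complete parsed model of one CellDesigner map."""

    name: str
    entities: dict[str, Entity] = field(default_factory=dict)
    species_states: dict[str, SpeciesState] = field(default_factory=dict)
    aliases: dict[str, Alias] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    modules: list[ModuleDef] = field(default_factory=list)
    source_digest: str = ""
    warnings: list[str] = field(default_factory=list)

    def validate_references(self) -> list[str]:
        """Return dangling internal references (empty means closure holds)."""
        dangling: list[str] = []
        for st in self.species_states.values():
            for eid in st.entity_ids:
                if eid not in self.entities:
                    dangling.append(f"species {st.state_id}: entity {eid}")
        for al in self.aliases.values():
            if al.state_id not in self.species_states:
                dangling.append(f"alias {al.alias_id}: species {al.state_id}")
        for rx in self.reactions.values():
            for sid, _role in rx.participants:
                if sid not in self.species_states:
                    dangling.append(f"reaction {rx.reaction_id}: species {sid}")
        for mod in self.modules:
            for sid in mod.member_states:
                if sid not in self.species_states:
                    dangling.append(f"module {mod.module_name}: species {sid}")
        return dangling

    def aliases_of_state(self, state_id: str) -> list[Alias]:
        return [a for a in self.aliases.values() if a.state_id == state_id]

    def states_of_entity(self, entity_id: str) -> list[SpeciesState]:
        return [
            s for s in self.species_states.values() if entity_id in s.entity_ids
        ]

    def reactions_of_state(self, state_id: str) -> list[Reaction]:
        return [
            r
            for r in self.reactions.values()
            if any(s == state_id for s, _role in r.participants)
        ]


def content_digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()
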