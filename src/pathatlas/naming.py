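"""Canonical species-name grammar.

A species state is serialized as::

    name        := component (":" component)* ("@" compartment)?
    component   := entity_name ("|" modification)*
    modification:= (residue_label "_")? state_label

"Cdc25|Pho@cytoplasm" is phosphorylated Cdc25 in the cytoplasm;
"Cdc13:Cdc2|Thr167_pho@cytoplasm" is the Cdc13:Cdc2 complex whose Cdc2
component is phosphorylated on threonine 167.  The grammar was popularized
by the BiNoM naming convention and the separators are reserved: "@" for the
compartment, "|" for modifications, ":" between complex components.

``format_name`` and ``parse_name`` are exact inverses on conformant input;
case of state labels is preserved as found ("Pho" and "pho" both occur in
the wild and are not normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MapDocument, ModificationState, SpeciesState, _first_digit_run

RESERVED = "@|:"


class NameError_(ValueError):
    """Grammar or encoding error in a canonical name."""


@dataclass(frozen=True)
class NameComponent:
    entity_name: str
    modifications: tuple[ModificationState, ...] = ()


@dataclass(frozen=True)
class ParsedName:
    """Structural skeleton recovered from a canonical name string."""

    components: tuple[NameComponent, ...]
    compartment: str | None = None

    @property
    def text(self) -> str:
        return _format(
            [(c.entity_name, c.modifications) for c in self.components],
            self.compartment,
        )


def _format_modification(m: ModificationState) -> str:
    if m.residue_label:
        return f"{m.residue_label}_{m.state_label}"
    return m.state_label


def _mod_sort_key(m: ModificationState) -> tuple:
    # residue position first, then lexical: deterministic for multi-site states
    pos = m.residue_position if m.residue_position is not None else -1
    return (pos, m.residue_label or "", m.state_label)


def _format(
    components: list[tuple[str, tuple[ModificationState, ...]]],
    compartment: str | None,
) -> str:
    parts = []
    for name, mods in components:
        if any(ch in RESERVED for ch in name):
            raise NameError_(
                f"entity name {name!r} contains a reserved character ({RESERVED})"
            )
        piece = name
        for m in sorted(mods, key=_mod_sort_key):
            piece += "|" + _format_modification(m)
        parts.append(piece)
    text = ":".join(parts)
    if compartment is not None:
        if any(ch in RESERVED for ch in compartment):
            raise NameError_(
                f"compartment {compartment!r} contains a reserved character"
            )
        text += "@" + compartment
    return text


def format_name(state: SpeciesState, doc: MapDocument) -> str:
    """Canonical name of *state*, resolving entity ids through *doc*."""
    components = []
    for eid, mods in state.components:
        entity = doc.entities[eid]
        components.append((entity.display_name, mods))
    return _format(components, state.compartment)


def format_skeleton(parsed: ParsedName) -> str:
    return parsed.text


def parse_name(text: str) -> ParsedName:
    """Parse a canonical name back into components, modifications and
    compartment.  Raises :class:`NameError_` with the offending position on
    grammar violations (empty fields, dangling separators, two "@")."""
    if not text:
        raise NameError_("empty name (position 0)")
    at_count = text.count("@")
    if at_count > 1:
        raise NameError_(
            f"more than one '@' in {text!r} (position {text.rindex('@')})"
        )
    compartment: str | None = None
    body = text
    if at_count == 1:
        body, compartment = text.split("@")
        if not compartment:
            raise NameError_(f"dangling '@' in {text!r} (position {len(text) - 1})")
        if not body:
            raise NameError_(f"name {text!r} has no components before '@'")
    components: list[NameComponent] = []
    offset = 0
    for comp_text in body.split(":"):
        if not comp_text:
            raise NameError_(f"empty component in {text!r} (position {offset})")
        fields = comp_text.split("|")
        entity_name = fields[0]
        if not entity_name:
            raise NameError_(f"empty entity name in {text!r} (position {offset})")
        mods = []
        for mod_text in fields[1:]:
            if not mod_text:
                raise NameError_(
                    f"dangling '|' in {text!r} (position {offset + len(comp_text)})"
                )
            mods.append(parse_modification(mod_text))
        components.append(NameComponent(entity_name, tuple(mods)))
        offset += len(comp_text) + 1
    return ParsedName(tuple(components), compartment)


def parse_modification(token: str) -> ModificationState:
    """Split one modification token: the last "_"-separated field is the
    state label; anything before it is the residue label ("Thr167_pho" →
    residue Thr167, state pho; "Pho" → bare state)."""
    if "_" in token:
        residue, state = token.rsplit("_", 1)
        if not state:
            raise NameError_(f"modification token {token!r} has empty state label")
        return ModificationState(
            state_label=state,
            residue_label=residue or None,
            residue_position=_first_digit_run(residue) if residue else None,
        )
    return ModificationState(state_label=token)
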