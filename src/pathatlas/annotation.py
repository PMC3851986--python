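"""Structured entity annotations and identifier-tag hyperlink expansion.

Annotations attached to map entities are structured in named sections, each
grouping one type of information — conventionally "Identifiers" (database
IDs), "Maps_Modules" (module membership) and "References" (literature), but
any section name is accepted.  A section header is a line of the form
``NAME:`` alone on a line; text that contains no such header is kept as a
single unsectioned block, so maps annotated in any other style degrade
gracefully instead of failing.

Inside section bodies, tokens of the form ``PREFIX:ID`` (for a registered
prefix such as PMID, HUGO, UNIPROT) and ``@resource:id`` (any resource of
the MIRIAM identifier registry) are expanded into hyperlinks; everything
else is HTML-escaped and passed through untouched.
"""

from __future__ import annotations

import html
import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: default per-section highlight palette, keyed by section order (cosmetic)
SECTION_PALETTE = ("#dbe9ff", "#dfffdb", "#fff3d6", "#ffdbe9", "#e9dbff")


@dataclass(frozen=True)
class Section:
    name: str  # "" for the unsectioned block
    body: str  # verbatim text up to the next header (newlines included)
    header_text: str = ""  # the exact header line, kept for lossless rebuild


@dataclass(frozen=True)
class AnnotationDoc:
    sections: tuple[Section, ...]
    sectioned: bool

    def section(self, name: str) -> Section | None:
        for s in self.sections:
            if s.name == name:
                return s
        return None


_HEADER_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):[ \t]*(?:\n|\Z)", re.M)


def parse_annotation(raw: str) -> AnnotationDoc:
    """Split *raw* into named sections.  Permissive by design: when no
    header line is found the whole text becomes one unsectioned block.
    Bodies are kept verbatim (offset slices of the input), so the split
    loses no characters."""
    matches = list(_HEADER_RE.finditer(raw))
    if not matches:
        return AnnotationDoc((Section("", raw),), sectioned=False)
    sections: list[Section] = []
    # any prose before the first header becomes a leading unnamed section
    if matches[0].start() > 0:
        sections.append(Section("", raw[: matches[0].start()]))
    for k, m in enumerate(matches):
        end = matches[k + 1].start() if k + 1 < len(matches) else len(raw)
        sections.append(Section(m.group(1), raw[m.end() : end], m.group(0)))
    return AnnotationDoc(tuple(sections), sectioned=True)


def reconstruct(doc: AnnotationDoc) -> str:
    """Exact inverse of :func:`parse_annotation`."""
    return "".join(s.header_text + s.body for s in doc.sections)


DEFAULT_REGISTRY_ENTRIES = {
    "PMID": "https://pubmed.ncbi.nlm.nih.gov/{id}",
    "HUGO": "https://www.genenames.org/data/gene-symbol-report/#!/symbol/{id}",
    "UNIPROT": "https://www.uniprot.org/uniprotkb/{id}",
}

#: MIRIAM registry resolver for ``@resource:id`` tags
MIRIAM_URL = "https://identifiers.org/{resource}:{id}"


@dataclass
class TagRegistry:
    """Mapping of tag prefixes to URL templates (one ``{id}`` placeholder).

    Ships PMID / HUGO / UNIPROT; user-defined tags are merged in from the
    build configuration via :meth:`extend`.
    """

    entries: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGISTRY_ENTRIES)
    )

    def __post_init__(self) -> None:
        for prefix, template in self.entries.items():
            if template.count("{id}") != 1:
                raise ValueError(
                    f"registry template for {prefix!r} must contain exactly "
                    f"one {{id}} placeholder: {template!r}"
                )

    def extend(self, extra: dict[str, str]) -> "TagRegistry":
        merged = dict(self.entries)
        merged.update(extra)
        return TagRegistry(merged)

    def url_for(self, prefix: str, ident: str) -> str | None:
        template = self.entries.get(prefix)
        if template is None:
            return None
        return template.replace("{id}", ident)


# a tag token: PREFIX:ID or @resource:ID, delimited by whitespace / punctuation
# that cannot occur inside identifiers.  MIRIAM IDs may themselves contain
# ":" (the split is at the first colon after the resource name); a trailing
# sentence period is never part of the ID.
_TAG_RE = re.compile(
    r"(?P<miriam>@(?P<resource>[A-Za-z][A-Za-z0-9._-]*):"
    r"(?P<mid>[A-Za-z0-9](?:[A-Za-z0-9._:-]*[A-Za-z0-9])?))"
    r"|(?P<plain>(?P<prefix>[A-Z][A-Z0-9_]+):"
    r"(?P<pid>[A-Za-z0-9](?:[A-Za-z0-9._-]*[A-Za-z0-9])?))"
)

# existing hyperlinks are kept verbatim so expansion is idempotent
_ANCHOR_RE = re.compile(r"<a\s[^>]*>.*?</a>", re.S)
# escape "&" only when it does not already start a character entity
_AMP_RE = re.compile(r"&(?!(?:[a-zA-Z][a-zA-Z0-9]*|#[0-9]+|#x[0-9a-fA-F]+);)")


def _smart_escape(text: str) -> str:
    return _AMP_RE.sub("&amp;", text).replace("<", "&lt;").replace(">", "&gt;")

#: MIRIAM resources recognized by default; tags for unknown resources are
#: left as plain text with a warning rather than producing a dead link.
KNOWN_MIRIAM_RESOURCES = frozenset(
    {
        "biocyc", "pubmed", "uniprot", "hgnc", "hgnc.symbol", "chebi",
        "ensembl", "go", "kegg.compound", "kegg.pathway", "reactome",
        "interpro", "pfam", "doi", "taxonomy", "ec-code",
    }
)


def expand_tags(text: str, registry: TagRegistry | None = None) -> str:
    """Expand identifier tags in *text* into HTML anchors.

    Idempotent on its own output: existing anchors are copied verbatim (so
    the labels inside them are never re-expanded) and escaping never
    re-escapes an existing character entity.
    """
    registry = registry or TagRegistry()
    pieces: list[str] = []
    last = 0
    for anchor in _ANCHOR_RE.finditer(text):
        pieces.append(_expand_segment(text[last : anchor.start()], registry))
        pieces.append(anchor.group(0))
        last = anchor.end()
    pieces.append(_expand_segment(text[last:], registry))
    return "".join(pieces)


def _expand_segment(text: str, registry: TagRegistry) -> str:
    out: list[str] = []
    pos = 0
    for m in _TAG_RE.finditer(text):
        if m.group("miriam"):
            resource, ident = m.group("resource"), m.group("mid")
            if resource.lower() not in KNOWN_MIRIAM_RESOURCES:
                log.warning("unknown MIRIAM resource %r left unexpanded", resource)
                continue
            url = MIRIAM_URL.format(resource=resource, id=ident)
            label = f"{resource}:{ident}"
        else:
            prefix, ident = m.group("prefix"), m.group("pid")
            url = registry.url_for(prefix, ident)
            if url is None:
                continue
            label = f"{prefix}:{ident}"
        out.append(_smart_escape(text[pos : m.start()]))
        out.append(f'<a href="{html.escape(url, quote=True)}">{html.escape(label)}</a>')
        pos = m.end()
    out.append(_smart_escape(text[pos:]))
    return "".join(out)


def render_sections(doc: AnnotationDoc, registry: TagRegistry | None = None) -> str:
    """HTML rendering of an annotation: one colored block per section with
    all identifier tags expanded."""
    blocks = []
    for i, s in enumerate(doc.sections):
        color = SECTION_PALETTE[i % len(SECTION_PALETTE)]
        body = expand_tags(s.body, registry)
        title = f"<h4>{html.escape(s.name)}</h4>" if s.name else ""
        blocks.append(
            f'<div class="ann-section" style="background:{color}">{title}'
            f"<p>{body}</p></div>"
        )
    return "\n".join(blocks)


def extract_module_membership(doc: AnnotationDoc) -> list[str]:
    """Module names listed in the Maps_Modules section (one per line or
    comma-separated); empty list when the section is absent."""
    sec = doc.section("Maps_Modules")
    if sec is None:
        return []
    names: list[str] = []
    for line in sec.body.replace(",", "\n").split("\n"):
        name = line.strip()
        if name:
            names.append(name)
    return names
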