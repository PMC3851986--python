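"""Annotation posts: generation, release-to-release synchronization, archive.

Every map object — entity, module, reaction — gets a pre-generated post
holding its expanded annotation, the list of its modification forms, the
reactions it participates in (with its role in each), and map-link anchors
so readers can jump from the post to the object on the map.  Posts collect
reader comments.

When a new map release is synchronized against the store, three things can
happen per key: the object disappeared, so its post is archived (never
deleted — the archive stays readable for traceability); its generated
content changed, so the old version moves to the archive together with all
its comments and a fresh higher version becomes active; or nothing changed
and the record is untouched.  Change detection hashes the generated content
rather than the raw XML, so layout-only map edits do not spam the archive.

The store is a local versioned JSON file plus rendered static pages; a
remote-blog adapter interface is defined for hosted blog systems, with only
a no-op implementation shipped.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from . import annotation as ann
from . import naming
from .model import MapDocument, Role


class PostStatus(str, Enum):
    ACTIVE = "ACTIVE"
    ARCHIVED = "ARCHIVED"


@dataclass(frozen=True)
class Comment:
    author: str
    timestamp: str
    text: str


@dataclass(frozen=True)
class PostRecord:
    key: str
    version: int
    status: PostStatus
    content: str
    content_digest: str
    comments: tuple[Comment, ...] = ()


@dataclass
class PostStore:
    records: list[PostRecord] = field(default_factory=list)

    def active(self, key: str) -> PostRecord | None:
        for r in self.records:
            if r.key == key and r.status is PostStatus.ACTIVE:
                return r
        return None

    def history(self, key: str) -> list[PostRecord]:
        return sorted(
            (r for r in self.records if r.key == key), key=lambda r: r.version
        )

    def keys(self) -> list[str]:
        return sorted({r.key for r in self.records})

    def check_integrity(self) -> None:
        """At most one ACTIVE record per key; versions consecutive from 1."""
        for key in self.keys():
            hist = self.history(key)
            actives = [r for r in hist if r.status is PostStatus.ACTIVE]
            if len(actives) > 1:
                raise StoreIntegrityError(
                    f"key {key!r} has {len(actives)} ACTIVE records"
                )
            versions = [r.version for r in hist]
            if versions != list(range(1, len(versions) + 1)):
                raise StoreIntegrityError(
                    f"key {key!r} versions {versions} are not consecutive from 1"
                )


class StoreIntegrityError(RuntimeError):
    pass


class UnknownKeyError(KeyError):
    pass


# ---------------------------------------------------------------------------
# post generation


def post_keys_for(doc: MapDocument, modules: dict[str, MapDocument] | None = None
                  ) -> list[str]:
    keys = [f"entity-{eid}" for eid in doc.entities]
    keys += [f"module-{name}" for name in sorted(modules or {})]
    keys += [f"reaction-{rid}" for rid in doc.reactions]
    return keys


def generate_post(
    key: str,
    doc: MapDocument,
    modules: dict[str, MapDocument] | None = None,
    registry: ann.TagRegistry | None = None,
) -> str:
    """Hypertext content for one post key (``entity-*``, ``module-*`` or
    ``reaction-*``).  Raises :class:`UnknownKeyError` for anything else."""
    registry = registry or ann.TagRegistry()
    if key.startswith("entity-"):
        eid = key[len("entity-"):]
        if eid not in doc.entities:
            raise UnknownKeyError(key)
        return _entity_post(eid, doc, registry)
    if key.startswith("module-"):
        name = key[len("module-"):]
        if not modules or name not in modules:
            raise UnknownKeyError(key)
        return _module_post(name, modules[name])
    if key.startswith("reaction-"):
        rid = key[len("reaction-"):]
        if rid not in doc.reactions:
            raise UnknownKeyError(key)
        return _reaction_post(doc.reactions[rid], doc)
    raise UnknownKeyError(key)


def _map_link(fragment: str, label: str = "\U0001F310") -> str:
    # the globe anchor jumps back to the object on the map page
    return f'<a class="map-link" href="../index.html#{html.escape(fragment)}">{label}</a>'


def _entity_post(eid: str, doc: MapDocument, registry: ann.TagRegistry) -> str:
    entity = doc.entities[eid]
    adoc = ann.parse_annotation(entity.annotation_text)
    parts = [f"<h2>{html.escape(entity.display_name)}</h2>"]
    parts.append(ann.render_sections(adoc, registry))

    states = doc.states_of_entity(eid)
    forms = "".join(
        f"<li>{html.escape(naming.format_name(s, doc))} "
        f"{_map_link(s.state_id)}</li>"
        for s in states
    )
    parts.append(f"<h3>Forms</h3><ul>{forms}</ul>")

    rows = []
    for state in states:
        for rx in doc.reactions_of_state(state.state_id):
            for role in rx.roles_of(state.state_id):
                subtype = dict(rx.modifier_subtypes).get(state.state_id, "")
                role_text = role.value + (f" ({subtype})" if subtype else "")
                rows.append(
                    f"<li>{html.escape(rx.reaction_id)}: "
                    f"{html.escape(naming.format_name(state, doc))} as "
                    f"{html.escape(role_text)} {_map_link(rx.reaction_id)}</li>"
                )
    parts.append("<h3>Reactions</h3><ul>" + "".join(rows) + "</ul>")
    return "\n".join(parts)


def _module_post(name: str, sub: MapDocument) -> str:
    members = "".join(
        f"<li>{html.escape(naming.format_name(s, sub))} {_map_link(s.state_id)}</li>"
        for s in sub.species_states.values()
    )
    return (
        f"<h2>Module {html.escape(name)}</h2>"
        f"<ul>{members}</ul>"
    )


def _reaction_post(rx, doc: MapDocument) -> str:
    rows = []
    for sid, role in rx.participants:
        state = doc.species_states[sid]
        subtype = dict(rx.modifier_subtypes).get(sid, "")
        role_text = role.value + (f" ({subtype})" if subtype else "")
        rows.append(
            f"<li>{html.escape(naming.format_name(state, doc))}: "
            f"{html.escape(role_text)} {_map_link(sid)}</li>"
        )
    return (
        f"<h2>Reaction {html.escape(rx.reaction_id)}</h2>"
        f"<ul>{''.join(rows)}</ul> {_map_link(rx.reaction_id)}"
    )


def _digest(content: str) -> str:
    return hashlib.sha256(content.encode()).hexdigest()


# ---------------------------------------------------------------------------
# synchronization


@dataclass
class ChangeReport:
    added: list[str] = field(default_factory=list)
    updated: list[str] = field(default_factory=list)
    archived: list[str] = field(default_factory=list)
    unchanged: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.added or self.updated or self.archived)


def sync_store(
    store: PostStore,
    new_doc: MapDocument,
    modules: dict[str, MapDocument] | None = None,
    registry: ann.TagRegistry | None = None,
) -> tuple[PostStore, ChangeReport]:
    """Synchronize the store against a new map release.

    Pure: returns a new store; the input store is unchanged.  Records are
    only ever added or flipped ACTIVE->ARCHIVED, never deleted, so history
    is monotone and comments survive archiving.
    """
    store.check_integrity()
    report = ChangeReport()
    new_records = list(store.records)
    current_keys = post_keys_for(new_doc, modules)
    generated = {
        key: generate_post(key, new_doc, modules, registry) for key in current_keys
    }

    for key, content in generated.items():
        digest = _digest(content)
        active = store.active(key)
        if active is None:
            version = (store.history(key)[-1].version + 1) if store.history(key) else 1
            new_records.append(
                PostRecord(
                    key=key,
                    version=version,
                    status=PostStatus.ACTIVE,
                    content=content,
                    content_digest=digest,
                )
            )
            report.added.append(key)
        elif active.content_digest != digest:
            idx = new_records.index(active)
            new_records[idx] = replace(active, status=PostStatus.ARCHIVED)
            new_records.append(
                PostRecord(
                    key=key,
                    version=active.version + 1,
                    status=PostStatus.ACTIVE,
                    content=content,
                    content_digest=digest,
                )
            )
            report.updated.append(key)
        else:
            report.unchanged.append(key)

    wanted = set(generated)
    for r in store.records:
        if r.status is PostStatus.ACTIVE and r.key not in wanted:
            idx = new_records.index(r)
            new_records[idx] = replace(r, status=PostStatus.ARCHIVED)
            report.archived.append(r.key)

    out = PostStore(records=new_records)
    out.check_integrity()
    return out, report


def add_comment(store: PostStore, key: str, comment: Comment) -> PostStore:
    """Attach a comment to the ACTIVE post for *key* (new store returned)."""
    active = store.active(key)
    if active is None:
        raise UnknownKeyError(key)
    records = list(store.records)
    idx = records.index(active)
    records[idx] = replace(active, comments=active.comments + (comment,))
    return PostStore(records=records)


# ---------------------------------------------------------------------------
# persistence and rendering


def save_store(store: PostStore, path: Path) -> None:
    payload = [
        {
            "key": r.key,
            "version": r.version,
            "status": r.status.value,
            "content": r.content,
            "content_digest": r.content_digest,
            "comments": [
                {"author": c.author, "timestamp": c.timestamp, "text": c.text}
                for c in r.comments
            ],
        }
        for r in store.records
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_store(path: Path) -> PostStore:
    path = Path(path)
    if not path.exists():
        return PostStore()
    store = PostStore(
        records=[
            PostRecord(
                key=d["key"],
                version=d["version"],
                status=PostStatus(d["status"]),
                content=d["content"],
                content_digest=d["content_digest"],
                comments=tuple(
                    Comment(c["author"], c["timestamp"], c["text"])
                    for c in d["comments"]
                ),
            )
            for d in json.loads(path.read_text())
        ]
    )
    store.check_integrity()
    return store


_POST_PAGE = """<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8"><title>{title}</title>
<link rel="stylesheet" href="{css}"></head>
<body><header><h1>{title}</h1></header>
<main>{content}
<h3>Comments</h3>{comments}
{archive_note}</main></body></html>
"""


def render_posts(store: PostStore, posts_dir: Path) -> list[str]:
    """Render active posts to ``posts/<key>.html`` and archived versions to
    ``posts/archive/<key>-v<version>.html`` plus an archive index."""
    posts_dir = Path(posts_dir)
    archive_dir = posts_dir / "archive"
    archive_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    archived_entries: list[str] = []
    for r in store.records:
        comments = "".join(
            f'<div class="comment"><b>{html.escape(c.author)}</b> '
            f"({html.escape(c.timestamp)}): {c.text}</div>"
            for c in r.comments
        ) or "<p>No comments.</p>"
        if r.status is PostStatus.ACTIVE:
            rel = f"{r.key}.html"
            note = '<p><a href="archive/index.html">post archive</a></p>'
            out = posts_dir / rel
            css = "../assets/style.css"
        else:
            rel = f"archive/{r.key}-v{r.version}.html"
            note = f"<p>Archived version {r.version}.</p>"
            out = posts_dir / rel
            css = "../../assets/style.css"
            archived_entries.append(
                f'<li><a href="{html.escape(r.key)}-v{r.version}.html">'
                f"{html.escape(r.key)} v{r.version}</a></li>"
            )
        out.write_text(
            _POST_PAGE.format(
                title=html.escape(r.key), content=r.content,
                comments=comments, archive_note=note, css=css,
            )
        )
        written.append(f"posts/{rel}")
    (archive_dir / "index.html").write_text(
        _POST_PAGE.format(
            title="Post archive",
            content="<ul>" + "".join(archived_entries) + "</ul>",
            comments="", archive_note="", css="../../assets/style.css",
        )
    )
    written.append("posts/archive/index.html")
    return written


# ---------------------------------------------------------------------------
# remote adapter interface (hosting is out of scope; lifecycle is local)


class RemoteBlogAdapter:
    """Interface for pushing the post lifecycle to a hosted blog system.

    Implementations map the three lifecycle transitions onto the remote
    platform's API; the shipped :class:`NullBlogAdapter` records calls and
    does nothing, which is what the local ("simple mode") build uses.
    """

    def create_post(self, record: PostRecord) -> None:
        raise NotImplementedError

    def update_post(self, record: PostRecord) -> None:
        raise NotImplementedError

    def archive_post(self, record: PostRecord) -> None:
        raise NotImplementedError


class NullBlogAdapter(RemoteBlogAdapter):
    def __init__(self) -> None:
        self.calls: list[tuple[str, str, int]] = []

    def create_post(self, record: PostRecord) -> None:
        self.calls.append(("create", record.key, record.version))

    def update_post(self, record: PostRecord) -> None:
        self.calls.append(("update", record.key, record.version))

    def archive_post(self, record: PostRecord) -> None:
        self.calls.append(("archive", record.key, record.version))
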