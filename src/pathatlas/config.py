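"""Build configuration: one JSON file naming the map, views and options.

Validated field by field with explicit error messages (no schema engine);
``load_config`` resolves relative paths against the config file's own
directory so a fixture directory is relocatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .zoomtiles import DEFAULT_TILE_EDGE

MODES = ("simple", "complete")


class ConfigError(ValueError):
    """Config missing, unreadable or schema-invalid (message names the field)."""


@dataclass
class BuildConfig:
    map_name: str
    map_file: Path
    view_files: list[Path]
    module_files: dict[str, Path] = field(default_factory=dict)
    mode: str = "simple"
    tile_edge: int = DEFAULT_TILE_EDGE
    tags: dict[str, str] = field(default_factory=dict)
    include_source_link: bool = False
    output: Path | None = None


def load_config(path: Path) -> BuildConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    base = path.parent

    def fail(fieldname: str, why: str) -> ConfigError:
        return ConfigError(f"config field {fieldname!r}: {why}")

    map_section = raw.get("map")
    if not isinstance(map_section, dict):
        raise fail("map", "required object with 'name' and 'file'")
    name = map_section.get("name")
    if not isinstance(name, str) or not name:
        raise fail("map.name", "required non-empty string")
    map_file = map_section.get("file")
    if not isinstance(map_file, str):
        raise fail("map.file", "required string path")

    views = raw.get("views")
    if not isinstance(views, list) or not views or not all(
        isinstance(v, str) for v in views
    ):
        raise fail("views", "required non-empty list of image paths")

    modules = raw.get("modules", {})
    if not isinstance(modules, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in modules.items()
    ):
        raise fail("modules", "must be an object of name -> xml path")

    mode = raw.get("mode", "simple")
    if mode not in MODES:
        raise fail("mode", f"must be one of {MODES}")

    tile_edge = raw.get("tile_edge", DEFAULT_TILE_EDGE)
    if not isinstance(tile_edge, int) or tile_edge <= 0:
        raise fail("tile_edge", "must be a positive integer")

    tags = raw.get("tags", {})
    if not isinstance(tags, dict) or not all(
        isinstance(k, str) and isinstance(v, str) and v.count("{id}") == 1
        for k, v in tags.items()
    ):
        raise fail("tags", "must map prefix -> URL template with one {id}")

    include_source_link = raw.get("include_source_link", False)
    if not isinstance(include_source_link, bool):
        raise fail("include_source_link", "must be a boolean")

    output = raw.get("output")
    if output is not None and not isinstance(output, str):
        raise fail("output", "must be a string path")

    return BuildConfig(
        map_name=name,
        map_file=base / map_file,
        view_files=[base / v for v in views],
        module_files={k: base / v for k, v in modules.items()},
        mode=mode,
        tile_edge=tile_edge,
        tags=tags,
        include_source_link=include_source_link,
        output=base / output if output else None,
    )
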