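"""Semantic-zoom view chains and fixed-size tile pyramids.

A map ships with a chain of zoom views: level 0 is the least detailed
(top-level) image and each deeper level doubles both pixel dimensions, so
that a tiled slippy-map viewer can swap levels without moving content.
Three constraints follow from that viewer contract: consecutive views must
differ by exactly a factor of two, the aspect ratio must not drift (objects
must keep their relative positions), and dimensions divisible by the tile
edge (256 px) are preferred — the last is only a preference, so violations
are warnings and edge tiles are padded.

When the map manager supplies only the most- and least-detailed views, the
intermediate levels are synthesized by factor-2 area-average downscaling of
the detailed image; such views are flagged ``semantic=False`` since nothing
is re-drawn for them, only resampled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from PIL import Image

DEFAULT_TILE_EDGE = 256
DEFAULT_FILL = (255, 255, 255, 255)  # opaque white, CellDesigner's canvas color


@dataclass
class ZoomView:
    level: int
    width: int
    height: int
    image: Image.Image | None = None
    semantic: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"zoom view level {self.level} has empty size "
                f"{self.width}x{self.height}"
            )
        if self.image is not None and self.image.size != (self.width, self.height):
            raise ValueError(
                f"zoom view level {self.level}: image size {self.image.size} "
                f"does not match declared {self.width}x{self.height}"
            )


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_view_chain(
    views: list[ZoomView], tile_edge: int = DEFAULT_TILE_EDGE
) -> ValidationReport:
    """Check the half-size rule, aspect-ratio conservation and tile-edge
    divisibility over a level-sorted view chain."""
    if not views:
        raise ValueError("view chain is empty")
    report = ValidationReport()
    for a, b in zip(views, views[1:]):
        if b.width != 2 * a.width or b.height != 2 * a.height:
            report.issues.append(
                ValidationIssue(
                    "error",
                    f"levels {a.level}->{b.level}: {b.width}x{b.height} is not "
                    f"exactly twice {a.width}x{a.height} (half-size rule)",
                )
            )
        elif a.width * b.height != b.width * a.height:
            report.issues.append(
                ValidationIssue(
                    "error",
                    f"levels {a.level}->{b.level}: aspect ratio drifts "
                    f"({a.width}:{a.height} vs {b.width}:{b.height})",
                )
            )
    for v in views:
        # sizes below one tile are unavoidable at coarse levels and simply
        # padded; the divisibility preference only bites above the edge
        if (v.width % tile_edge and v.width > tile_edge) or (
            v.height % tile_edge and v.height > tile_edge
        ):
            report.issues.append(
                ValidationIssue(
                    "warning",
                    f"level {v.level}: {v.width}x{v.height} not divisible by "
                    f"{tile_edge}; edge tiles will be padded",
                )
            )
    return report


def autogenerate_intermediates(detailed: ZoomView, top: ZoomView) -> list[ZoomView]:
    """Fill the chain between *top* (level 0) and *detailed* by repeated
    factor-2 downscaling of the detailed image.

    The detailed width must be ``top.width * 2**k``; the returned chain has
    ``k + 1`` views ordered coarse to fine.  The two supplied views are
    returned as-is (manager-supplied views are never overwritten)."""
    if detailed.width % top.width or detailed.height % top.height:
        raise ValueError(
            f"detailed view ({detailed.width}px) is not a power-of-two "
            f"multiple of the top view ({top.width}px)"
        )
    ratio = detailed.width // top.width
    k = ratio.bit_length() - 1
    if 2**k != ratio or detailed.height != top.height * ratio:
        raise ValueError(
            f"view widths {detailed.width} and {top.width} are not related "
            "by a power of two"
        )
    if k == 0:
        return [ZoomView(0, detailed.width, detailed.height, detailed.image,
                         detailed.semantic)]
    chain: list[ZoomView] = [None] * (k + 1)  # type: ignore[list-item]
    chain[0] = ZoomView(0, top.width, top.height, top.image, top.semantic)
    chain[k] = ZoomView(k, detailed.width, detailed.height, detailed.image,
                        detailed.semantic)
    img = detailed.image
    for level in range(k - 1, 0, -1):
        w = top.width * 2**level
        h = top.height * 2**level
        if img is not None:
            img = img.resize((w, h), Image.Resampling.BOX)  # area average
        chain[level] = ZoomView(level, w, h, img, semantic=False)
    return chain


def cut_tiles(
    view: ZoomView,
    tile_edge: int = DEFAULT_TILE_EDGE,
    fill=DEFAULT_FILL,
) -> dict[tuple[int, int], Image.Image]:
    """Cut one level into ``ceil(w/edge) x ceil(h/edge)`` square tiles.

    Interior tiles are exact crops; right/bottom edge tiles are padded to
    the full tile edge with *fill*."""
    if tile_edge <= 0:
        raise ValueError("tile_edge must be positive")
    if view.image is None:
        raise ValueError(f"level {view.level} has no raster to tile")
    img = view.image.convert("RGBA")
    nx = math.ceil(view.width / tile_edge)
    ny = math.ceil(view.height / tile_edge)
    tiles: dict[tuple[int, int], Image.Image] = {}
    for ty in range(ny):
        for tx in range(nx):
            x0, y0 = tx * tile_edge, ty * tile_edge
            x1, y1 = min(x0 + tile_edge, view.width), min(y0 + tile_edge, view.height)
            crop = img.crop((x0, y0, x1, y1))
            if crop.size != (tile_edge, tile_edge):
                tile = Image.new("RGBA", (tile_edge, tile_edge), fill)
                tile.paste(crop, (0, 0))
            else:
                tile = crop
            tiles[(tx, ty)] = tile
    return tiles


@dataclass
class TilePyramid:
    tile_edge: int
    levels: list[ZoomView]
    tiles: dict[tuple[int, int, int], Image.Image] = field(default_factory=dict)

    def tile_grid(self, level: int) -> tuple[int, int]:
        v = self._view(level)
        return (
            math.ceil(v.width / self.tile_edge),
            math.ceil(v.height / self.tile_edge),
        )

    def _view(self, level: int) -> ZoomView:
        for v in self.levels:
            if v.level == level:
                return v
        raise KeyError(f"no zoom level {level} in pyramid")

    def scale_point(
        self, p: tuple[float, float], from_level: int, to_level: int
    ) -> tuple[float, float]:
        """Map canvas coordinates between zoom levels.

        Each level doubles the pixel size, so the transform is a pure scale
        by ``2**(to - from)``; markers placed from the most-detailed alias
        record therefore stay put visually at every level."""
        self._view(from_level), self._view(to_level)
        f = 2.0 ** (to_level - from_level)
        return (p[0] * f, p[1] * f)

    @property
    def descriptor(self) -> dict:
        return {
            "tile_edge": self.tile_edge,
            "levels": [
                {
                    "level": v.level,
                    "width": v.width,
                    "height": v.height,
                    "semantic": v.semantic,
                }
                for v in self.levels
            ],
        }


def build_pyramid(
    views: list[ZoomView],
    tile_edge: int = DEFAULT_TILE_EDGE,
    fill=DEFAULT_FILL,
    strict: bool = True,
) -> TilePyramid:
    """Validate a view chain and tile every level."""
    report = validate_view_chain(views, tile_edge)
    if strict and not report.ok:
        raise ValueError(
            "invalid view chain: " + "; ".join(i.message for i in report.errors)
        )
    pyramid = TilePyramid(tile_edge=tile_edge, levels=list(views))
    for v in views:
        for (tx, ty), tile in cut_tiles(v, tile_edge, fill).items():
            pyramid.tiles[(v.level, tx, ty)] = tile
    return pyramid


def write_pyramid(pyramid: TilePyramid, out_dir: Path) -> Path:
    """Write tiles as ``{level}/{tx}_{ty}.png`` plus a JSON descriptor;
    returns the descriptor path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (level, tx, ty), tile in pyramid.tiles.items():
        d = out_dir / str(level)
        d.mkdir(exist_ok=True)
        tile.save(d / f"{tx}_{ty}.png")
    desc = out_dir / "pyramid.json"
    desc.write_text(json.dumps(pyramid.descriptor, indent=1))
    return desc
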