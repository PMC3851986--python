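"""Zoom-view chains, tile cutting and cross-level coordinate scaling."""

import math

import pytest
from PIL import Image

from pathatlas.zoomtiles import (
    ZoomView,
    autogenerate_intermediates,
    build_pyramid,
    cut_tiles,
    validate_view_chain,
)


def _view(level, w, h, noise=False):
    img = Image.new("RGB", (w, h), (255, 255, 255))
    if noise:
        # deterministic non-uniform content so crops are distinguishable
        px = img.load()
        for y in range(0, h, 7):
            for x in range(0, w, 5):
                px[x, y] = ((x * 37) % 256, (y * 91) % 256, (x + y) % 256)
    return ZoomView(level=level, width=w, height=h, image=img)


class TestValidateChain:
    def test_exact_factor2_chain_clean(self):
        views = [
            _view(0, 256, 128), _view(1, 512, 256),
            _view(2, 1024, 512), _view(3, 2048, 1024),
        ]
        report = validate_view_chain(views)
        assert report.ok and not report.warnings

    def test_half_size_violation_is_error(self):
        report = validate_view_chain([_view(0, 700, 350), _view(1, 1000, 500)])
        assert not report.ok
        assert "half-size" in report.errors[0].message

    def test_non_divisible_single_view_warns_only(self):
        report = validate_view_chain([_view(0, 300, 300)])
        assert report.ok
        assert len(report.warnings) == 1

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            validate_view_chain([])


class TestIntermediates:
    def test_eightfold_gap_yields_four_levels(self):
        detailed = _view(3, 2048, 1024)
        top = _view(0, 256, 128)
        chain = autogenerate_intermediates(detailed, top)
        assert [v.width for v in chain] == [256, 512, 1024, 2048]
        assert [v.level for v in chain] == [0, 1, 2, 3]
        # manager-supplied endpoints kept, synthesized middles flagged
        assert chain[0].semantic and chain[3].semantic
        assert not chain[1].semantic and not chain[2].semantic
        assert validate_view_chain(chain).ok

    def test_equal_views_single_level(self):
        chain = autogenerate_intermediates(_view(0, 512, 512), _view(0, 512, 512))
        assert len(chain) == 1

    def test_factor_two_gap_two_levels(self):
        chain = autogenerate_intermediates(_view(1, 512, 256), _view(0, 256, 128))
        assert len(chain) == 2

    def test_non_power_of_two_ratio_rejected(self):
        with pytest.raises(ValueError, match="768"):
            autogenerate_intermediates(_view(1, 768, 768), _view(0, 256, 256))

    def test_downscale_conserves_aspect_ratio(self):
        chain = autogenerate_intermediates(_view(2, 1024, 512), _view(0, 256, 128))
        ratios = {v.width / v.height for v in chain}
        assert ratios == {2.0}


class TestCutTiles:
    @pytest.mark.parametrize(
        "w,h,expected",
        [(1024, 512, 8), (256, 256, 1), (300, 300, 4), (257, 256, 2)],
    )
    def test_tile_counts_follow_ceil_formula(self, w, h, expected):
        tiles = cut_tiles(_view(0, w, h))
        assert len(tiles) == expected
        assert len(tiles) == math.ceil(w / 256) * math.ceil(h / 256)

    def test_all_tiles_are_square_256(self):
        for tile in cut_tiles(_view(0, 300, 300)).values():
            assert tile.size == (256, 256)

    def test_interior_reassembly_byte_exact(self):
        view = _view(0, 512, 512, noise=True)
        tiles = cut_tiles(view)
        canvas = Image.new("RGBA", (512, 512))
        for (tx, ty), tile in tiles.items():
            canvas.paste(tile, (tx * 256, ty * 256))
        assert canvas.tobytes() == view.image.convert("RGBA").tobytes()

    def test_edge_tiles_padded_with_fill(self):
        view = _view(0, 300, 300, noise=True)
        tiles = cut_tiles(view, fill=(255, 0, 0, 255))
        right = tiles[(1, 0)]
        assert right.getpixel((255, 0)) == (255, 0, 0, 255)  # beyond source
        # unpadded region of the edge tile is still an exact crop
        assert (
            right.crop((0, 0, 44, 256)).tobytes()
            == view.image.convert("RGBA").crop((256, 0, 300, 256)).tobytes()
        )


class TestScalePoint:
    @pytest.fixture
    def pyramid(self):
        views = [
            _view(0, 256, 128), _view(1, 512, 256),
            _view(2, 1024, 512), _view(3, 2048, 1024),
        ]
        return build_pyramid(views)

    def test_detail_to_top_divides_by_eight(self, pyramid):
        assert pyramid.scale_point((512, 256), 3, 0) == (64, 32)

    def test_identity_when_levels_equal(self, pyramid):
        assert pyramid.scale_point((17.5, 3.25), 2, 2) == (17.5, 3.25)

    def test_origin_is_fixed_point(self, pyramid):
        for lv in range(4):
            assert pyramid.scale_point((0, 0), 3, lv) == (0, 0)

    def test_composition_equals_direct(self, pyramid):
        for p in [(10, 20), (512, 256), (1.5, 999)]:
            via = pyramid.scale_point(pyramid.scale_point(p, 3, 1), 1, 0)
            assert via == pyramid.scale_point(p, 3, 0)

    def test_unknown_level_raises(self, pyramid):
        with pytest.raises(KeyError):
            pyramid.scale_point((1, 1), 0, 9)


class TestPyramid:
    def test_tile_count_invariant_on_all_levels(self):
        views = [_view(0, 256, 128), _view(1, 512, 256), _view(2, 1024, 512)]
        pyramid = build_pyramid(views)
        for v in views:
            nx, ny = pyramid.tile_grid(v.level)
            level_tiles = [k for k in pyramid.tiles if k[0] == v.level]
            assert len(level_tiles) == nx * ny

    def test_write_pyramid_layout(self, tmp_path):
        import json

        from pathatlas.zoomtiles import write_pyramid

        pyramid = build_pyramid([_view(0, 256, 128), _view(1, 512, 256)])
        desc = json.loads(write_pyramid(pyramid, tmp_path).read_text())
        assert desc["tile_edge"] == 256
        assert (tmp_path / "1" / "1_0.png").exists()
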