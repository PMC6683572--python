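import hashlib

import numpy as np
import pytest

import _oracle
from coverimg.classify import (
    LabelCounts,
    PixelLabel,
    classify_image,
    classify_pixel,
    render_mask_overlay,
)
from coverimg.color_space import Color
from coverimg.raster_io import Raster
from coverimg.selection import Selection


def _sel(include, ignore=(), metric="rgb", tolerance=35.0):
    return Selection(name="t", include=tuple(include), ignore=tuple(ignore),
                     metric=metric, tolerance=tolerance)


class TestClassifyPixel:
    def test_single_include_match(self):
        sel = _sel([(10, 10, 10)], [(200, 200, 200)])
        assert classify_pixel(Color(12, 10, 10), sel) == PixelLabel.FOREGROUND

    def test_single_ignore_match(self):
        sel = _sel([(10, 10, 10)], [(200, 200, 200)])
        assert classify_pixel(Color(198, 200, 205), sel) == PixelLabel.IGNORED

    def test_neither_is_background(self):
        sel = _sel([(10, 10, 10)], [(200, 200, 200)])
        assert classify_pixel(Color(100, 100, 100), sel) == PixelLabel.BACKGROUND

    def test_exact_tie_resolves_to_ignored(self):
        # pixel equidistant (measure 100) from include and ignore channels
        sel = _sel([(10, 10, 10)], [(30, 10, 10)], tolerance=11)
        assert classify_pixel(Color(20, 10, 10), sel) == PixelLabel.IGNORED

    def test_nearest_include_wins_when_closer(self):
        sel = _sel([(10, 10, 10)], [(31, 10, 10)], tolerance=12)
        assert classify_pixel(Color(20, 10, 10), sel) == PixelLabel.FOREGROUND

    @pytest.mark.parametrize("policy,expected", [
        ("nearest", PixelLabel.IGNORED),
        ("ignore-wins", PixelLabel.IGNORED),
        ("include-wins", PixelLabel.FOREGROUND),
    ])
    def test_conflict_policies_on_tie(self, policy, expected):
        sel = _sel([(10, 10, 10)], [(30, 10, 10)], tolerance=11)
        assert classify_pixel(Color(20, 10, 10), sel, conflict=policy) == expected

    def test_exhaustive_1d_family_matches_oracle(self):
        # every gray pixel value vs the same selection, all three policies
        sel = _sel([(60, 60, 60)], [(90, 90, 90)], tolerance=40)
        for policy in ("nearest", "ignore-wins", "include-wins"):
            for v in range(256):
                got = classify_pixel(Color(v, v, v), sel, conflict=policy)
                want = _oracle.classify(
                    [[(v, v, v)]], sel.include, sel.ignore,
                    sel.tolerance, sel.metric, policy,
                )[0][0]
                assert int(got) == want, (v, policy)


class TestClassifyImage:
    def test_uniform_image_saturates(self):
        img = Raster(pixels=np.full((6, 6, 3), (52, 130, 60), np.uint8))
        sel = _sel([(52, 130, 60)])
        _, counts = classify_image(img, sel)
        assert (counts.c, counts.i, counts.b) == (36, 0, 0)

    def test_constructed_60x60_counts(self):
        # 1200 px == include channel, 400 px == ignore channel, rest far away
        px = np.full((60, 60, 3), (200, 40, 200), np.uint8)  # far from both
        flat = px.reshape(-1, 3)
        flat[:1200] = (52, 130, 60)
        flat[1200:1600] = (255, 255, 255)
        img = Raster(pixels=px)
        sel = _sel([(52, 130, 60)], [(255, 255, 255)], tolerance=35)
        _, counts = classify_image(img, sel)
        assert (counts.c, counts.i, counts.b) == (1200, 400, 2000)
        assert counts.n == 3600

    @pytest.mark.parametrize("metric", ["rgb", "ycbcr"])
    @pytest.mark.parametrize("policy", ["nearest", "ignore-wins", "include-wins"])
    def test_matches_oracle_bit_exactly(self, metric, policy, rng):
        for trial in range(4):
            px = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
            include = [Color(*rng.integers(0, 256, 3)) for _ in range(3)]
            ignore = [Color(*rng.integers(0, 256, 3)) for _ in range(2)]
            tol = float(rng.choice([0, 15, 35, 80, 200]))
            sel = _sel(include, ignore, metric=metric, tolerance=tol)
            mask, counts = classify_image(Raster(pixels=px), sel, conflict=policy)
            want = np.array(
                _oracle.classify(px, include, ignore, tol, metric, policy),
                dtype=np.uint8,
            )
            assert np.array_equal(mask.labels, want)

    def test_conservation(self, random_raster, basic_selection):
        _, counts = classify_image(random_raster(20, 20, seed=1),
                                   basic_selection)
        assert counts.c + counts.i + counts.b == counts.n == 400

    def test_determinism_hash_compared(self, random_raster, basic_selection):
        img = random_raster(20, 20, seed=2)
        h = [
            hashlib.sha256(
                classify_image(img, basic_selection)[0].labels.tobytes()
            ).hexdigest()
            for _ in range(2)
        ]
        assert h[0] == h[1]

    def test_nonbackground_set_monotone_in_tolerance(self, random_raster):
        img = random_raster(24, 24, seed=3)
        sel = _sel([(52, 130, 60), (180, 150, 45)], [(255, 255, 255)])
        prev = None
        for tol in (0, 10, 20, 35, 60, 120, 250):
            mask, _ = classify_image(img, sel.with_overrides(tolerance=tol))
            nonbg = mask.labels != int(PixelLabel.BACKGROUND)
            if prev is not None:
                assert (prev <= nonbg).all()  # never shrinks
            prev = nonbg

    def test_foreground_can_flip_to_ignored_under_ignore_wins(self):
        # min_inc=400 < min_ign=900: FOREGROUND at tol 21; at tol 31 the
        # ignore channel comes into range and the ignore-wins policy flips
        # the pixel, so C alone is not monotone under that policy
        px = Color(20, 10, 10)
        sel = _sel([(40, 10, 10)], [(50, 10, 10)])
        lo = sel.with_overrides(tolerance=21)
        hi = sel.with_overrides(tolerance=31)
        assert classify_pixel(px, lo, "ignore-wins") == PixelLabel.FOREGROUND
        assert classify_pixel(px, hi, "ignore-wins") == PixelLabel.IGNORED
        # under the default nearest policy the nearer include channel keeps it
        assert classify_pixel(px, hi, "nearest") == PixelLabel.FOREGROUND

    def test_tolerance_zero_all_background(self, random_raster):
        img = random_raster(10, 10, seed=4)
        sel = _sel([(52, 130, 60)], [(255, 255, 255)], tolerance=0)
        _, counts = classify_image(img, sel)
        assert counts.b == counts.n

    def test_tolerance_above_max_rgb_all_foreground(self, random_raster):
        img = random_raster(10, 10, seed=5)
        sel = _sel([(52, 130, 60)], tolerance=443)  # > sqrt(3 * 255^2)
        _, counts = classify_image(img, sel)
        assert counts.c == counts.n


class TestLabelCounts:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            LabelCounts(n=10, c=5, i=3, b=3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            LabelCounts(n=1, c=-1, i=1, b=1)


class TestRenderMaskOverlay:
    def test_all_foreground_is_identity(self, random_raster, basic_selection):
        img = Raster(pixels=np.full((5, 5, 3), (52, 130, 60), np.uint8))
        mask, _ = classify_image(img, basic_selection)
        out = render_mask_overlay(img, mask)
        assert np.array_equal(out.pixels, img.pixels)

    def test_all_background_is_uniform_palette(self, basic_selection):
        img = Raster(pixels=np.full((5, 5, 3), (200, 40, 200), np.uint8))
        mask, _ = classify_image(img, basic_selection)
        out = render_mask_overlay(
            img, mask, {PixelLabel.IGNORED: Color(0, 0, 255),
                        PixelLabel.BACKGROUND: Color(7, 7, 7)}
        )
        assert (out.pixels == (7, 7, 7)).all()

    def test_changed_pixel_count_is_i_plus_b(self, random_raster,
                                             basic_selection):
        img = random_raster(16, 16, seed=6)
        mask, counts = classify_image(img, basic_selection)
        out = render_mask_overlay(
            img, mask, {PixelLabel.IGNORED: Color(1, 0, 0),
                        PixelLabel.BACKGROUND: Color(2, 0, 0)}
        )
        changed = (out.pixels != img.pixels).any(axis=2).sum()
        assert changed == counts.i + counts.b

    def test_dimension_mismatch(self, random_raster, basic_selection):
        img = random_raster(8, 8, seed=7)
        mask, _ = classify_image(img, basic_selection)
        with pytest.raises(ValueError, match="match"):
            render_mask_overlay(random_raster(9, 8, seed=8), mask)
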