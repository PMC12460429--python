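import math

import numpy as np
import pytest

from citruspick import matching
from citruspick.labelio import FRUIT_CLASS, STEM_CLASS
from citruspick.matching import FittedLine, fit_points_line, point_line_distance

import oracles
from conftest import bar_mask, disk_mask, make_mask


class TestFitLine:
    def test_collinear_points_recover_slope_intercept_exactly(self):
        pts = np.array([(0, 1), (1, 3), (2, 5)], dtype=float)
        line = fit_points_line(pts, method="ols")
        a, b = line.slope_intercept
        assert a == pytest.approx(2.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_vertical_points_tls(self):
        pts = np.array([(3, 0), (3, 5), (3, 9)], dtype=float)
        line = fit_points_line(pts, method="tls")
        assert abs(line.direction[0]) < 1e-12 and abs(abs(line.direction[1]) - 1) < 1e-12
        assert line.anchor[0] == pytest.approx(3.0)
        assert line.slope_intercept is None

    def test_vertical_points_ols_errors_toward_tls(self):
        pts = np.array([(3, 0), (3, 5)], dtype=float)
        with pytest.raises(ValueError, match="tls"):
            fit_points_line(pts, method="ols")

    def test_fewer_than_two_distinct_points_errors(self):
        with pytest.raises(ValueError):
            fit_points_line(np.array([(1.0, 1.0), (1.0, 1.0)]))

    def test_noisy_ols_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 100, 200)
        y = 0.5 * x + 10 + rng.normal(0, 1, 200)
        pts = np.column_stack([x, y])
        line = fit_points_line(pts, method="ols")
        a, b = line.slope_intercept
        a0, b0 = oracles.ols_line([tuple(p) for p in pts])
        assert a == pytest.approx(a0, abs=1e-9)
        assert b == pytest.approx(b0, abs=1e-9)

    def test_tls_agrees_with_ols_on_exact_line(self):
        pts = np.array([(0.0, 1.0), (1.0, 3.0), (2.0, 5.0), (5.0, 11.0)])
        a_tls, b_tls = fit_points_line(pts, method="tls").slope_intercept
        a_ols, b_ols = fit_points_line(pts, method="ols").slope_intercept
        assert a_tls == pytest.approx(a_ols, abs=1e-9)
        assert b_tls == pytest.approx(b_ols, abs=1e-9)

    @pytest.mark.parametrize("mode", ["contour", "all_pixels"])
    def test_stem_mask_fit_tracks_bar_axis(self, mode):
        stem = bar_mask((100, 100), 20, 60, 50, 54)
        line = matching.fit_stem_line(stem, mode=mode, method="tls")
        # horizontal bar: direction ~ (1, 0), passes near y = 52
        assert abs(line.direction[1]) < 0.05
        assert point_line_distance((40.0, 52.0), line) < 1.0


class TestFruitFeatures:
    def test_two_by_two_block_centroid(self):
        m = np.zeros((40, 40), bool)
        m[20:22, 10:12] = True
        feat = matching.fruit_features(make_mask(m))
        assert feat.centroid == (10.5, 20.5)
        assert feat.pixel_count == 4

    def test_single_pixel(self):
        m = np.zeros((10, 10), bool)
        m[7, 5] = True
        feat = matching.fruit_features(make_mask(m))
        assert feat.centroid == (5.0, 7.0)
        assert feat.r_min == feat.r_max == 0.0

    def test_disk_radii_and_centroid(self):
        fruit = disk_mask((100, 100), 50, 50, 10)
        feat = matching.fruit_features(fruit)
        assert abs(feat.centroid[0] - 50) < 0.1 and abs(feat.centroid[1] - 50) < 0.1
        assert 9 <= feat.r_min <= feat.r_max <= 11

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            matching.fruit_features(make_mask(np.zeros((5, 5), bool)))


class TestPointLineDistance:
    @pytest.mark.parametrize(
        "line, point, expected",
        [
            (FittedLine.from_slope_intercept(1.0, 0.0), (0.0, 1.0), 1 / math.sqrt(2)),
            (FittedLine.from_slope_intercept(1.0, 0.0), (4.0, 4.0), 0.0),
            (FittedLine.vertical(3.0), (5.0, 0.0), 2.0),
            (FittedLine.from_slope_intercept(0.0, 2.0), (7.0, 5.0), 3.0),
        ],
    )
    def test_textbook_distances(self, line, point, expected):
        assert point_line_distance(point, line) == pytest.approx(expected, abs=1e-12)

    def test_slope_form_and_anchor_form_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=2)
            line = FittedLine.from_slope_intercept(a, b)
            x, y = rng.uniform(-10, 10, 2)
            d_formula = abs(a * x - y + b) / math.sqrt(a * a + 1)
            assert point_line_distance((x, y), line) == pytest.approx(d_formula, abs=1e-9)


class TestMatchScene:
    def test_disk_near_line_matches(self):
        fruit = disk_mask((100, 100), 50, 50, 10)
        feat = matching.fruit_features(fruit)
        line = FittedLine.from_slope_intercept(0.0, 53.0)  # horizontal, 3 px away
        (res,) = matching.match_scene([feat], [(0, line)])
        assert res.matched and res.best_stem == 0
        assert res.d1 == pytest.approx(3.0, abs=0.2)
        assert res.threshold == pytest.approx(feat.r_max)

    def test_far_line_unmatched(self):
        fruit = disk_mask((100, 100), 30, 30, 8)
        feat = matching.fruit_features(fruit)
        line = FittedLine.vertical(90.0)
        (res,) = matching.match_scene([feat], [(0, line)])
        assert not res.matched and res.d1 > res.threshold

    def test_no_stems_gives_unmatched_empty_map(self):
        feat = matching.fruit_features(disk_mask((50, 50), 25, 25, 5))
        (res,) = matching.match_scene([feat], [])
        assert not res.matched and res.candidate_distances == {} and res.d1 is None

    def test_radius_mode_min_uses_r_min(self):
        # slightly elliptical fruit: r_min < d1 < r_max leaves the fruit
        # matched under "max" but unmatched under "min"
        m = np.zeros((120, 120), bool)
        yy, xx = np.mgrid[:120, :120]
        m |= ((xx - 60) / 20) ** 2 + ((yy - 60) / 12) ** 2 <= 1
        feat = matching.fruit_features(make_mask(m))
        line = FittedLine.vertical(60 + 16.0)
        (res_max,) = matching.match_scene([feat], [(0, line)], radius_mode="max")
        (res_min,) = matching.match_scene([feat], [(0, line)], radius_mode="min")
        assert res_max.matched and not res_min.matched

    def test_tie_breaks_to_lowest_stem_id(self):
        feat = matching.fruit_features(disk_mask((100, 100), 50, 50, 10))
        left = FittedLine.vertical(45.0)
        right = FittedLine.vertical(55.0)
        (res,) = matching.match_scene([feat], [(7, right), (2, left)])
        assert res.best_stem == 2

    def test_d1_non_increasing_as_stems_added(self):
        feat = matching.fruit_features(disk_mask((100, 100), 50, 50, 10))
        stems = [(i, FittedLine.vertical(float(90 - 10 * i))) for i in range(5)]
        prev = math.inf
        for k in range(1, 6):
            (res,) = matching.match_scene([feat], stems[:k])
            assert res.d1 <= prev + 1e-12
            prev = res.d1

    def test_equivalence_with_brute_force_on_scenes(self, clean_scenes):
        for masks, truth in clean_scenes[:10]:
            fruits = [m for m in masks if m.class_id == FRUIT_CLASS]
            stems = [m for m in masks if m.class_id == STEM_CLASS]
            feats = [matching.fruit_features(f) for f in fruits]
            fitted = [(s.instance_id, matching.fit_stem_line(s)) for s in stems]
            got = matching.match_scene(feats, fitted)
            expected = oracles.brute_force_match(
                feats, [(sid, l.anchor, l.direction) for sid, l in fitted]
            )
            for g, e in zip(got, expected):
                assert g.fruit_id == e["fruit_id"]
                assert g.matched == e["matched"]
                assert g.best_stem == e["best_stem"]
                assert g.d1 == pytest.approx(e["d1"], abs=1e-9)

    def test_shared_stem_scene_maps_both_fruits_to_one_stem(self):
        from citruspick.scenegen import SceneConfig, generate_scene

        masks, truth = generate_scene(
            SceneConfig(n_fruits=2, p_shared_stem=1.0, p_fruitless_stem=0.0, seed=5)
        )
        assert len(truth.stems) == 1
        fruits = [m for m in masks if m.class_id == FRUIT_CLASS]
        stems = [m for m in masks if m.class_id == STEM_CLASS]
        feats = [matching.fruit_features(f) for f in fruits]
        fitted = [(s.instance_id, matching.fit_stem_line(s)) for s in stems]
        results = matching.match_scene(feats, fitted)
        assert all(r.matched for r in results)
        assert len({r.best_stem for r in results}) == 1

    def test_rigid_transform_equivariance(self, clean_scenes):
        """90-degree rotation of all masks preserves match flags and distances."""
        masks, _ = clean_scenes[0]
        fruits = [m for m in masks if m.class_id == FRUIT_CLASS]
        stems = [m for m in masks if m.class_id == STEM_CLASS]

        def run(fr, stm):
            feats = [matching.fruit_features(f) for f in fr]
            fitted = [(s.instance_id, matching.fit_stem_line(s, method="tls")) for s in stm]
            return matching.match_scene(feats, fitted)

        base = run(fruits, stems)
        from conftest import make_mask

        rot_fruits = [
            make_mask(np.rot90(m.raster), class_id=m.class_id, instance_id=m.instance_id)
            for m in fruits
        ]
        rot_stems = [
            make_mask(np.rot90(m.raster), class_id=m.class_id, instance_id=m.instance_id)
            for m in stems
        ]
        rotated = run(rot_fruits, rot_stems)
        for b, r in zip(base, rotated):
            assert b.matched == r.matched
            assert b.best_stem == r.best_stem
            assert b.d1 == pytest.approx(r.d1, abs=1e-6)
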