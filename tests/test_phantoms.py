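"""Phantom geometry oracles and cohort-generator statistics."""

import numpy as np
import pytest

from cervitrace.phantoms import (
    DEFAULT_EFFECT_MODEL,
    CenterlineOutOfViewError,
    PhantomSpec,
    centerline_point,
    generate_cohort,
    generate_phantom,
    random_phantom_spec,
    true_arc_length,
    true_chord_length,
)

from conftest import semicircle_spec


class TestArcLength:
    def test_straight_segment_is_its_chord(self):
        spec = PhantomSpec("straight", [(10, 10), (10, 40)],
                           image_shape_px=(256, 256), pixel_spacing_mm=0.2)
        assert true_arc_length(spec) == pytest.approx(30.0, abs=1e-9)
        assert true_chord_length(spec) == pytest.approx(30.0, abs=1e-12)

    def test_semicircle_is_fifteen_pi(self):
        spec = semicircle_spec(0.2)
        assert true_arc_length(spec) == pytest.approx(15 * np.pi, rel=1e-9)
        assert true_chord_length(spec) == pytest.approx(30.0, abs=1e-9)

    def test_quarter_circle_closed_form(self):
        c, r = (40.0, 40.0), 20.0
        pts = [(c[0] - r, c[1]),
               (c[0] - r * np.cos(np.pi / 4), c[1] - r * np.sin(np.pi / 4)),
               (c[0], c[1] - r)]
        spec = PhantomSpec("circular_arc", pts, image_shape_px=(320, 320),
                           pixel_spacing_mm=0.2)
        assert true_arc_length(spec) == pytest.approx(10 * np.pi, rel=1e-9)

    def test_cubic_bezier_matches_polyline_refinement(self):
        spec = PhantomSpec("bezier_cubic",
                           [(10, 10), (30, 20), (8, 30), (20, 40)],
                           image_shape_px=(256, 256), pixel_spacing_mm=0.2)
        t = np.linspace(0, 1, 10 ** 6)
        poly = np.sum(np.linalg.norm(
            np.diff(centerline_point(spec, t), axis=0), axis=1))
        assert true_arc_length(spec) == pytest.approx(poly, rel=1e-5)


class TestGeneratePhantom:
    def test_straight_ground_truth(self):
        spec = PhantomSpec("straight", [(10, 10), (10, 40)],
                           image_shape_px=(256, 256), pixel_spacing_mm=0.2)
        _, _, truth = generate_phantom(spec)
        assert truth.chord_mm == pytest.approx(30.0, abs=1e-9)
        assert truth.arc_mm == pytest.approx(30.0, abs=1e-6)

    def test_semicircle_ground_truth(self, semicircle_phantom):
        _, _, truth = semicircle_phantom
        assert truth.chord_mm == pytest.approx(30.0, abs=1e-6)
        assert truth.arc_mm == pytest.approx(15 * np.pi, rel=1e-9)

    def test_same_spec_same_seed_bit_identical(self):
        spec = PhantomSpec("bezier_quadratic", [(10, 8), (20, 22), (12, 40)],
                           image_shape_px=(128, 256), pixel_spacing_mm=0.2,
                           seed=11)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_centerline_exiting_view_is_rejected(self):
        with pytest.raises(CenterlineOutOfViewError, match="control point"):
            PhantomSpec("straight", [(0.5, 10), (10, 40)],
                        image_shape_px=(128, 256), pixel_spacing_mm=0.2)
        # arc bulging outside despite in-view control points
        spec = PhantomSpec(
            "circular_arc", [(6, 10), (3.2, 18), (6, 40)],
            image_shape_px=(64, 256), pixel_spacing_mm=0.2,
            gland_band_mm=3.0, canal_halfwidth_mm=0.5)
        with pytest.raises(CenterlineOutOfViewError, match="control point"):
            generate_phantom(spec)

    def test_arc_at_least_chord_and_mask_contains_centerline(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            spec = random_phantom_spec(rng)
            _, mask, truth = generate_phantom(spec)
            assert truth.arc_mm >= truth.chord_mm - 1e-9
            pts = centerline_point(spec, np.linspace(0, 1, 200))
            px = np.round(pts / spec.pixel_spacing_mm).astype(int)
            assert mask.pixels[px[:, 0], px[:, 1]].all()

    def test_straight_centerline_has_equal_arc_and_chord_only(self):
        rng = np.random.default_rng(3)
        spec = random_phantom_spec(rng, kinds=("circular_arc",))
        _, _, truth = generate_phantom(spec)
        assert truth.arc_mm > truth.chord_mm

    def test_horizontal_flip_preserves_lengths(self):
        """Mirroring the scene maps the centerline to a mirrored curve
        with identical chord/arc lengths."""
        spec = PhantomSpec("bezier_quadratic", [(10, 8), (20, 22), (12, 40)],
                           image_shape_px=(128, 256), pixel_spacing_mm=0.2)
        fc = (spec.image_shape_px[1] - 1) * spec.pixel_spacing_mm
        mirrored = PhantomSpec(
            "bezier_quadratic",
            [(r, fc - c) for r, c in spec.control_points],
            image_shape_px=spec.image_shape_px,
            pixel_spacing_mm=spec.pixel_spacing_mm)
        _, _, t1 = generate_phantom(spec)
        _, _, t2 = generate_phantom(mirrored)
        assert t2.chord_mm == pytest.approx(t1.chord_mm, abs=1e-9)
        assert t2.arc_mm == pytest.approx(t1.arc_mm, rel=1e-9)


class TestCohortGenerator:
    def test_ai_line_mean_matches_model(self):
        cohort = generate_cohort(100, 0, 0, seed=1)
        se = 9.2 / np.sqrt(100)
        assert abs(cohort.table["cl_ai_mm"].mean() - 43.3) < 3 * se

    def test_zero_sd_gives_constant_values(self):
        model = {m: {g: ((40.0, 0.0) if m == "cl_ai_mm" else (30.0, 0.0))
                     for g in ("term", "sptb_32_36", "sptb_lt32")}
                 for m in ("cl_single_mm", "cl_two_mm", "cl_ai_mm")}
        cohort = generate_cohort(0, 0, 5, effect_model=model, seed=0)
        assert (cohort.table["cl_ai_mm"] == 40.0).all()
        assert (cohort.table["cl_single_mm"] == 30.0).all()

    def test_same_seed_identical_tables(self):
        a = generate_cohort(50, 5, 2, seed=9)
        b = generate_cohort(50, 5, 2, seed=9)
        assert a.table.equals(b.table)

    def test_all_groups_empty_is_an_error(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 0, 0)

    def test_arc_never_below_chords(self):
        t = generate_cohort(2000, 200, 40, seed=4).table
        assert (t["cl_ai_mm"] >= t["cl_single_mm"] - 1e-9).all()
        assert (t["cl_ai_mm"] >= t["cl_two_mm"] - 1e-9).all()

    @pytest.mark.parametrize("group,n_args", [
        ("term", (10000, 0, 0)),
        ("sptb_32_36", (0, 10000, 0)),
        ("sptb_lt32", (0, 0, 10000)),
    ])
    def test_moments_converge_to_model(self, group, n_args):
        table = generate_cohort(*n_args, seed=2).group(group)
        for col in ("cl_single_mm", "cl_two_mm", "cl_ai_mm"):
            mean, sd = DEFAULT_EFFECT_MODEL[col][group]
            assert table[col].mean() == pytest.approx(mean, rel=0.02)
            assert table[col].std() == pytest.approx(sd, rel=0.02)
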