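import math

import numpy as np
import pytest

from plastiscan import (
    CLASS_IDS,
    SUBSTRATE,
    DistortionRanges,
    DistortionSpec,
    EllipseShape,
    FiberShape,
    PeakSpec,
    PlantedParticle,
    PolymerTemplate,
    SceneSpec,
    builtin_templates,
    class_index,
    default_axis,
    make_reference_library,
    random_scene_spec,
    synth_scene,
    synth_spectrum,
)

NO_DISTORTION = DistortionSpec()
PE = next(t for t in builtin_templates() if t.class_id == "PE")


class TestSpectrum:
    def test_zero_thickness_zero_distortion_is_flat(self, axis):
        s = synth_spectrum(PE, 0.0, NO_DISTORTION, axis, seed=0)
        np.testing.assert_array_equal(s, 0.0)

    def test_beer_lambert_linearity_without_saturation(self, axis):
        """Doubling thickness doubles absorbance when no ceiling applies."""
        tpl = PolymerTemplate("PE", (PeakSpec(2915, 14, 0.8),), baseline_level=0.0)
        a1 = synth_spectrum(tpl, 0.7, NO_DISTORTION, axis, seed=0)
        a2 = synth_spectrum(tpl, 1.4, NO_DISTORTION, axis, seed=0)
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_total_absorption_flattens_peak_ratio(self, axis):
        """At large thickness every band saturates toward the ceiling and the
        height ratio of two bands of different strength approaches 1."""
        tpl = PolymerTemplate(
            "PE", (PeakSpec(2915, 14, 0.8), PeakSpec(1472, 10, 0.3))
        )
        dist = DistortionSpec(ta_ceiling=1.5)
        thin = synth_spectrum(tpl, 1.0, dist, axis, seed=0)
        thick = synth_spectrum(tpl, 200.0, dist, axis, seed=0)
        i1 = int(np.argmin(np.abs(axis.values - 2915)))
        i2 = int(np.argmin(np.abs(axis.values - 1472)))
        assert thin[i1] / thin[i2] > 1.5          # distinct bands when thin
        assert thick[i1] / thick[i2] == pytest.approx(1.0, abs=1e-3)
        assert thick.max() == pytest.approx(1.5, abs=1e-3)
        # closed form at the grid band nearest the peak: c*(1-exp(-A_ideal/c))
        v = axis.values[i1]
        a_ideal = (0.8 * 14**2 / ((v - 2915) ** 2 + 14**2)
                   + 0.3 * 10**2 / ((v - 1472) ** 2 + 10**2))
        assert thin[i1] == pytest.approx(1.5 * -math.expm1(-a_ideal / 1.5), rel=1e-9)

    def test_saturation_monotone_and_bounded_in_thickness(self, axis):
        dist = DistortionSpec(ta_ceiling=2.0, mie_amplitude=0.05,
                              baseline_slope=1e-5)
        prev = None
        bound = 2.0 + 0.05 + 1e-5 * (axis.hi - axis.lo)
        for thickness in [0.0, 0.5, 1.0, 2.0, 5.0, 50.0]:
            s = synth_spectrum(PE, thickness, dist, axis, seed=0)
            if prev is not None:
                assert np.all(s >= prev - 1e-12)
            assert np.all(s <= bound + 1e-9)
            prev = s

    def test_mie_term_is_additive_sinusoid(self, axis):
        dist = DistortionSpec(mie_amplitude=0.1, mie_period=800.0, mie_phase=0.3)
        s = synth_spectrum(PE, 0.0, dist, axis, seed=0)
        expected = 0.1 * np.sin(2 * np.pi * axis.values / 800.0 + 0.3)
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_deterministic_given_seed(self, axis):
        dist = DistortionSpec(noise_sigma=0.01)
        a = synth_spectrum(PE, 1.0, dist, axis, seed=5)
        b = synth_spectrum(PE, 1.0, dist, axis, seed=5)
        np.testing.assert_array_equal(a, b)
        c = synth_spectrum(PE, 1.0, dist, axis, seed=6)
        assert not np.array_equal(a, c)

    def test_empty_axis_rejected(self):
        from plastiscan import WavenumberAxis
        with pytest.raises(ValueError):
            WavenumberAxis(np.array([]))
        with pytest.raises(ValueError):
            synth_spectrum(PE, -1.0, NO_DISTORTION, default_axis(), seed=0)


class TestTemplates:
    def test_all_22_classes_covered_in_table_order(self):
        assert tuple(t.class_id for t in builtin_templates()) == CLASS_IDS

    def test_polymer_templates_have_2_to_6_distinct_peaks(self):
        for t in builtin_templates():
            if t.class_id == "Other":
                continue
            assert 2 <= len(t.peaks) <= 6
            centers = [p.center for p in t.peaks]
            assert len(set(centers)) == len(centers)
            axis = default_axis()
            assert all(axis.lo <= c <= axis.hi for c in centers)


class TestScene:
    def test_empty_scene_is_all_substrate(self):
        img, truth = synth_scene(SceneSpec(rows=8, cols=8, seed=1))
        assert np.all(truth.label_map == SUBSTRATE)
        assert truth.particles == []
        assert img.shape == (8, 8, 587)

    def test_planted_fiber_rasterizes_to_stated_pixels(self):
        fiber = FiberShape(center=(4.0, 4.0), length=5.0, angle_deg=0.0)
        spec = SceneSpec(rows=9, cols=9, seed=2,
                         particles=(PlantedParticle(PE, fiber),))
        img, truth = synth_scene(spec)
        assert len(truth.particles) == 1
        p = truth.particles[0]
        assert p["class_id"] == "PE"
        assert len(p["pixels"]) == 5
        np.testing.assert_array_equal(np.unique(p["pixels"][:, 0]), [4])
        np.testing.assert_array_equal(np.sort(p["pixels"][:, 1]), [2, 3, 4, 5, 6])

    def test_same_seed_identical_cube(self):
        spec = random_scene_spec(5, rows=64, cols=64, seed=9)
        img1, _ = synth_scene(spec)
        img2, _ = synth_scene(spec)
        np.testing.assert_array_equal(img1.cube, img2.cube)

    def test_overlap_later_wins(self):
        sq1 = EllipseShape((4.0, 4.0), (2.0, 2.0))
        sq2 = EllipseShape((4.0, 6.0), (2.0, 2.0))
        pp = next(t for t in builtin_templates() if t.class_id == "PP")
        spec = SceneSpec(rows=12, cols=12, seed=3, particles=(
            PlantedParticle(PE, sq1), PlantedParticle(pp, sq2)))
        _, truth = synth_scene(spec)
        overlap = set(map(tuple, sq1.rasterize(12, 12))) & set(
            map(tuple, sq2.rasterize(12, 12)))
        assert overlap
        for r, c in overlap:
            assert truth.label_map[r, c] == class_index("PP")
        sets = [set(map(tuple, p["pixels"])) for p in truth.particles]
        assert not (sets[0] & sets[1])

    def test_every_nonsubstrate_pixel_owned_once(self):
        spec = random_scene_spec(6, rows=96, cols=96, seed=4, matrix_fraction=0.3)
        _, truth = synth_scene(spec)
        owned = set()
        for p in truth.particles:
            for px in map(tuple, p["pixels"]):
                assert px not in owned
                owned.add(px)
        for px in map(tuple, truth.matrix_pixels):
            assert px not in owned
            owned.add(px)
        fg = {tuple(px) for px in np.argwhere(truth.label_map != SUBSTRATE)}
        assert owned == fg

    def test_random_scene_particles_are_edge_connected(self):
        from _oracles import flood_fill_components
        spec = random_scene_spec(10, rows=128, cols=128, seed=5)
        _, truth = synth_scene(spec)
        assert len(truth.particles) == 10
        comps = flood_fill_components(truth.label_map)
        assert len(comps) == 10


class TestReferenceLibrary:
    def test_balanced_count(self):
        X, y = make_reference_library(n_per_class=10, seed=0)
        assert X.shape == (220, 587)
        assert all(np.sum(y == c) == 10 for c in range(22))

    def test_half_other_balance_rule(self):
        X, y = make_reference_library(seed=0, mimic_paper_balance=True, total=400)
        assert len(y) == 400
        assert np.sum(y == class_index("Other")) == 200

    def test_same_seed_identical(self):
        X1, y1 = make_reference_library(n_per_class=5, seed=3)
        X2, y2 = make_reference_library(n_per_class=5, seed=3)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_distortion_ranges_draw_within_bounds(self):
        rng = np.random.default_rng(0)
        ranges = DistortionRanges()
        for _ in range(50):
            d = ranges.draw(rng)
            assert ranges.mie_amplitude[0] <= d.mie_amplitude <= ranges.mie_amplitude[1]
            assert ranges.ta_ceiling[0] <= d.ta_ceiling <= ranges.ta_ceiling[1]
            assert d.noise_sigma == ranges.noise_sigma
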