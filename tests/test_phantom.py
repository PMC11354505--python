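import math

import numpy as np
import pytest
from scipy import integrate

from octvol.agreement import bland_altman
from octvol.annotation_io import Contour
from octvol.geometry import polygon_area
from octvol.phantom import (
    ObserverModel,
    PhantomSpec,
    analytic_cross_section,
    analytic_volume,
    quadrature_volume,
    render_stack,
    simulate_observers,
)
from octvol.volumetry import entity_volume, foveal_volume

SHAPES = [
    ("ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.3}),
    ("slab_cylinder", {"r": 0.5, "t": 0.3}),
    ("paraboloid_pit", {"a": 0.45, "h": 0.25}),
    ("lens", {"R": 0.5, "h": 0.2}),
]


class TestAnalyticVolume:
    def test_sphere(self):
        spec = PhantomSpec("ellipsoid", {"a": 0.5, "b": 0.5, "c": 0.5})
        assert analytic_volume(spec) == pytest.approx(0.523599, abs=1e-6)

    def test_cylinder(self):
        spec = PhantomSpec("slab_cylinder", {"r": 0.5, "t": 0.3})
        assert analytic_volume(spec) == pytest.approx(0.235619, abs=1e-6)

    def test_lens_cap_formula(self):
        # 2 * (pi h^2 (3R - h) / 3) for h = 0.2, R = 0.5, cross-checked by
        # 1-D quadrature of the cap profile: V = 2 * int_0^h pi (2Rz - z^2) dz
        # with z measured from the cap's flat base... computed below directly
        # as the solid of revolution of the lens half-thickness profile.
        spec = PhantomSpec("lens", {"R": 0.5, "h": 0.2})
        assert analytic_volume(spec) == pytest.approx(0.108909, abs=1e-6)
        cap, _ = integrate.quad(lambda z: math.pi * (0.5**2 - (0.5 - 0.2 + z) ** 2), 0.0, 0.2)
        assert analytic_volume(spec) == pytest.approx(2 * cap, rel=1e-12)

    def test_paraboloid(self):
        spec = PhantomSpec("paraboloid_pit", {"a": 0.45, "h": 0.25})
        assert analytic_volume(spec) == pytest.approx(math.pi * 0.45**2 * 0.25 / 2, rel=1e-12)

    @pytest.mark.parametrize("shape,params", SHAPES)
    def test_quadrature_self_check(self, shape, params):
        # integral of analytic_cross_section over y equals analytic_volume
        spec = PhantomSpec(shape, params)
        assert abs(quadrature_volume(spec) - analytic_volume(spec)) < 1e-6


class TestAnalyticCrossSection:
    def test_ellipsoid_equator(self):
        spec = PhantomSpec("ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.3})
        assert analytic_cross_section(spec, spec.center_y) == pytest.approx(
            math.pi * 0.4 * 0.3, rel=1e-12
        )

    @pytest.mark.parametrize("shape,params", SHAPES)
    def test_zero_outside_footprint(self, shape, params):
        spec = PhantomSpec(shape, params)
        ext = spec.footprint_halfwidth
        # exactly at the rim the section vanishes (up to float rounding of ext)
        assert analytic_cross_section(spec, spec.center_y + ext) == pytest.approx(0.0, abs=1e-15)
        assert analytic_cross_section(spec, spec.center_y + ext + 1e-9) == 0.0
        assert analytic_cross_section(spec, spec.center_y + ext + 1.0) == 0.0

    def test_lens_equator_closed_form(self):
        spec = PhantomSpec("lens", {"R": 0.5, "h": 0.2})
        # numeric oracle: area = 2 * int of (sqrt(R^2 - x^2) - (R - h)) over the rim
        w = math.sqrt(0.2 * (2 * 0.5 - 0.2))
        oracle, _ = integrate.quad(
            lambda x: 2 * (math.sqrt(0.25 - x * x) - 0.3), -w, w
        )
        assert analytic_cross_section(spec, spec.center_y) == pytest.approx(oracle, rel=1e-10)


class TestRenderStack:
    def test_inscribed_square_area(self):
        # 4-vertex polygon on a circular section: inscribed square, area 2 r^2
        spec = PhantomSpec(
            "ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.4}, vertices_per_contour=4
        )
        stack = render_stack(spec)
        mid = spec.n_scans // 2
        contour = stack.scans[mid].contours[0]
        assert polygon_area(contour) == pytest.approx(2 * 0.4**2, rel=1e-12)

    def test_vertex_convergence_quadratic(self):
        # area error of the inscribed polygon ~ 1 / vertices^2
        spec0 = PhantomSpec("ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.3})
        target = analytic_cross_section(spec0, spec0.center_y)
        counts = [8, 16, 32, 64, 128, 256]
        errors = []
        for m in counts:
            spec = PhantomSpec(
                "ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.3}, vertices_per_contour=m
            )
            stack = render_stack(spec)
            mid = spec.n_scans // 2
            errors.append(abs(polygon_area(stack.scans[mid].contours[0]) - target))
        slope = np.polyfit(np.log(counts), np.log(errors), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    @pytest.mark.parametrize("shape,params", SHAPES)
    def test_rendered_sections_inscribed(self, shape, params):
        # Inscribed polygons never exceed the analytic section area, and get
        # close at high vertex counts.  (slab_cylinder renders the full slab;
        # compare its clipped measurement instead.)
        spec = PhantomSpec(shape, params, vertices_per_contour=512, scan_spacing=0.06, n_scans=49)
        stack = render_stack(spec)
        if shape == "slab_cylinder":
            result = foveal_volume(stack, "entity", roi=spec.roi())
            per_scan = dict(result.per_scan)
            for scan in stack.scans:
                if scan.scan_index in per_scan:
                    expected = analytic_cross_section(spec, scan.lateral_offset_y)
                    assert per_scan[scan.scan_index] == pytest.approx(expected, rel=1e-9)
            return
        for scan in stack.scans:
            for contour in scan.contours:
                area = polygon_area(contour)
                expected = analytic_cross_section(spec, scan.lateral_offset_y)
                assert area <= expected + 1e-12
                assert area == pytest.approx(expected, rel=2e-3)

    def test_shape_missing_every_scan(self):
        # 1-scan raster placed right on the shape's centre has a contour;
        # shift the centre off the raster footprint and nothing renders.
        spec = PhantomSpec(
            "ellipsoid",
            {"a": 0.1, "b": 0.04, "c": 0.1},
            center=(0.0, 0.05),
            scan_spacing=0.12,
            n_scans=2,
        )
        stack = render_stack(spec)
        # footprint [0.01, 0.09] contains no raster line (y = 0 or 0.12)
        assert sum(len(s.contours) for s in stack.scans) == 0

    def test_every_scan_listed(self):
        spec = PhantomSpec("ellipsoid", {"a": 0.4, "b": 0.5, "c": 0.3})
        stack = render_stack(spec)
        assert [s.scan_index for s in stack.scans] == list(range(spec.n_scans))

    def test_fovea_on_nearest_scan(self):
        spec = PhantomSpec("slab_cylinder", {"r": 0.5, "t": 0.3})
        stack = render_stack(spec)
        assert stack.fovea_center.scan_index == (spec.n_scans - 1) // 2

    def test_footprint_outside_raster_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("ellipsoid", {"a": 0.5, "b": 3.0, "c": 0.5})

    def test_end_to_end_volume_within_discretization_bound(self):
        spec = PhantomSpec(
            "ellipsoid", {"a": 0.5, "b": 0.5, "c": 0.5}, vertices_per_contour=512
        )
        stack = render_stack(spec)
        v = entity_volume(stack, "entity").total_volume
        assert v == pytest.approx(analytic_volume(spec), rel=5e-3)


class TestSimulateObservers:
    def _spec(self):
        return PhantomSpec("ellipsoid", {"a": 0.5, "b": 0.5, "c": 0.5})

    def test_noise_free_observers_agree_exactly(self):
        quiet = ObserverModel()
        study = simulate_observers(self._spec(), quiet, quiet, n_subjects=4, seed=1)
        pairs = study.comparisons["obs1-obs2"]
        np.testing.assert_array_equal(pairs.values_a, pairs.values_b)
        intra = study.comparisons["obs1_s1-obs1_s2"]
        np.testing.assert_array_equal(intra.values_a, intra.values_b)

    def test_pure_bias_propagates_to_volumes(self):
        biased = ObserverModel(area_bias=0.01)
        quiet = ObserverModel()
        study = simulate_observers(self._spec(), biased, quiet, n_subjects=4, seed=1)
        pairs = study.comparisons["obs1-obs2"]
        diffs = pairs.values_a - pairs.values_b
        np.testing.assert_allclose(diffs, 0.01 * study.true_volumes, rtol=1e-9)
        truth = study.comparisons["truth-obs2"]
        np.testing.assert_allclose(truth.values_a, study.true_volumes, rtol=0)

    def test_seed_reproducible_bit_identical(self):
        o1 = ObserverModel(area_noise_sd=0.02, seed=1)
        o2 = ObserverModel(area_noise_sd=0.02, seed=2)
        s1 = simulate_observers(self._spec(), o1, o2, n_subjects=5, subject_size_jitter=0.01, seed=42)
        s2 = simulate_observers(self._spec(), o1, o2, n_subjects=5, subject_size_jitter=0.01, seed=42)
        for key in s1.comparisons:
            assert s1.comparisons[key].pairs == s2.comparisons[key].pairs
        s3 = simulate_observers(self._spec(), o1, o2, n_subjects=5, subject_size_jitter=0.01, seed=43)
        assert s1.comparisons["obs1-obs2"].pairs != s3.comparisons["obs1-obs2"].pairs

    def test_jitter_scales_true_volumes(self):
        o = ObserverModel()
        study = simulate_observers(self._spec(), o, o, n_subjects=6, subject_size_jitter=0.05, seed=9)
        base = simulate_observers(self._spec(), o, o, n_subjects=3, seed=9).true_volumes[0]
        # volumes scale ~ factor^3 (up to raster discretization)
        ratio = study.true_volumes / base
        assert np.all(ratio > 0)
        np.testing.assert_allclose(ratio, study.size_factors**3, rtol=0.02)

    def test_parameter_recovery_small(self):
        # 60 replicates at modest n: mean estimated bias centred on the
        # analytic expectation 0.01 * V_true.
        spec = self._spec()
        o1 = ObserverModel(area_bias=0.01, area_noise_sd=0.02, seed=1)
        o2 = ObserverModel(area_bias=0.0, area_noise_sd=0.02, seed=2)
        biases = []
        for rep in range(60):
            study = simulate_observers(spec, o1, o2, n_subjects=30, sessions=1, seed=500 + rep)
            biases.append(bland_altman(study.comparisons["obs1-obs2"]).bias)
        expected = 0.01 * simulate_observers(spec, o1, o2, 3, sessions=1, seed=0).true_volumes[0]
        se = np.std(biases, ddof=1) / math.sqrt(len(biases))
        assert abs(np.mean(biases) - expected) < 4 * se

    def test_min_subjects(self):
        with pytest.raises(ValueError):
            simulate_observers(self._spec(), ObserverModel(), ObserverModel(), n_subjects=2)

    def test_invalid_spec_params(self):
        with pytest.raises(ValueError):
            PhantomSpec("cube", {"a": 1.0})
        with pytest.raises(ValueError):
            PhantomSpec("ellipsoid", {"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError):
            PhantomSpec("ellipsoid", {"a": -1.0, "b": 0.2, "c": 0.2})
        with pytest.raises(ValueError):
            PhantomSpec("lens", {"R": 0.2, "h": 0.3})
        with pytest.raises(ValueError):
            ObserverModel(area_noise_sd=-0.1)
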