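"""RMS spot, Seidel sums, geometric MTF, improvement rate, design evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from iolens.eye_model import ConicSurface, EyePrescription, builtin_prescription
from iolens.metrics import (
    SpotDiagram,
    evaluate_design,
    geometric_mtf,
    improvement_rate,
    improvement_report,
    rms_spot,
    seidel_aberrations,
    trace_spot,
)
from iolens.trace_engine import GridSpec, Ray, paraxial_trace, trace_ray


def spot_of(points, ref=(0.0, 0.0), mode="centroid"):
    return SpotDiagram(np.asarray(points, dtype=float), ref, mode, 6.0, 0.0)


class TestRmsSpot:
    def test_single_point_at_reference_is_zero(self):
        assert rms_spot(spot_of([[0.0, 0.0]])) == 0.0

    def test_unit_circle_points(self):
        pts = [[1, 0], [-1, 0], [0, 1], [0, -1]]
        assert rms_spot(spot_of(pts)) == pytest.approx(1.0, abs=1e-15)

    def test_matches_loop_summation_oracle(self, rng):
        pts = rng.normal(0.0, 0.3, size=(1000, 2))
        ref = (0.123, -0.456)
        acc = 0.0
        for x, y in pts:  # independent brute-force accumulation
            acc += (x - ref[0]) ** 2 + (y - ref[1]) ** 2
        assert rms_spot(spot_of(pts, ref)) == pytest.approx(math.sqrt(acc / 1000), abs=1e-12)

    @given(arrays(float, (25, 2), elements=st.floats(-1, 1)),
           st.floats(0.1, 10), st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_centroid_reference_translation_and_scale(self, pts, s, dx, dy):
        def centroid_rms(q):
            c = q.mean(axis=0)
            return rms_spot(spot_of(q, (float(c[0]), float(c[1]))))

        base = centroid_rms(pts)
        shifted = centroid_rms(pts + [dx, dy])
        scaled = centroid_rms(pts * s)
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(s * base, rel=1e-9, abs=1e-12)


class TestSeidel:
    def test_all_plane_system_has_zero_sums(self):
        # collimated input: refracting planes leave the beam collimated and
        # aberration-free (at finite conjugates a plane interface does
        # aberrate, which is why the object sits at infinity here)
        surfaces = (
            ConicSurface(0.0, 0.0, 5.0, "glass", 1.5, 10.0, is_stop=True, label="a"),
            ConicSurface(0.0, 0.0, 5.0, "humor", 1.336, 10.0, label="b"),
            ConicSurface(0.0, 0.0, 0.0, "humor", 1.336, 10.0, label="img"),
        )
        p = EyePrescription("planes", surfaces, math.inf, 2.0)
        sd = seidel_aberrations(p, paraxial_trace(p, allow_afocal=True), field_deg=3.0)
        assert np.allclose(sd.totals, 0.0, atol=1e-15)

    @pytest.mark.parametrize("c1,c2", [(0.05, -0.05), (0.08, -0.02), (0.0, -0.06)])
    def test_thin_lens_matches_coddington_closed_form(self, c1, c2):
        # textbook thin-lens spherical aberration, stop at lens, object at
        # infinity (conjugate variable 1), in air
        n = 1.5
        surfaces = (
            ConicSurface(c1, 0.0, 0.0, "glass", n, 20.0, is_stop=True, label="a"),
            ConicSurface(c2, 0.0, 30.0, "air", 1.0, 20.0, label="b"),
            ConicSurface(0.0, 0.0, 0.0, "air", 1.0, 100.0, label="img"),
        )
        p = EyePrescription("thin", surfaces, math.inf, 4.0)
        par = paraxial_trace(p)
        sd = seidel_aberrations(p, par, field_deg=0.0)
        y = par.y_marginal[0]
        phi = (n - 1.0) * (c1 - c2)
        B = (c1 + c2) / (c1 - c2)
        C = 1.0
        closed = (y ** 4 * phi ** 3 / 4.0) * (
            (n / (n - 1.0)) ** 2
            + (n + 2.0) / (n * (n - 1.0) ** 2) * B ** 2
            - 4.0 * (n + 1.0) / (n * (n - 1.0)) * B * C
            + (3.0 * n + 2.0) / n * C ** 2
        )
        assert sd.totals[0] == pytest.approx(closed, rel=1e-9)

    def test_aplanatic_surface_has_zero_sa_and_coma(self):
        # sphere with (virtual) object at its aplanatic conjugate:
        # distance -(n1+n2)/(c n1) from the vertex
        n1, n2, c = 1.0, 1.5, 0.05
        surfaces = (
            ConicSurface(c, 0.0, 30.0, "glass", n2, 20.0, is_stop=True, label="a"),
            ConicSurface(0.0, 0.0, 0.0, "glass", n2, 100.0, label="img"),
        )
        p = EyePrescription("aplanat", surfaces, -(n1 + n2) / (c * n1), 2.0)
        sd = seidel_aberrations(p, field_deg=2.0)
        assert abs(sd.totals[0]) < 1e-9
        assert abs(sd.totals[1]) < 1e-9

    def test_cartesian_ellipsoid_cancels_spherical(self):
        # collimated input refracted stigmatically by the conic with
        # K = -(n1/n2)^2: conic term must cancel the sphere term exactly
        n2 = 1.5
        c = 0.05
        K = -1.0 / n2 ** 2
        surfaces = (
            ConicSurface(c, K, 40.0, "glass", n2, 8.0, is_stop=True, label="a"),
            ConicSurface(0.0, 0.0, 0.0, "glass", n2, 50.0, label="img"),
        )
        p = EyePrescription("cartesian", surfaces, math.inf, 10.0)
        sd = seidel_aberrations(p, field_deg=0.0)
        assert abs(sd.totals[0]) < 1e-12
        # the same surface really is stigmatic: real rays at any height focus
        # to the axial point
        par = paraxial_trace(p)
        q = EyePrescription("cartesian", (
            ConicSurface(c, K, par.image_distance, "glass", n2, 8.0, is_stop=True, label="a"),
            ConicSurface(0.0, 0.0, 0.0, "glass", n2, 50.0, label="img"),
        ), math.inf, 10.0)
        for h in (1.0, 3.0, 5.0):
            res = trace_ray(q, Ray.parallel(0.0, h))
            assert res.image_point[1] == pytest.approx(0.0, abs=1e-10)

    def test_totals_equal_per_surface_sums(self, builtin_eye):
        sd = seidel_aberrations(builtin_eye, field_deg=5.0)
        assert np.allclose(sd.totals, sd.per_surface.sum(axis=0), atol=1e-15)
        assert sd.sa == sd.totals[0]
        assert sd.tco == pytest.approx(3.0 * sd.totals[1])

    def test_index_matched_plane_changes_nothing(self, ga_6mm):
        sd0 = seidel_aberrations(ga_6mm, field_deg=5.0)
        surfaces = list(ga_6mm.surfaces)
        s6 = surfaces[5]
        surfaces[5] = ConicSurface(s6.curvature, s6.conic, 6.0, "humor", 1.336,
                                   s6.semi_aperture, label="#6")
        surfaces.insert(6, ConicSurface(0.0, 0.0, s6.thickness - 6.0, "humor", 1.336,
                                        7.0, label="dummy"))
        q = EyePrescription("aug", tuple(surfaces), math.inf, 6.0)
        sd1 = seidel_aberrations(q, field_deg=5.0)
        assert np.allclose(sd1.totals, sd0.totals, atol=1e-12)


class TestGeometricMtf:
    def test_coincident_points_give_unit_modulation(self):
        pts = np.tile([[0.2, -0.1]], (50, 1))
        curve = geometric_mtf(spot_of(pts), [0.0, 10.0, 50.0, 200.0])
        assert np.allclose(curve.modulation, 1.0, atol=1e-12)

    def test_zero_frequency_is_unity_and_range_bounded(self, rng):
        pts = rng.normal(0, 0.05, size=(500, 2))
        f = np.linspace(0, 100, 41)
        curve = geometric_mtf(spot_of(pts), f)
        assert curve.modulation[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all((curve.modulation >= 0.0) & (curve.modulation <= 1.0))

    def test_gaussian_spot_matches_characteristic_function(self, rng):
        # frequencies kept where the closed-form modulation stays >= 0.45:
        # at n = 1e5 the Monte-Carlo scatter of |mean exp(-2pi i f u)| is
        # ~2e-3 absolute, so only there is a 1% relative check statistically
        # fair for any seed
        sigma = 0.01
        pts = np.column_stack([np.zeros(100_000), rng.normal(0, sigma, 100_000)])
        f = np.array([5.0, 10.0, 15.0, 20.0])
        m = geometric_mtf(spot_of(pts), f, orientation="tangential").modulation
        pred = np.exp(-2.0 * math.pi ** 2 * sigma ** 2 * f ** 2)
        assert np.max(np.abs(m - pred) / pred) < 0.01

    def test_translation_invariance(self, rng):
        pts = rng.normal(0, 0.02, size=(300, 2))
        f = [10.0, 25.0]
        a = geometric_mtf(spot_of(pts), f).modulation
        b = geometric_mtf(spot_of(pts + [3.0, -2.0]), f).modulation
        assert np.allclose(a, b, atol=1e-12)

    def test_doubling_spot_halves_half_contrast_frequency(self, rng):
        pts = rng.normal(0, 0.02, size=(20_000, 2))
        f = np.linspace(0.0, 60.0, 1201)

        def f_half(points):
            m = geometric_mtf(spot_of(points), f).modulation
            return f[np.argmax(m < 0.5)]

        assert f_half(pts * 2.0) == pytest.approx(f_half(pts) / 2.0, rel=0.02)

    def test_orientations_separate_axes(self):
        pts = np.column_stack([np.linspace(-0.1, 0.1, 41), np.zeros(41)])
        sag = geometric_mtf(spot_of(pts), [20.0], orientation="sagittal").modulation[0]
        tan = geometric_mtf(spot_of(pts), [20.0], orientation="tangential").modulation[0]
        assert tan == pytest.approx(1.0, abs=1e-12)
        assert sag < 0.9


class TestImprovementRate:
    def test_equal_values_give_zero(self):
        assert improvement_rate(0.5, 0.5, "aberration") == 0.0
        assert improvement_rate(0.5, 0.5, "resolution") == 0.0

    def test_aberration_mode_published_sa_row(self):
        assert improvement_rate(0.014618, 0.01, "aberration") == pytest.approx(-46.18, abs=0.005)

    def test_resolution_mode_published_mtf_row(self):
        assert improvement_rate(0.901, 0.768, "resolution") == pytest.approx(14.76, abs=0.005)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ZeroDivisionError):
            improvement_rate(1.0, 0.0, "aberration")
        with pytest.raises(ZeroDivisionError):
            improvement_rate(0.0, 1.0, "resolution")

    def test_report_carries_absolute_difference(self):
        rep = improvement_report("SA", 0.014618, 0.01, "aberration")
        assert rep.difference == pytest.approx(0.004618, abs=1e-12)
        assert rep.percent == pytest.approx(-46.18, abs=0.005)


class TestEvaluateDesign:
    def test_repeated_evaluation_is_bit_identical(self, ga_6mm):
        a = evaluate_design(ga_6mm)
        b = evaluate_design(ga_6mm)
        assert a["SA"] == b["SA"] and a["TCO"] == b["TCO"] and a["RMS"] == b["RMS"]
        assert a["MTF"] == b["MTF"]

    def test_reports_expected_metrics(self, codev_6mm):
        r = evaluate_design(codev_6mm, frequencies=(10.0, 20.0, 30.0))
        assert set(r["MTF"]) == {10.0, 20.0, 30.0}
        assert r["RMS"] > 0.0
        assert math.isfinite(r["SA"]) and math.isfinite(r["TCO"])
        assert r["n_rays"] == 331

    def test_ga_design_beats_builtin_rms_at_6mm(self, ga_6mm, codev_6mm):
        assert evaluate_design(ga_6mm)["RMS"] < evaluate_design(codev_6mm)["RMS"]

    def test_chief_reference_spot_available(self, ga_6mm):
        spot = trace_spot(ga_6mm, GridSpec("hexapolar", 4), reference="chief")
        assert spot.reference_mode == "chief"
        assert rms_spot(spot) >= 0.0
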