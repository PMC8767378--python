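"""Geometric primitives, ruler calibration, and subject measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasoform.anthropometry import (MeasurementDef, angle_at_vertex,
                                    calibrate_scale, euclidean_distance,
                                    frontal_symmetry_ratios, measure_subject,
                                    metric_inner_product)
from nasoform.errors import CalibrationError, GeometryError, MeasurementError
from nasoform.landmarks import CalibrationInfo, LandmarkSet

finite = st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False)


class TestDistanceAndInnerProduct:
    @pytest.mark.parametrize("p,q,expect", [
        ((0, 0), (0, 0), 0.0),
        ((0, 0), (3, 4), 5.0),
        ((1, 1), (1, 1), 0.0),
    ])
    def test_known_distances(self, p, q, expect):
        assert euclidean_distance(p, q) == pytest.approx(expect)

    @given(st.tuples(finite, finite), st.tuples(finite, finite))
    @settings(max_examples=200, derandomize=True)
    def test_distance_matches_scalar_oracle_and_symmetry(self, p, q):
        ref = math.sqrt(sum((float(a) - float(b)) ** 2 for a, b in zip(p, q)))
        assert euclidean_distance(p, q) == pytest.approx(ref, abs=1e-9)
        assert euclidean_distance(p, q) == euclidean_distance(q, p)

    @pytest.mark.parametrize("u,v,expect", [
        ((1, 0), (0, 1), 0.0),
        ((2, 0), (3, 0), 6.0),
    ])
    def test_inner_product_known(self, u, v, expect):
        assert metric_inner_product(u, v) == pytest.approx(expect)

    @given(st.tuples(finite, finite), st.tuples(finite, finite))
    @settings(max_examples=100, derandomize=True)
    def test_inner_product_componentwise_oracle(self, u, v):
        ref = sum(float(a) * float(b) for a, b in zip(u, v))
        assert metric_inner_product(u, v) == pytest.approx(ref, rel=1e-12, abs=1e-9)


class TestAngles:
    def test_right_angle(self):
        assert angle_at_vertex((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_collinear_is_180(self):
        assert angle_at_vertex((0, 0), (1, 0), (2, 0)) == pytest.approx(180.0)

    def test_coincident_points_raise(self):
        with pytest.raises(GeometryError):
            angle_at_vertex((1, 1), (1, 1), (0, 0))

    @given(st.lists(st.tuples(finite, finite), min_size=3, max_size=3, unique=True))
    @settings(max_examples=200, derandomize=True)
    def test_law_of_cosines_oracle(self, tri):
        a, b, c = tri
        ab = euclidean_distance(a, b)
        cb = euclidean_distance(c, b)
        ac = euclidean_distance(a, c)
        if ab < 1e-3 or cb < 1e-3:
            return
        cosv = max(-1.0, min(1.0, (ab ** 2 + cb ** 2 - ac ** 2) / (2 * ab * cb)))
        assert angle_at_vertex(a, b, c) == pytest.approx(
            math.degrees(math.acos(cosv)), abs=1e-5)

    @given(st.floats(0, 360), st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=100, derandomize=True)
    def test_similarity_invariance(self, rot_deg, shift, scale):
        a, b, c = np.array([1.0, 0.2]), np.array([0.0, 0.0]), np.array([0.3, 1.4])
        base = angle_at_vertex(a, b, c)
        t = math.radians(rot_deg)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        pts = [scale * (R @ p) + shift for p in (a, b, c)]
        assert angle_at_vertex(*pts) == pytest.approx(base, abs=1e-7)


class TestCalibration:
    def test_regular_ticks(self):
        ticks = [(x, 50.0) for x in (0.0, 5.0, 10.0, 15.0)]
        cal = calibrate_scale(ticks, tick_spacing_mm=1.0)
        assert cal.mm_per_px == pytest.approx(0.2)
        assert cal.source == "ruler_ticks"

    def test_jittered_ticks_within_2pct(self, rng):
        true_spacing = 7.0
        ticks = [(0.0, i * true_spacing + rng.uniform(-0.1, 0.1)) for i in range(10)]
        cal = calibrate_scale(ticks, tick_spacing_mm=2.0)
        assert cal.mm_per_px == pytest.approx(2.0 / true_spacing, rel=0.02)

    def test_too_few_ticks(self):
        with pytest.raises(CalibrationError):
            calibrate_scale([(0, 0), (5, 0)], 1.0)

    def test_non_collinear_rejected(self):
        ticks = [(0, 0), (5, 4), (10, -4), (15, 4)]
        with pytest.raises(CalibrationError):
            calibrate_scale(ticks, 1.0)


def _frontal_set(**overrides):
    pts = {
        "g": (112.0, 40.0), "sn": (112.0, 140.0), "n": (112.0, 60.0),
        "prn": (112.0, 120.0),
        "mf_R": (87.0, 80.0), "mf_L": (137.0, 80.0),
        "mal_R": (95.0, 125.0), "mal_L": (129.0, 125.0),
        "ac_R": (97.0, 135.0), "ac_L": (127.0, 135.0),
        "al_R": (92.0, 132.0), "al_L": (132.0, 132.0),
    }
    pts.update(overrides)
    return LandmarkSet(subject_id="t", view="frontal", points=pts)


class TestFrontalRatios:
    def test_symmetric_face(self):
        r = frontal_symmetry_ratios(_frontal_set())
        assert r["mid_alar_lr_ratio"] == pytest.approx(1.0)
        assert r["base_lr_ratio"] == pytest.approx(1.0)
        assert r["alar_lr_ratio"] == pytest.approx(1.0)
        assert r["axis_angle_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_height_width_ratio_arithmetic(self):
        r = frontal_symmetry_ratios(_frontal_set())
        assert r["height_width_ratio"] == pytest.approx(100.0 / 50.0)

    def test_shifted_alare_breaks_symmetry_in_predicted_direction(self):
        r = frontal_symmetry_ratios(_frontal_set(al_R=(82.0, 132.0)))
        # right half-width grew, so R/L ratio rises above 1
        assert r["alar_lr_ratio"] > 1.0

    def test_missing_code_raises(self):
        ls = _frontal_set()
        del ls.points["mf_R"]
        with pytest.raises(MeasurementError):
            frontal_symmetry_ratios(ls)


class TestMeasureSubject:
    def test_alar_width_scaling(self):
        d = MeasurementDef("al-al", "distance", ("al_R", "al_L"), "frontal", "mm")
        ls = LandmarkSet("s", "frontal",
                         {"al_R": (100.0, 200.0), "al_L": (160.0, 200.0)})
        cal = {"frontal": CalibrationInfo("frontal", 0.25)}
        t = measure_subject({"frontal": ls}, cal, [d])
        assert t.value("al-al") == pytest.approx(15.0)
        assert t.values["al-al"][1] == "mm"

    def test_missing_required_landmark_names_code_and_view(self):
        d = MeasurementDef("al-al", "distance", ("al_R", "al_L"), "frontal", "mm")
        ls = LandmarkSet("s", "frontal", {"al_R": (0.0, 0.0)})
        with pytest.raises(MeasurementError, match="al_L.*frontal"):
            measure_subject({"frontal": ls},
                            {"frontal": CalibrationInfo("frontal", 1.0)}, [d])

    def test_optional_kyphion_measurement_absent_not_error(self):
        defs = [
            MeasurementDef("n-k-r", "angle", ("n", "k", "r"), "lateral",
                           "degrees", optional=True),
            MeasurementDef("n-prn-sn", "angle", ("n", "prn", "sn"), "lateral",
                           "degrees"),
        ]
        ls = LandmarkSet("s", "lateral", {
            "n": (0.0, 0.0), "r": (10.0, 12.0), "prn": (20.0, 30.0),
            "sn": (12.0, 45.0)})
        t = measure_subject({"lateral": ls}, {}, defs)
        assert "n-k-r" not in t
        assert "n-prn-sn" in t

    def test_scale_equivariance(self):
        d = MeasurementDef("al-al", "distance", ("al_R", "al_L"), "frontal", "mm")
        base = LandmarkSet("s", "frontal",
                           {"al_R": (10.0, 20.0), "al_L": (46.0, 80.0)})
        k = 3.7
        scaled = LandmarkSet("s", "frontal",
                             {c: (x * k, y * k) for c, (x, y) in base.points.items()})
        t1 = measure_subject({"frontal": base},
                             {"frontal": CalibrationInfo("frontal", 0.5)}, [d])
        t2 = measure_subject({"frontal": scaled},
                             {"frontal": CalibrationInfo("frontal", 0.5 / k)}, [d])
        assert t1.value("al-al") == pytest.approx(t2.value("al-al"))

    def test_rotation_invariance_with_corotated_ruler(self, rng):
        ang = math.radians(23.0)
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        pts = {"al_R": np.array([40.0, 90.0]), "al_L": np.array([120.0, 95.0])}
        ticks = [np.array([5.0, 10.0 + 6.0 * i]) for i in range(6)]
        d = MeasurementDef("al-al", "distance", ("al_R", "al_L"), "frontal", "mm")

        def run(transform):
            ls = LandmarkSet("s", "frontal",
                             {c: tuple(transform(p)) for c, p in pts.items()})
            cal = calibrate_scale([transform(t) for t in ticks], 2.0)
            return measure_subject({"frontal": ls}, {"frontal": cal}, [d]).value("al-al")

        assert run(lambda p: p) == pytest.approx(run(lambda p: R @ p), abs=1e-9)


class TestRenderRoundTrip:
    """Ground-truth geometry recovered through the measurement pipeline."""

    EXACT = ("n-prn", "n-sn", "n-r", "n-gn", "al-al", "ac-ac", "en-en",
             "mf-mf", "mal-mal")

    def test_distances_within_quantization(self, rendered_subject):
        rec, views = rendered_subject
        sets = {v: rv.landmarks for v, rv in views.items()}
        cals = {v: rv.calibration for v, rv in views.items()}
        table = measure_subject(sets, cals, provenance="ground_truth")
        for code in self.EXACT:
            view = "frontal" if code in ("al-al", "ac-ac", "en-en", "mf-mf",
                                         "mal-mal") else "lateral"
            bound = 0.5 * cals[view].mm_per_px / 10.0   # cm
            assert abs(table.value(code) - rec.surface[code]) <= bound, code

    def test_nasofrontal_angle_round_trip(self, rendered_subject):
        from nasoform.anthropometry import measurement_def

        rec, views = rendered_subject
        table = measure_subject({"lateral": views["lateral"].landmarks},
                                {"lateral": views["lateral"].calibration},
                                [measurement_def("g-n-prn")])
        assert table.value("g-n-prn") == pytest.approx(
            rec.surface["g-n-prn"], abs=0.05)

    def test_cross_view_vertical_consistency(self, rendered_subject):
        """n->sn vertical separation agrees between frontal and lateral views."""
        _, views = rendered_subject
        up = (0.0, 1.0)
        sep = {}
        for v in ("frontal", "lateral"):
            ls = views[v].landmarks
            d = np.subtract(ls.points["sn"], ls.points["n"])
            sep[v] = metric_inner_product(d, up) * views[v].calibration.mm_per_px
        assert sep["frontal"] == pytest.approx(sep["lateral"], rel=0.01)

    def test_calibration_recovered_from_ruler_ticks(self, rendered_subject):
        _, views = rendered_subject
        for v, rv in views.items():
            cal = calibrate_scale(rv.ruler_ticks_px, rv.tick_spacing_mm, view=v)
            assert cal.mm_per_px == pytest.approx(rv.calibration.mm_per_px,
                                                  rel=1e-9)
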