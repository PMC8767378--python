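"""Kyphion detection, bone angles, V/S and A-E classification, and the BPNN."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasoform.errors import (ConfigurationError, DataError, FeatureError,
                             GeometryError)
from nasoform.morphology import (BoneAngles, BoneDims, BoneProfile, BpnnConfig,
                                 FrontalThresholds, bone_angles, build_bpnn,
                                 classify_frontal_type, classify_lateral_shape,
                                 classify_record, construct_bone_profile,
                                 detect_kyphion, predict_bone_morphology,
                                 train_bpnn)
from nasoform.synthetic import (PopulationParams, cadaver_fixture,
                                sample_population)


def _profile(hump_mm: float, frac: float = 0.5, mm_per_px: float = 1.0,
             n_interior: int = 5) -> BoneProfile:
    """Straight n-s-r-prn profile with a triangular dorsal bump of given height."""
    n = np.array([0.0, 0.0])
    s = np.array([4.0, 5.0])
    r = np.array([18.0, 16.0])
    prn = np.array([24.0, 24.0])
    chord = r - s
    ant = np.array([chord[1], -chord[0]])
    ant = ant / np.linalg.norm(ant)
    if ant[0] < 0:
        ant = -ant
    pts = [n, s]
    labels = ["n", "s"]
    for f in sorted(set(np.linspace(0.15, 0.9, n_interior)) | {frac}):
        h = hump_mm * (f / frac if f <= frac else (1 - f) / (1 - frac))
        pts.append(s + f * chord + h * ant)
        labels.append("k" if (hump_mm > 0 and abs(f - frac) < 1e-12) else "")
    pts.append(r)
    labels.append("r")
    pts.append(prn)
    labels.append("prn")
    return BoneProfile([(p[0] / mm_per_px, p[1] / mm_per_px) for p in pts],
                       labels, mm_per_px)


class TestDetectKyphion:
    def test_straight_profile_yields_none(self):
        assert detect_kyphion(_profile(0.0)) is None

    def test_bump_apex_found_with_height(self):
        found = detect_kyphion(_profile(1.0), tau_k_mm=0.5)
        assert found is not None
        point, dev = found
        assert dev == pytest.approx(1.0, abs=1e-9)

    def test_subthreshold_bump_not_detected(self):
        assert detect_kyphion(_profile(0.3), tau_k_mm=0.5) is None

    @given(st.floats(0.1, 3.0), st.floats(0.2, 0.8))
    @settings(max_examples=50, derandomize=True)
    def test_matches_brute_force_scan(self, hump, frac):
        prof = _profile(hump, frac=frac)
        s = np.asarray(prof.point("s"))
        r = np.asarray(prof.point("r"))
        chord = r - s
        u = chord / np.linalg.norm(chord)
        ant = np.array([u[1], -u[0]])
        if ant[0] < 0:
            ant = -ant
        i_s, i_r = prof.labels.index("s"), prof.labels.index("r")
        devs = [float(np.dot(np.asarray(p) - s, ant)) * prof.mm_per_px
                for p in prof.points[i_s + 1:i_r]]
        best = max(devs)
        found = detect_kyphion(prof, tau_k_mm=0.05)
        assert found is not None
        assert found[1] == pytest.approx(best, abs=1e-9)

    def test_monotone_in_bump_height(self):
        """Raising the hump never flips an S classification back to V."""
        prev_s = False
        for hump in np.linspace(0.1, 3.0, 25):
            prof = _profile(float(hump))
            found = detect_kyphion(prof, tau_k_mm=0.5)
            angles = bone_angles(prof, kyphion=found[0] if found else None)
            label = classify_lateral_shape(angles, found is not None, tau_a_deg=4.0)
            if prev_s:
                assert label == "S"
            prev_s = label == "S"


class TestBoneAngles:
    def test_collinear_kyphion_gives_180(self):
        prof = _profile(0.0)
        s, r = prof.point("s"), prof.point("r")
        mid = ((s[0] + r[0]) / 2, (s[1] + r[1]) / 2)
        angles = bone_angles(prof, kyphion=mid)
        assert angles.KA == pytest.approx(180.0)

    def test_right_angle_dpa_construction(self):
        prof = BoneProfile(
            points=[(-5.0, -5.0), (0.0, 0.0), (5.0, 5.0), (10.0, 0.0), (14.0, 2.0)],
            labels=["g", "n", "s", "r", "prn"], mm_per_px=1.0)
        # n->s = (5,5), s->r = (5,-5): perpendicular
        assert bone_angles(prof).DPA == pytest.approx(90.0)

    def test_angles_equal_vertex_oracle(self):
        from nasoform.anthropometry import angle_at_vertex

        prof = _profile(1.2)
        found = detect_kyphion(prof, 0.5)
        a = bone_angles(prof, kyphion=found[0])
        assert a.DPA == pytest.approx(
            angle_at_vertex(prof.point("n"), prof.point("s"), prof.point("r")))
        assert a.KA == pytest.approx(
            angle_at_vertex(prof.point("s"), found[0], prof.point("r")))
        assert a.RA == pytest.approx(
            angle_at_vertex(found[0], prof.point("r"), prof.point("prn")))

    def test_missing_point_raises(self):
        prof = _profile(0.0)
        prof.labels[prof.labels.index("prn")] = ""
        with pytest.raises(GeometryError):
            bone_angles(prof)


class TestLateralClassification:
    def test_no_kyphion_is_v(self):
        assert classify_lateral_shape(BoneAngles(NA=130, DPA=150, RA=140),
                                      kyphion_present=False) == "V"

    def test_marked_angulation_is_s(self):
        a = BoneAngles(NA=130, DPA=150, RA=140, KA=160.0)
        assert classify_lateral_shape(a, True, tau_a_deg=4.0) == "S"

    def test_subthreshold_angulation_is_v(self):
        a = BoneAngles(NA=130, DPA=150, RA=140, KA=178.0)
        assert classify_lateral_shape(a, True, tau_a_deg=4.0) == "V"

    def test_kyphion_without_angle_is_error(self):
        with pytest.raises(GeometryError):
            classify_lateral_shape(BoneAngles(NA=130, DPA=150, RA=140), True)


class TestFrontalClassification:
    def test_decision_tree_trace_wide_vertical(self):
        dims = BoneDims(n_s=5.7, s_r=18.6, n_r=23.8, d3=10.0, d4=12.5, d5=9.9)
        assert classify_frontal_type(dims, border_slope_deg=70.0) == "A"
        assert classify_frontal_type(dims, border_slope_deg=90.0) == "E"

    def test_decision_tree_trace_narrow(self):
        dims = BoneDims(n_s=5.7, s_r=18.6, n_r=23.8, d3=7.0, d4=17.0, d5=6.8)
        assert classify_frontal_type(dims, border_slope_deg=70.0) == "C"

    def test_concave_routes(self):
        d = BoneDims(n_s=5.7, s_r=18.6, n_r=23.8, d3=10.0, d4=16.0, d5=7.5)
        assert classify_frontal_type(d, 70.0) == "B"
        wide = BoneDims(n_s=5.7, s_r=18.6, n_r=23.8, d3=15.0, d4=16.0, d5=11.0)
        assert classify_frontal_type(wide, 70.0) == "D"

    def test_generator_round_trip_self_consistency(self, population):
        for rec in population:
            _, frontal = classify_record(rec)
            assert frontal == rec.frontal_type

    @given(st.floats(1.0, 20.0), st.floats(1.0, 20.0), st.floats(0.01, 1.0),
           st.floats(0.0, 180.0))
    @settings(max_examples=200, derandomize=True)
    def test_total_and_deterministic(self, d3, d4, frac, slope):
        dims = BoneDims(n_s=5.0, s_r=18.0, n_r=23.0, d3=d3, d4=d4,
                        d5=frac * min(d3, d4))
        a = classify_frontal_type(dims, slope)
        b = classify_frontal_type(dims, slope)
        assert a == b and a in "ABCDE"

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DataError):
            classify_frontal_type(
                BoneDims(n_s=5, s_r=18, n_r=23, d3=0.0, d4=10, d5=5), 70.0)


class TestCadaverClassifier:
    def test_reproduces_published_marginals(self):
        from collections import Counter

        recs, _ = cadaver_fixture()
        lateral, frontal = zip(*(classify_record(r) for r in recs))
        assert Counter(lateral) == {"V": 26, "S": 7}
        assert Counter(frontal) == {"A": 19, "B": 10, "C": 1, "D": 2, "E": 1}


class TestBpnn:
    def test_parameter_count_arithmetic(self):
        cfg = BpnnConfig(features=("a", "b", "c"), hidden=(4,),
                         heads=("regression",), regression_targets=("y", "z"))
        model = build_bpnn(cfg)
        assert model.n_params() == 3 * 4 + 4 + 4 * 2 + 2

    def test_zero_hidden_rejected(self):
        with pytest.raises(ConfigurationError):
            build_bpnn(BpnnConfig(hidden=()))

    def test_seeded_init_identical(self):
        a = build_bpnn(BpnnConfig(seed=5))
        b = build_bpnn(BpnnConfig(seed=5))
        for p, q in zip(a.params, b.params):
            np.testing.assert_array_equal(p, q)

    def test_too_few_records_rejected(self, population):
        with pytest.raises(DataError):
            train_bpnn(population[:5], BpnnConfig(epochs=1))

    def test_probabilities_sum_to_one(self, population):
        model, _ = train_bpnn(population[:100], BpnnConfig(epochs=20, seed=0))
        res = predict_bone_morphology(model, population[100])
        assert sum(res.lateral_probs.values()) == pytest.approx(1.0, abs=1e-6)
        assert sum(res.frontal_probs.values()) == pytest.approx(1.0, abs=1e-6)

    def test_missing_feature_raises(self, population):
        model, _ = train_bpnn(population[:50], BpnnConfig(epochs=2, seed=0))
        bad = dataclasses.replace(population[51])
        bad.surface = {k: v for k, v in bad.surface.items() if k != "n-r"}
        with pytest.raises(FeatureError, match="n-r"):
            predict_bone_morphology(model, bad)

    def test_kyphion_free_training_predicts_all_v(self):
        recs = sample_population(dataclasses.replace(
            PopulationParams(n=300, seed=8), kyphion_prevalence=0.0))
        model, _ = train_bpnn(recs[:250], BpnnConfig(epochs=200, seed=0))
        preds = [predict_bone_morphology(model, r).lateral_shape
                 for r in recs[250:]]
        assert set(preds) == {"V"}

    def test_mean_male_input_predicts_near_male_mean_dims(self, population):
        """An average-male input maps close to the male-average bone dims."""
        cfg = BpnnConfig(heads=("regression",), epochs=200, seed=0)
        model, _ = train_bpnn(population, cfg)
        males = [r for r in population if r.sex == "M"]
        mean_rec = dataclasses.replace(males[0])
        mean_rec.age = float(np.mean([r.age for r in males]))
        mean_rec.height = float(np.mean([r.height for r in males]))
        mean_rec.weight = float(np.mean([r.weight for r in males]))
        mean_rec.surface = {k: float(np.mean([r.surface[k] for r in males]))
                            for k in males[0].surface}
        res = predict_bone_morphology(model, mean_rec)
        for t in ("N-R", "d4"):
            vals = [r.bone[t] for r in males]
            se = np.std(vals) / math.sqrt(len(males))
            assert abs(res.bone_dims[t] - np.mean(vals)) < max(3 * se, 0.4)

    def test_training_loss_decreases(self, population):
        _, hist = train_bpnn(population, BpnnConfig(epochs=50, seed=1))
        assert hist["loss"][-1] < hist["loss"][0]

    def test_shuffled_labels_destroy_recovery(self):
        from nasoform.experiments import bpnn_recovery

        r = bpnn_recovery(seed=2, noise_scale=1.0, shuffle=True,
                          n_train=600, n_test=300, epochs=120)
        assert r["mean"] <= 0.1
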