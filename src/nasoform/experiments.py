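"""Desk-scale reference experiments.

Each function runs one self-contained study on synthetic or fixture data and
returns plain numbers: the cadaver morphology percentages, pooled group
means, the feature-extractor shape check, oracle-equivalence error bounds,
gradient checks, BPNN parameter recovery, and the keypoint-CNN learning
sanity run.  ``scripts/acceptance.py`` and the test suite both call these,
so the reported quantities are always recomputed from scratch.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

from . import nn
from .anthropometry import euclidean_distance
from .keypoint import (NetworkConfig, build_keypoint_network,
                       conv_forward_reference, normalize_image,
                       train_keypoint_model, _coords_matrix, _mae_px,
                       _targets_from_coords)
from .metrics import (Detection, GroundTruth, GroupSummary, KeypointEvalConfig,
                      mae, mean_average_precision, pooled_mean, r_squared,
                      summarize_classification)
from .morphology import (BpnnConfig, build_bpnn, classify_record,
                         design_matrices, train_bpnn)
from .synthetic import (ANGLE_DEFAULTS, BONE_DEFAULTS, PopulationParams,
                        RenderConfig, cadaver_fixture, render_subject_views,
                        sample_population)


def cadaver_summary() -> dict[str, float]:
    """Morphology percentages of the 33-cadaver sample, via the full
    rule-based classifier on the fixture geometry."""
    records, _ = cadaver_fixture()
    lateral, frontal = zip(*(classify_record(r) for r in records))
    fr = summarize_classification(frontal)
    lt = summarize_classification(lateral)
    kyph = [r.has_kyphion for r in records]
    s_among_kyph = [s for s, k in zip(lateral, kyph) if k]
    return {
        "type_a_pct": float(fr.loc["A", "percentage"]),
        "type_b_pct": float(fr.loc["B", "percentage"]),
        "v_shape_pct": float(lt.loc["V", "percentage"]),
        "kyphion_prevalence_pct": round(100.0 * sum(kyph) / len(kyph), 1),
        "s_given_kyphion_pct": round(
            100.0 * sum(s == "S" for s in s_among_kyph) / len(s_among_kyph), 1),
    }


def pooled_means() -> dict[str, float]:
    """Sample-size-weighted pooled means of the published group statistics.

    Bone distances pool the cadaver sexes (18/15; the kyphion rows, measured
    on 4+4 subjects, pool with equal weights); profile angles pool the living
    evaluation cohort (81 male / 101 female).
    """
    def bone(code: str, n_m: int, n_f: int) -> float:
        m_m, _, m_f, _ = BONE_DEFAULTS[code]
        return pooled_mean([GroupSummary("M", n_m, m_m), GroupSummary("F", n_f, m_f)])

    def angle(code: str) -> float:
        link = ANGLE_DEFAULTS[code]
        return pooled_mean([GroupSummary("M", 81, link.mean_m),
                            GroupSummary("F", 101, link.mean_f)])

    return {
        "pooled_n_r_mm": round(bone("N-R", 18, 15), 2),
        "pooled_s_r_mm": round(bone("S-R", 18, 15), 2),
        "pooled_s_k_mm": round(bone("S-K", 4, 4), 2),
        "pooled_nasofrontal_deg": round(angle("g-n-prn"), 2),
        "pooled_nasomental_deg": round(angle("n-prn-sn"), 2),
    }


def extractor_shape_check(seed: int = 0) -> dict[str, float]:
    """Instantiate the full 19-layer network and push one 224x224x3 image
    through the feature extractor; returns the realised output shape."""
    model, summary = build_keypoint_network(NetworkConfig(), seed=seed)
    rng = np.random.default_rng(seed)
    x = normalize_image(rng.integers(0, 256, size=(1, 224, 224, 3)), sigma=0.5)
    feat = model.extract_features(x)
    return {
        "feature_map_side": int(feat.shape[1]),
        "feature_map_channels": int(feat.shape[3]),
        "conv_layers": summary["conv_layers"],
        "dense_layers": summary["dense_layers"],
        "pool_layers": summary["pool_layers"],
    }


def oracle_equivalence(seed: int = 0, n: int = 1000) -> dict[str, float]:
    """Max discrepancy between the vectorised implementations and their
    brute-force scalar oracles on random instances."""
    rng = np.random.default_rng(seed)

    # Euclidean distance vs per-coordinate sum of squares
    pq = rng.normal(0, 100, size=(n, 2, 2))
    derr = 0.0
    for p, q in pq:
        ref = (sum((float(a) - float(b)) ** 2 for a, b in zip(p, q))) ** 0.5
        derr = max(derr, abs(euclidean_distance(p, q) - ref))

    # convolution vs quadruple-loop oracle (valid mode, random sizes)
    cerr = 0.0
    for _ in range(50):
        hs = int(rng.integers(3, 9))
        x = rng.standard_normal((hs, hs))
        w = rng.standard_normal((3, 3))
        b = float(rng.standard_normal())
        ref = conv_forward_reference(x, w, b, activation="relu")
        layer = nn.Conv2D(1, 1, k=3, padding="valid", dtype=np.float64)
        layer.w[:, :, 0, 0] = w
        layer.b[0] = b
        out = nn.ReLU().forward(layer.forward(x[None, :, :, None]))[0, :, :, 0]
        cerr = max(cerr, float(np.abs(ref - out).max()))

    # MAE and R^2 vs scalar loops
    y = rng.standard_normal(n)
    yh = y + rng.standard_normal(n) * 0.3
    mae_ref = sum(abs(float(a) - float(b)) for a, b in zip(y, yh)) / n
    ybar = sum(map(float, y)) / n
    ss_res = sum((float(a) - float(b)) ** 2 for a, b in zip(y, yh))
    ss_tot = sum((float(a) - ybar) ** 2 for a in y)
    merr = abs(mae(y, yh) - mae_ref)
    rerr = abs(r_squared(y, yh) - (1 - ss_res / ss_tot))

    # mAP: contrived 3-detection case with a hand-enumerated PR area
    truths = [GroundTruth("i1", "p", (0.0, 0.0)), GroundTruth("i2", "p", (50.0, 0.0)),
              GroundTruth("i3", "p", (0.0, 50.0))]
    dets = [Detection("i1", "p", (1.0, 0.0), 0.9),     # TP
            Detection("i2", "p", (30.0, 0.0), 0.6),    # FP (off by 20)
            Detection("i3", "p", (0.0, 51.0), 0.3)]    # TP
    # precision after each det: 1/1, 1/2, 2/3; recall: 1/3, 1/3, 2/3
    # 101-pt AP = [r<=1/3 -> 1.0] 34 pts + (1/3, 2/3] -> 2/3 for 33 pts
    ap_ref = (34 * 1.0 + 33 * (2 / 3)) / 101
    ap = mean_average_precision(dets, truths, KeypointEvalConfig(radius=5.0))
    aerr = abs(ap - ap_ref)

    return {"distance_max_err": derr, "conv_max_err": cerr,
            "mae_err": merr, "r2_err": rerr, "map_err": aerr}


def gradient_checks(seed: int = 0) -> dict[str, float]:
    """Analytic vs central-difference gradients for a small CNN and the BPNN."""
    rng = np.random.default_rng(seed)
    cnn = nn.Sequential([
        nn.Conv2D(2, 3, k=3, padding="valid", rng=rng, dtype=np.float64), nn.ReLU(),
        nn.MaxPool2D(2, 2),
        nn.Conv2D(3, 2, k=3, padding="same", rng=rng, dtype=np.float64), nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Dense(2, 4, rng=rng, dtype=np.float64), nn.ReLU(),
        nn.Dense(4, 3, rng=rng, dtype=np.float64), nn.Sigmoid(),
    ])
    x = rng.standard_normal((2, 9, 9, 2))
    t = rng.random((2, 3))
    cnn_err = nn.finite_difference_gradcheck(cnn, x, t, eps=1e-6, rng=rng)

    bpnn = build_bpnn(BpnnConfig(features=("a", "b", "c"), hidden=(8, 4),
                                 heads=("regression",),
                                 regression_targets=("y1", "y2"), seed=seed))
    xb = rng.standard_normal((5, 3))
    tb = rng.standard_normal((5, 2))
    stack = nn.Sequential(bpnn.trunk.layers + [bpnn.heads["regression"]])
    # move zero-initialised biases off the ReLU kink: finite differences are
    # only meaningful where the loss is differentiable
    for p in stack.params:
        if p.ndim == 1:
            p += rng.uniform(0.01, 0.05, size=p.shape)
    bpnn_err = nn.finite_difference_gradcheck(stack, xb, tb, eps=1e-6, rng=rng)
    return {"cnn_gradcheck_max_rel_err": cnn_err,
            "bpnn_gradcheck_max_rel_err": bpnn_err}


def _shuffle_targets(records: Sequence, rng: np.random.Generator) -> list:
    shuffled = [copy.copy(r) for r in records]
    bones = [r.bone for r in shuffled]
    perm = rng.permutation(len(bones))
    for r, j in zip(shuffled, perm):
        r.bone = bones[j]
    return shuffled


def bpnn_recovery(seed: int = 0, noise_scale: float = 1.0, shuffle: bool = False,
                  n_train: int = 2000, n_test: int = 1000, epochs: int = 400
                  ) -> dict[str, float]:
    """Held-out R^2 of the BPNN on synthetic populations with a known link.

    ``noise_scale=0`` gives the noiseless parameter-recovery setting;
    ``shuffle=True`` destroys the feature-target pairing as a null control.
    Returns per-target R^2 plus their mean and the N-R value.
    """
    params = PopulationParams(n=n_train + n_test, seed=seed,
                              noise_scale=noise_scale)
    records = sample_population(params)
    train_recs, test_recs = records[:n_train], records[n_train:]
    if shuffle:
        train_recs = _shuffle_targets(train_recs, np.random.default_rng(seed + 1))
    cfg = BpnnConfig(heads=("regression",), epochs=epochs, seed=seed)
    model, _ = train_bpnn(train_recs, cfg)
    X, Y, _, _ = design_matrices(test_recs, cfg)
    xs = (X - model.x_mean) / model.x_sd
    pred = model.forward(xs)["regression"] * model.y_sd + model.y_mean
    out = {t: float(r_squared(Y[:, i], pred[:, i]))
           for i, t in enumerate(cfg.regression_targets)}
    out["mean"] = float(np.mean(list(out.values())))
    return out


def render_keypoint_dataset(n_images: int, seed: int,
                            view: str = "lateral",
                            image_size: int = 224) -> list:
    """Rendered (image, ground-truth landmarks) pairs for one view."""
    recs = sample_population(PopulationParams(n=n_images, seed=seed))
    cfg = RenderConfig(image_size=(image_size, image_size))
    data = []
    for i, rec in enumerate(recs):
        rv = render_subject_views(rec, cfg, seed=seed + 10_000 + i)[view]
        data.append((rv.image, rv.landmarks))
    return data


def keypoint_learning_sanity(seed: int = 0, n_images: int = 200,
                             epochs: int = 12) -> dict[str, float]:
    """Train the reduced-width 19-layer network on rendered lateral views.

    Compares validation landmark MAE (px) after training against the
    untrained (freshly initialised) network on the same validation split.
    """
    data = render_keypoint_dataset(n_images, seed)
    cfg = NetworkConfig(epochs=epochs, batch_size=20).reduced()
    model, hist = train_keypoint_model(data, cfg, seed=seed)

    # untrained baseline with identical initialisation and normalisation
    base, _ = build_keypoint_network(cfg, seed=seed)
    base.sigma = model.sigma
    h, w, _ = cfg.input_shape
    codes = cfg.codes()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(cfg.validation_split * len(data))))
    val = [data[i] for i in order[:n_val]]
    x = normalize_image(np.stack([d[0] for d in val]).astype(float),
                        base.sigma).astype(np.float32)
    t = np.stack([_targets_from_coords(_coords_matrix(ls, codes), (h, w))
                  for _, ls in val])
    baseline_mae = _mae_px(base, x, t)
    trained_mae = hist.val_mae_px[-1]
    return {
        "baseline_val_mae_px": float(baseline_mae),
        "trained_val_mae_px": float(trained_mae),
        "improvement_factor": float(baseline_mae / trained_mae),
        "epochs": float(epochs),
        "n_images": float(n_images),
    }
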