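"""Nasal-bone morphology: dorsal-hump (kyphion) detection, bone angles,
lateral V/S and frontal A-E classification, and the back-propagation neural
network (BPNN) that predicts bone dimensions and morphology classes from
surface measurements and body covariates.

Lateral shape rule: a V-shaped nasal bone has a straight dorsal line from
sellion to rhinion with a single angulation at the dorsal profile angle
(DPA); an S-shaped bone curves through a distinct kyphion, adding a second
angulation at the kyphion angle (KA).  Operationally a profile is S iff a
kyphion is detectable (perpendicular deviation from the sellion-rhinion
chord >= tau_k) and its angulation |180 - KA| reaches tau_a.

Frontal types follow the five-class scheme based on the frontonasal suture
width and the course of the nasomaxillary sutures (vertical / oblique /
concave), implemented as a fixed decision tree on the width ratio
w = d3/d4, the concavity c = 1 - d5/min(d3, d4), and the suture border
slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from . import nn
from .anthropometry import angle_at_vertex
from .errors import ConfigurationError, DataError, FeatureError, GeometryError

logger = logging.getLogger(__name__)

FRONTAL_TYPES = ("A", "B", "C", "D", "E")


# ---------------------------------------------------------------------------
# profiles, angles, rule-based classification
# ---------------------------------------------------------------------------

@dataclass
class BoneProfile:
    """Ordered lateral dorsal polyline from nasion to pronasale, in pixels.

    ``labels`` parallels ``points``; unnamed interpolated samples carry "".
    Under the orientation contract (subject faces +x, superior is -y) the
    x coordinates increase strictly along the profile.
    """

    points: list[tuple[float, float]]
    labels: list[str]
    mm_per_px: float

    def __post_init__(self) -> None:
        if len(self.points) < 4:
            raise GeometryError("bone profile needs >= 4 points")
        if len(self.points) != len(self.labels):
            raise GeometryError("points and labels must be parallel")
        xs = [p[0] for p in self.points]
        if not all(b > a for a, b in zip(xs, xs[1:])):
            raise GeometryError("profile x coordinates must be strictly increasing")

    def point(self, label: str) -> tuple[float, float]:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise GeometryError(f"profile has no point labelled {label!r}") from None

    def has(self, label: str) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class BoneAngles:
    """Nasion angle, dorsal profile angle, kyphion angle, rhinion angle (deg)."""

    NA: float
    DPA: float
    RA: float
    KA: float | None = None


@dataclass(frozen=True)
class BoneDims:
    """Bone dimensions in mm (S-K/K-R present only for kyphion-bearing noses)."""

    n_s: float
    s_r: float
    n_r: float
    d3: float     # upper width, at the nasofrontal suture
    d4: float     # lower width, at the nasomaxillary suture line
    d5: float     # narrowest width
    s_k: float | None = None
    k_r: float | None = None
    narrowest_pos: float = 0.5

    def narrowest_valid(self) -> bool:
        """The narrowest segment counts when it lies above the eye and at or
        below the sellion; with the sellion at fraction n_s/n_r of the bone
        length, that is narrowest_pos in [n_s/n_r, ~0.85]."""
        lo = self.n_s / self.n_r if self.n_r > 0 else 0.0
        return lo <= self.narrowest_pos <= 0.85


def detect_kyphion(
    profile: BoneProfile, tau_k_mm: float = 0.5
) -> tuple[tuple[float, float], float] | None:
    """Find the kyphion: the dorsal hump apex between sellion and rhinion.

    Scans interior profile points for the maximum perpendicular deviation from
    the sellion-rhinion chord on the dorsal (anterior) side, and returns
    ``(point, deviation_mm)`` iff that deviation reaches ``tau_k_mm``.
    """
    if tau_k_mm <= 0:
        raise ValueError(f"tau_k_mm must be positive, got {tau_k_mm}")
    s = np.asarray(profile.point("s"), float)
    r = np.asarray(profile.point("r"), float)
    chord = r - s
    clen = np.linalg.norm(chord)
    if clen == 0:
        raise GeometryError("sellion and rhinion coincide")
    u = chord / clen
    anterior = np.array([u[1], -u[0]])       # anterior normal (faces +x, sup -y)
    if anterior[0] < 0:
        anterior = -anterior
    i_s = profile.labels.index("s")
    i_r = profile.labels.index("r")
    best: tuple[tuple[float, float], float] | None = None
    for p in profile.points[i_s + 1:i_r]:
        dev_px = float(np.dot(np.asarray(p, float) - s, anterior))
        dev_mm = dev_px * profile.mm_per_px
        if dev_mm > 0 and (best is None or dev_mm > best[1]):
            best = (p, dev_mm)
    if best is None or best[1] < tau_k_mm:
        return None
    return best


def bone_angles(
    profile: BoneProfile, kyphion: tuple[float, float] | None = None
) -> BoneAngles:
    """Angular dimensions of the lateral bone profile.

    NA is taken at the nasion between the superior profile continuation (the
    point labelled "g" when present, else straight up) and the sellion
    direction; DPA at the sellion between nasion and rhinion; KA at the
    kyphion between sellion and rhinion (when a kyphion is given); RA at the
    rhinion between the kyphion (or sellion) and the pronasale.
    """
    n = profile.point("n")
    s = profile.point("s")
    r = profile.point("r")
    prn = profile.point("prn")
    up = profile.point("g") if profile.has("g") else (n[0], n[1] - 10.0)
    ka = None
    if kyphion is not None:
        ka = angle_at_vertex(s, kyphion, r)
    return BoneAngles(
        NA=angle_at_vertex(up, n, s),
        DPA=angle_at_vertex(n, s, r),
        RA=angle_at_vertex(kyphion if kyphion is not None else s, r, prn),
        KA=ka,
    )


def classify_lateral_shape(
    angles: BoneAngles, kyphion_present: bool, tau_a_deg: float = 4.0
) -> Literal["V", "S"]:
    """V vs S lateral shape: S iff a kyphion is present and the kyphion angle
    deviates from straight by at least ``tau_a_deg``."""
    if tau_a_deg <= 0:
        raise ValueError(f"tau_a_deg must be positive, got {tau_a_deg}")
    if not kyphion_present:
        return "V"
    if angles.KA is None:
        raise GeometryError("kyphion_present=True but no kyphion angle given")
    return "S" if abs(180.0 - angles.KA) >= tau_a_deg else "V"


@dataclass(frozen=True)
class FrontalThresholds:
    """Decision-tree thresholds for frontal types A-E (all configurable)."""

    rho_n: float = 0.45        # "relatively narrow" frontonasal suture: w < rho_n
    rho_w: float = 0.80        # "relatively wide": w >= rho_w
    kappa: float = 0.15        # concave nasomaxillary sutures: c >= kappa
    vertical_band_deg: float = 10.0   # |slope - 90| <= band counts as vertical

    def validate(self) -> None:
        if not (0 < self.rho_n < self.rho_w):
            raise ConfigurationError("need 0 < rho_n < rho_w")
        if self.kappa <= 0 or self.vertical_band_deg <= 0:
            raise ConfigurationError("kappa and vertical band must be positive")


def classify_frontal_type(
    dims: BoneDims,
    border_slope_deg: float,
    thresholds: FrontalThresholds = FrontalThresholds(),
) -> Literal["A", "B", "C", "D", "E"]:
    """Frontal nasal-bone type from widths and the suture border slope.

    With w = d3/d4 (frontonasal relative width), c = 1 - d5/min(d3, d4)
    (nasomaxillary concavity) and ``vertical`` = slope within the band
    around 90 deg, the tree is, in order:

    E: wide and straight-vertical; D: wide and concave; C: narrow and not
    concave; B: concave; A: otherwise (oblique, intermediate width).
    """
    thresholds.validate()
    if dims.d3 <= 0 or dims.d4 <= 0 or dims.d5 <= 0:
        raise DataError(f"non-positive width in {dims}")
    w = dims.d3 / dims.d4
    c = 1.0 - dims.d5 / min(dims.d3, dims.d4)
    vertical = abs(border_slope_deg - 90.0) <= thresholds.vertical_band_deg
    concave = c >= thresholds.kappa
    if w >= thresholds.rho_w and not concave and vertical:
        return "E"
    if w >= thresholds.rho_w and concave:
        return "D"
    if w < thresholds.rho_n and not concave:
        return "C"
    if concave:
        return "B"
    return "A"


def construct_bone_profile(rec, mm_per_px: float = 0.2, n_interior: int = 7) -> BoneProfile:
    """Build the lateral bone profile polyline implied by a subject record.

    Places n, s, r, prn from the record's bone distances (the dorsal profile
    angle at the sellion follows from the N-S / S-R / N-R triangle; profiles
    whose distances violate the triangle inequality are flattened to a
    straight dorsum), and superimposes the record's dorsal hump as a
    triangular bump with apex at the kyphion.
    """
    ns = rec.bone["N-S"]
    sr = rec.bone["S-R"]
    nr = rec.bone["N-R"]
    cosd = (ns * ns + sr * sr - nr * nr) / (2 * ns * sr)
    dpa = math.degrees(math.acos(np.clip(cosd, -1.0, 1.0)))
    # independent distance draws can fold the triangle; clamp to the
    # anatomically obtuse range so the polyline stays anterior-monotone
    dpa = min(180.0, max(100.0, dpa))

    base = math.radians(50.0)            # overall inferior-anterior course
    n = np.zeros(2)
    u_ns = np.array([math.cos(base), math.sin(base)])
    s = n + ns * u_ns
    bend = math.radians(180.0 - dpa)
    # choose the bend direction that keeps the profile anterior (x-monotone)
    u_a = np.array([math.cos(base + bend), math.sin(base + bend)])
    u_b = np.array([math.cos(base - bend), math.sin(base - bend)])
    u_sr = u_b if u_b[0] >= u_a[0] else u_a
    r = s + sr * u_sr
    prn = r + 9.0 * np.array([math.cos(base + 0.25), math.sin(base + 0.25)])
    g = n + 18.0 * np.array([-0.25, -1.0]) / np.linalg.norm([-0.25, -1.0])

    # interior dorsal samples between s and r with a triangular hump profile
    if rec.has_kyphion and rec.hump_mm > 0:
        frac_k = rec.bone.get("S-K", 14.3) / (
            rec.bone.get("S-K", 14.3) + rec.bone.get("K-R", 4.6))
    else:
        frac_k = 0.6
    chord = r - s
    ant = np.array([chord[1], -chord[0]])
    ant /= np.linalg.norm(ant)
    if ant[0] < 0:
        ant = -ant
    pts: list[np.ndarray] = []
    labels: list[str] = []

    def add(p: np.ndarray, lab: str = "") -> None:
        pts.append(p)
        labels.append(lab)

    add(g, "g")
    add(n, "n")
    add(s, "s")
    fracs = sorted(set(np.linspace(0.12, 0.92, n_interior)) | {frac_k})
    hump = rec.hump_mm if rec.has_kyphion else 0.0
    for f in fracs:
        height = hump * (f / frac_k if f <= frac_k else (1 - f) / (1 - frac_k))
        p = s + f * chord + height * ant
        add(p, "k" if (hump > 0 and abs(f - frac_k) < 1e-12) else "")
    add(r, "r")
    add(prn, "prn")
    return BoneProfile(points=[(float(p[0] / mm_per_px), float(p[1] / mm_per_px))
                               for p in pts],
                       labels=labels, mm_per_px=mm_per_px)


def classify_record(rec, tau_k_mm: float = 0.5, tau_a_deg: float = 4.0,
                    thresholds: FrontalThresholds = FrontalThresholds()
                    ) -> tuple[str, str]:
    """Run the full rule-based classifier on one record's geometry.

    Returns (lateral_shape, frontal_type) derived from the constructed bone
    profile and the record's widths - independent of the labels stored on the
    record.
    """
    profile = construct_bone_profile(rec)
    found = detect_kyphion(profile, tau_k_mm)
    angles = bone_angles(profile, kyphion=found[0] if found else None)
    lateral = classify_lateral_shape(angles, found is not None, tau_a_deg)
    dims = BoneDims(
        n_s=rec.bone["N-S"], s_r=rec.bone["S-R"], n_r=rec.bone["N-R"],
        d3=rec.bone["d3"], d4=rec.bone["d4"], d5=rec.bone["d5"],
        narrowest_pos=rec.narrowest_pos,
    )
    frontal = classify_frontal_type(dims, rec.frontal_border_slope_deg, thresholds)
    return lateral, frontal


# ---------------------------------------------------------------------------
# BPNN
# ---------------------------------------------------------------------------

DEFAULT_FEATURES = (
    "age", "sex", "height", "weight", "bmi",
    "n-prn", "n-sn", "al-al", "ac-ac", "n-r", "en-en", "sn-prn",
    "mf-mf", "mal-mal", "n-gn", "g-n-prn", "n-prn-sn",
)
DEFAULT_REGRESSION_TARGETS = ("N-S", "S-R", "N-R", "d3", "d4", "d5")


@dataclass(frozen=True)
class BpnnConfig:
    """Configuration of the bone-morphology BPNN."""

    features: tuple[str, ...] = DEFAULT_FEATURES
    regression_targets: tuple[str, ...] = DEFAULT_REGRESSION_TARGETS
    heads: tuple[str, ...] = ("regression", "frontal", "lateral")
    hidden: tuple[int, ...] = (32, 16)
    learning_rate: float = 0.001
    epochs: int = 400
    batch_size: int = 128
    seed: int = 0
    optimizer: str = "adam"             # "adam" | "sgd" (plain gradient descent)
    classification_weight: float = 0.2  # weight of each CE term vs the MSE term
    tolerable_error: float = 0.0        # early stop when train loss <= this

    def validate(self) -> None:
        if not self.features:
            raise ConfigurationError("feature list must be non-empty")
        if not self.hidden or any(h <= 0 for h in self.hidden):
            raise ConfigurationError(
                f"hidden sizes must be positive and non-empty, got {self.hidden}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        bad = set(self.heads) - {"regression", "frontal", "lateral"}
        if bad or not self.heads:
            raise ConfigurationError(f"invalid heads: {bad or 'empty'}")


class BpnnModel:
    """Multi-head MLP: shared ReLU trunk + linear regression / class heads."""

    def __init__(self, cfg: BpnnConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = (len(cfg.features),) + tuple(cfg.hidden)
        trunk: list[nn.Layer] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            trunk.append(nn.Dense(d_in, d_out, rng=rng, dtype=np.float64))
            trunk.append(nn.ReLU())
        self.trunk = nn.Sequential(trunk)
        h_last = dims[-1]
        self.heads: dict[str, nn.Dense] = {}
        if "regression" in cfg.heads:
            self.heads["regression"] = nn.Dense(
                h_last, len(cfg.regression_targets), rng=rng, dtype=np.float64)
        if "frontal" in cfg.heads:
            self.heads["frontal"] = nn.Dense(h_last, 5, rng=rng, dtype=np.float64)
        if "lateral" in cfg.heads:
            self.heads["lateral"] = nn.Dense(h_last, 2, rng=rng, dtype=np.float64)
        # feature / target standardisation constants (set by train_bpnn)
        self.x_mean = np.zeros(len(cfg.features))
        self.x_sd = np.ones(len(cfg.features))
        self.y_mean = np.zeros(len(cfg.regression_targets))
        self.y_sd = np.ones(len(cfg.regression_targets))

    @property
    def params(self) -> list[np.ndarray]:
        return self.trunk.params + [p for h in self.heads.values() for p in h.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return self.trunk.grads + [g for h in self.heads.values() for g in h.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        h = self.trunk.forward(x, train=train)
        return {name: head.forward(h, train=train) for name, head in self.heads.items()}

    def backward(self, douts: dict[str, np.ndarray]) -> None:
        dh = None
        for name, head in self.heads.items():
            d = head.backward(douts[name])
            dh = d if dh is None else dh + d
        self.trunk.backward(dh)


def build_bpnn(cfg: BpnnConfig) -> BpnnModel:
    """Construct a BPNN with seeded initial weights (identical per seed)."""
    return BpnnModel(cfg)


def _features_of(rec, names: Sequence[str]) -> list[float]:
    out = []
    for f in names:
        if f == "sex":
            out.append(1.0 if rec.sex == "M" else 0.0)
        elif f in ("age", "height", "weight", "bmi"):
            out.append(float(getattr(rec, f)))
        elif f in rec.surface:
            out.append(float(rec.surface[f]))
        else:
            raise FeatureError(f"record {rec.subject_id}: missing feature {f!r}")
    return out


def design_matrices(records: Sequence, cfg: BpnnConfig
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X, Y_regression, frontal labels, lateral labels) for a record table."""
    X = np.array([_features_of(r, cfg.features) for r in records], float)
    Y = np.array([[r.bone[t] for t in cfg.regression_targets] for r in records], float)
    yf = np.array([FRONTAL_TYPES.index(r.frontal_type) for r in records])
    yl = np.array([0 if r.lateral_shape == "V" else 1 for r in records])
    return X, Y, yf, yl


def train_bpnn(records: Sequence, cfg: BpnnConfig = BpnnConfig()
               ) -> tuple[BpnnModel, dict]:
    """Train the BPNN by backpropagation: W <- W - f * dError/dW.

    Features and regression targets are z-scored on the training set
    (constants stored on the model); the loss is MSE on standardized bone
    dimensions plus weighted cross-entropy for each classification head.
    Deterministic given ``cfg.seed``.
    """
    if len(records) < 10:
        raise DataError(f"need >= 10 training records, got {len(records)}")
    cfg.validate()
    model = build_bpnn(cfg)
    X, Y, yf, yl = design_matrices(records, cfg)

    x_sd = X.std(axis=0)
    dead = x_sd == 0
    if dead.any():
        names = [cfg.features[i] for i in np.flatnonzero(dead)]
        logger.warning("zero-variance features dropped from scaling: %s", names)
    model.x_mean = X.mean(axis=0)
    model.x_sd = np.where(dead, 1.0, x_sd)
    model.y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0)
    model.y_sd = np.where(y_sd == 0, 1.0, y_sd)
    Xs = (X - model.x_mean) / model.x_sd
    Xs[:, dead] = 0.0
    Ys = (Y - model.y_mean) / model.y_sd

    opt = nn.make_optimizer(cfg.optimizer, model.params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(records)
    history: dict[str, list[float]] = {"loss": [], "mse": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = ep_mse = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model.forward(Xs[idx], train=True)
            douts: dict[str, np.ndarray] = {}
            loss = 0.0
            mse = 0.0
            if "regression" in model.heads:
                mse, dmse = nn.mse_loss(out["regression"], Ys[idx])
                loss += mse
                douts["regression"] = dmse
            if "frontal" in model.heads:
                ce, dce = nn.cross_entropy_loss(out["frontal"], yf[idx])
                loss += cfg.classification_weight * ce
                douts["frontal"] = cfg.classification_weight * dce
            if "lateral" in model.heads:
                ce, dce = nn.cross_entropy_loss(out["lateral"], yl[idx])
                loss += cfg.classification_weight * ce
                douts["lateral"] = cfg.classification_weight * dce
            model.backward(douts)
            opt.step(model.grads)
            ep_loss += loss
            ep_mse += mse
            nb += 1
        history["loss"].append(ep_loss / nb)
        history["mse"].append(ep_mse / nb)
        if cfg.tolerable_error > 0 and history["loss"][-1] <= cfg.tolerable_error:
            break
    return model, history


@dataclass
class MorphologyResult:
    """Predicted bone dimensions and morphology classes for one subject."""

    bone_dims: dict[str, float]
    lateral_shape: Literal["V", "S"]
    frontal_type: Literal["A", "B", "C", "D", "E"]
    lateral_probs: dict[str, float]
    frontal_probs: dict[str, float]
    has_kyphion: bool


def predict_bone_morphology(model: BpnnModel, rec) -> MorphologyResult:
    """Predict bone dimensions (mm) and morphology classes for one record.

    Hard labels are the argmax of each head's probabilities, ties broken
    toward the earlier class letter (V before S).
    """
    x = np.asarray([_features_of(rec, model.cfg.features)], float)
    xs = (x - model.x_mean) / model.x_sd
    out = model.forward(xs, train=False)
    dims: dict[str, float] = {}
    if "regression" in model.heads:
        y = out["regression"][0] * model.y_sd + model.y_mean
        dims = {t: float(v) for t, v in zip(model.cfg.regression_targets, y)}
    lat_probs = {"V": 1.0, "S": 0.0}
    if "lateral" in model.heads:
        p = nn.softmax(out["lateral"][0])
        lat_probs = {"V": float(p[0]), "S": float(p[1])}
    fr_probs = {t: (1.0 if t == "A" else 0.0) for t in FRONTAL_TYPES}
    if "frontal" in model.heads:
        p = nn.softmax(out["frontal"][0])
        fr_probs = {t: float(v) for t, v in zip(FRONTAL_TYPES, p)}
    lateral = "V" if lat_probs["V"] >= lat_probs["S"] else "S"
    frontal = FRONTAL_TYPES[int(np.argmax([fr_probs[t] for t in FRONTAL_TYPES]))]
    has_k = getattr(rec, "has_kyphion", None)
    if has_k is None:
        has_k = lateral == "S"
    return MorphologyResult(
        bone_dims=dims, lateral_shape=lateral, frontal_type=frontal,
        lateral_probs=lat_probs, frontal_probs=fr_probs, has_kyphion=bool(has_k),
    )
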