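"""Synthetic study populations and stylised three-view face renderings.

Two generators make every pipeline stage testable without any external data:

* :func:`sample_population` draws subject records whose covariates, surface
  measurements, bone dimensions and morphology-class frequencies match the
  published group statistics of the source cohorts (living participants and
  cadavers), with a known linear-Gaussian surface<->bone link so that
  bone-dimension regression has a recoverable ground truth.
* :func:`render_subject_views` draws a stylised frontal/lateral/basilar scene
  for one subject - landmark disks on a schematic face plus a calibration
  ruler - returning the image together with exact ground-truth landmark
  coordinates and the mm-per-pixel scale.

:func:`cadaver_fixture` encodes the 33-cadaver reference sample exactly
(sex split, frontal type counts, lateral V/S counts, kyphion table, and
per-sex bone-distance means/SDs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, RenderError
from .landmarks import CalibrationInfo, LandmarkSet, View

Sex = Literal["M", "F"]
FRONTAL_TYPES = ("A", "B", "C", "D", "E")

# ---------------------------------------------------------------------------
# default population statistics
# ---------------------------------------------------------------------------

#: per-sex bone-distance / width Gaussians, mm: code -> (mean_M, sd_M, mean_F, sd_F)
BONE_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "N-S": (5.56, 1.25, 5.89, 1.19),
    "S-K": (14.54, 0.73, 14.08, 0.93),   # kyphion-bearing subjects only
    "K-R": (4.61, 1.29, 4.52, 1.08),     # kyphion-bearing subjects only
    "S-R": (18.85, 3.02, 18.22, 2.29),
    "N-R": (23.79, 3.46, 23.83, 2.29),
    "d4": (17.08, 2.08, 17.08, 2.08),    # lower width (nasomaxillary suture line)
}

#: pooled reference widths (mm) used to standardise derived widths in the link
D3_REF = (10.21, 2.53)   # upper width, nasofrontal suture
D5_REF = (8.24, 1.58)    # narrowest width


@dataclass(frozen=True)
class SurfaceLink:
    """Linear-Gaussian generative link for one surface measurement.

    value = mean_sex + bmi_slope*(bmi - bmi_mean) + loading*sd*z_bone
            + sqrt(1 - loading^2)*sd*noise_scale*eps,   eps ~ N(0, 1)

    where ``z_bone`` is the subject's linked bone dimension standardised
    within sex.  With ``loading`` close to 1 the surface trait is almost a
    deterministic function of the underlying bone dimension.
    """

    mean_m: float
    mean_f: float
    sd: float
    bmi_slope: float = 0.0
    bone_code: str = "N-R"
    loading: float = 0.0


#: surface distances, cm (baseline = normal-weight group; small sex offsets,
#: male larger, consistent with the reported sexual dimorphism)
SURFACE_DEFAULTS: dict[str, SurfaceLink] = {
    "n-prn": SurfaceLink(3.91, 3.80, 0.37, -0.020, "N-R", 0.85),
    "n-sn": SurfaceLink(4.97, 4.86, 0.31, 0.0, "N-S", 0.70),
    "al-al": SurfaceLink(4.09, 3.94, 0.31, 0.020, "d4", 0.80),
    "ac-ac": SurfaceLink(3.30, 3.17, 0.29, 0.017, "d4", 0.70),
    "n-r": SurfaceLink(1.30, 1.23, 0.21, -0.017, "N-R", 0.97),
    "en-en": SurfaceLink(3.62, 3.53, 0.23, 0.006, "d3", 0.60),
    "sn-prn": SurfaceLink(1.71, 1.64, 0.19, 0.012, "S-R", 0.60),
    "mf-mf": SurfaceLink(2.05, 1.96, 0.15, 0.0, "d3", 0.50),
    "mal-mal": SurfaceLink(3.37, 3.24, 0.25, 0.015, "d5", 0.60),
    "n-gn": SurfaceLink(11.60, 11.20, 0.80, 0.0, "N-R", 0.40),
}

#: surface angles, degrees; per-sex dispersions recovered from the printed
#: standard errors (SE * sqrt(n))
ANGLE_DEFAULTS: dict[str, SurfaceLink] = {
    "g-n-prn": SurfaceLink(133.89, 138.43, 0.0, 0.0, "N-R", 0.20),
    "n-prn-sn": SurfaceLink(103.43, 104.91, 0.0, 0.0, "N-R", 0.20),
}
ANGLE_SDS: dict[str, tuple[float, float]] = {
    "g-n-prn": (9.54, 5.73),
    "n-prn-sn": (5.76, 6.03),
}

#: frontal class frequencies (pooled cadaver counts 19/10/1/2/1 of 33)
FRONTAL_TYPE_PROBS = (19 / 33, 10 / 33, 1 / 33, 2 / 33, 1 / 33)

#: per-class sampling regions in (w = d3/d4, concavity c, border slope deg)
#: space; chosen with margin inside the classifier's default thresholds
#: (rho_n = 0.45, rho_w = 0.80, kappa = 0.15, vertical band +/-10 deg)
CLASS_REGIONS: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "A": ((0.48, 0.70), (0.01, 0.10), (60.0, 78.0)),
    "B": ((0.48, 0.70), (0.20, 0.33), (60.0, 78.0)),
    "C": ((0.30, 0.42), (0.01, 0.10), (60.0, 78.0)),
    "D": ((0.83, 0.95), (0.20, 0.33), (60.0, 95.0)),
    "E": ((0.83, 0.95), (0.01, 0.10), (83.0, 97.0)),
}

#: covariate Gaussians: (mean_M, sd_M, mean_F, sd_F)
AGE_DEFAULTS = (22.01, 1.39, 21.88, 1.68)
HEIGHT_DEFAULTS = (1.68, 0.06, 1.56, 0.055)    # metres
BMI_DEFAULTS = (22.34, 3.0)                    # shared between sexes


@dataclass(frozen=True)
class PopulationParams:
    """Everything :func:`sample_population` needs; defaults mirror the cohorts."""

    n: int = 182
    sex_ratio: float = 81 / 182          # fraction male
    seed: int = 0
    noise_scale: float = 1.0             # scales the residual eps of the link
    kyphion_prevalence: float = 8 / 33
    frontal_type_probs: tuple[float, ...] = FRONTAL_TYPE_PROBS
    bone: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(BONE_DEFAULTS))
    surface: Mapping[str, SurfaceLink] = field(
        default_factory=lambda: dict(SURFACE_DEFAULTS))
    angles: Mapping[str, SurfaceLink] = field(
        default_factory=lambda: dict(ANGLE_DEFAULTS))
    angle_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ANGLE_SDS))
    bmi_mean: float = BMI_DEFAULTS[0]
    bmi_sd: float = BMI_DEFAULTS[1]
    # kyphion geometry: detected humps vs sub-threshold humps (mm)
    hump_range_s: tuple[float, float] = (0.9, 2.2)
    hump_range_subthreshold: tuple[float, float] = (0.20, 0.42)
    tau_k_mm: float = 0.5                # kyphion detection threshold
    tau_a_deg: float = 4.0               # angulation threshold for S shape
    s_given_kyphion: float = 7 / 8

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError(f"n must be >= 0, got {self.n}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ParameterError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if not 0.0 <= self.kyphion_prevalence <= 1.0:
            raise ParameterError(
                f"kyphion_prevalence must be in [0, 1], got {self.kyphion_prevalence}")
        if len(self.frontal_type_probs) != 5:
            raise ParameterError("frontal_type_probs must have 5 entries")
        if abs(sum(self.frontal_type_probs) - 1.0) > 1e-9 or min(self.frontal_type_probs) < 0:
            raise ParameterError("frontal_type_probs must be non-negative and sum to 1")
        if self.noise_scale < 0:
            raise ParameterError(f"noise_scale must be >= 0, got {self.noise_scale}")
        for code, (mm, sm, mf, sf) in self.bone.items():
            if sm < 0 or sf < 0:
                raise ParameterError(f"bone[{code}]: SDs must be >= 0")
        for code, link in self.surface.items():
            if link.sd < 0:
                raise ParameterError(f"surface[{code}].sd must be >= 0")
            if not -1.0 <= link.loading <= 1.0:
                raise ParameterError(f"surface[{code}].loading must be in [-1, 1]")

    def zero_variance(self) -> "PopulationParams":
        """Copy with every SD set to 0 (degenerate, mean-only population)."""
        return replace(
            self,
            bone={c: (m, 0.0, f, 0.0) for c, (m, _, f, _) in self.bone.items()},
            surface={c: replace(l, sd=0.0) for c, l in self.surface.items()},
            angle_sds={c: (0.0, 0.0) for c in self.angle_sds},
            bmi_sd=0.0,
            noise_scale=0.0,
        )


@dataclass
class SubjectRecord:
    """One synthetic (or cadaver) subject: covariates, surface traits, ground truth."""

    subject_id: str
    sex: Sex
    age: float
    height: float        # m
    weight: float        # kg
    surface: dict[str, float]            # cm for distances, degrees for angles
    bone: dict[str, float]               # mm; S-K/K-R present only with kyphion
    has_kyphion: bool
    hump_mm: float                       # dorsal hump height; 0 without kyphion
    lateral_shape: Literal["V", "S"]
    frontal_type: Literal["A", "B", "C", "D", "E"]
    frontal_border_slope_deg: float
    narrowest_pos: float = 0.5           # fraction of N-R from N

    @property
    def bmi(self) -> float:
        return self.weight / self.height ** 2


def _truncnorm(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray,
               size: int, lower: float = 0.0) -> np.ndarray:
    """Gaussian truncated below at ``lower``; sd == 0 collapses to the mean."""
    mean = np.broadcast_to(np.asarray(mean, float), (size,)).copy()
    sd = np.broadcast_to(np.asarray(sd, float), (size,)).copy()
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        a = (lower - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], random_state=rng)
    return out


def _shape_from_hump(hump_mm: float, sk: float, kr: float,
                     tau_k: float, tau_a: float) -> str:
    """Apply the lateral V/S rule to generator geometry.

    The kyphion angle of a hump of height h over spans SK and KR deviates from
    a straight line by atan(h/SK) + atan(h/KR); a subject is S-shaped iff the
    hump is detectable (h >= tau_k) and that angulation reaches tau_a.
    """
    if hump_mm < tau_k:
        return "V"
    angulation = math.degrees(math.atan(hump_mm / sk) + math.atan(hump_mm / kr))
    return "S" if angulation >= tau_a else "V"


def sample_population(params: PopulationParams) -> list[SubjectRecord]:
    """Draw ``params.n`` subject records; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    if n == 0:
        return []

    male = rng.random(n) < params.sex_ratio
    sex = np.where(male, "M", "F")

    def per_sex(mm: float, sm: float, mf: float, sf: float,
                lower: float = 0.0) -> np.ndarray:
        out = np.empty(n)
        out[male] = _truncnorm(rng, mm, sm, int(male.sum()), lower)
        out[~male] = _truncnorm(rng, mf, sf, int((~male).sum()), lower)
        return out

    age = per_sex(*AGE_DEFAULTS, lower=16.0)
    height = per_sex(*HEIGHT_DEFAULTS, lower=1.2)
    bmi = _truncnorm(rng, params.bmi_mean, params.bmi_sd, n, lower=14.0)
    weight = bmi * height ** 2

    # --- bone dimensions -------------------------------------------------
    bone_vals: dict[str, np.ndarray] = {}
    for code in ("N-S", "S-R", "N-R", "d4"):
        bone_vals[code] = per_sex(*params.bone[code])
    sk = per_sex(*params.bone["S-K"])
    kr = per_sex(*params.bone["K-R"])

    # --- frontal type and widths -----------------------------------------
    types_idx = rng.choice(5, size=n, p=np.asarray(params.frontal_type_probs))
    w = np.empty(n)
    conc = np.empty(n)
    slope = np.empty(n)
    for t, (wr, cr, sr) in CLASS_REGIONS.items():
        m = types_idx == FRONTAL_TYPES.index(t)
        k = int(m.sum())
        w[m] = rng.uniform(*wr, size=k)
        conc[m] = rng.uniform(*cr, size=k)
        slope[m] = rng.uniform(*sr, size=k)
    d3 = w * bone_vals["d4"]
    d5 = (1.0 - conc) * np.minimum(d3, bone_vals["d4"])
    bone_vals["d3"], bone_vals["d5"] = d3, d5
    narrowest_pos = rng.uniform(0.35, 0.65, size=n)

    # --- kyphion / lateral shape -----------------------------------------
    has_k = rng.random(n) < params.kyphion_prevalence
    s_intent = rng.random(n) < params.s_given_kyphion
    hump = np.zeros(n)
    lo_s, hi_s = params.hump_range_s
    lo_v, hi_v = params.hump_range_subthreshold
    hump[has_k & s_intent] = rng.uniform(lo_s, hi_s, size=int((has_k & s_intent).sum()))
    hump[has_k & ~s_intent] = rng.uniform(lo_v, hi_v, size=int((has_k & ~s_intent).sum()))

    # --- surface measurements via the linear-Gaussian link ----------------
    def z_of(code: str, idx_male: np.ndarray) -> np.ndarray:
        # d3/d5 are derived (class-conditional) widths; standardise against the
        # realised population moments so linked surface means stay unbiased
        if code in ("d3", "d5"):
            v = d3 if code == "d3" else d5
            sd = v.std()
            return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        mm, sm, mf, sf = params.bone[code]
        mu = np.where(idx_male, mm, mf)
        sd = np.where(idx_male, sm, sf)
        return np.where(sd > 0, (bone_vals[code] - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    surface_vals: dict[str, np.ndarray] = {}
    for code, link in params.surface.items():
        mu = np.where(male, link.mean_m, link.mean_f)
        z = z_of(link.bone_code, male)
        eps = rng.standard_normal(n)
        surface_vals[code] = (
            mu
            + link.bmi_slope * (bmi - params.bmi_mean)
            + link.loading * link.sd * z
            + math.sqrt(max(0.0, 1.0 - link.loading ** 2)) * link.sd
            * params.noise_scale * eps
        )
    for code, link in params.angles.items():
        sd_m, sd_f = params.angle_sds[code]
        mu = np.where(male, link.mean_m, link.mean_f)
        sd = np.where(male, sd_m, sd_f)
        z = z_of(link.bone_code, male)
        eps = rng.standard_normal(n)
        surface_vals[code] = (
            mu + link.loading * sd * z
            + np.sqrt(np.maximum(0.0, 1.0 - link.loading ** 2)) * sd
            * params.noise_scale * eps
        )

    # --- assemble ---------------------------------------------------------
    records: list[SubjectRecord] = []
    for i in range(n):
        bone_i = {c: float(bone_vals[c][i]) for c in
                  ("N-S", "S-R", "N-R", "d3", "d4", "d5")}
        if has_k[i]:
            bone_i["S-K"] = float(sk[i])
            bone_i["K-R"] = float(kr[i])
            shape = _shape_from_hump(float(hump[i]), float(sk[i]), float(kr[i]),
                                     params.tau_k_mm, params.tau_a_deg)
        else:
            shape = "V"
        records.append(SubjectRecord(
            subject_id=f"syn{i:05d}",
            sex=str(sex[i]),
            age=float(age[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            surface={c: float(v[i]) for c, v in surface_vals.items()},
            bone=bone_i,
            has_kyphion=bool(has_k[i]),
            hump_mm=float(hump[i]) if has_k[i] else 0.0,
            lateral_shape=shape,
            frontal_type=FRONTAL_TYPES[types_idx[i]],
            frontal_border_slope_deg=float(slope[i]),
            narrowest_pos=float(narrowest_pos[i]),
        ))
    return records


def records_to_frame(records: Sequence[SubjectRecord]):
    """Flatten records into a pandas DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "sex": r.sex, "age": r.age,
            "height": r.height, "weight": r.weight, "bmi": r.bmi,
            "has_kyphion": r.has_kyphion, "hump_mm": r.hump_mm,
            "lateral_shape": r.lateral_shape, "frontal_type": r.frontal_type,
            "frontal_border_slope_deg": r.frontal_border_slope_deg,
            "narrowest_pos": r.narrowest_pos,
        }
        for c, v in r.surface.items():
            row[f"surface.{c}"] = v
        for c, v in r.bone.items():
            row[f"bone.{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df) -> list[SubjectRecord]:
    """Rebuild subject records from a :func:`records_to_frame` DataFrame."""
    records = []
    surface_cols = [c for c in df.columns if c.startswith("surface.")]
    bone_cols = [c for c in df.columns if c.startswith("bone.")]
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), sex=str(row["sex"]),
            age=float(row["age"]), height=float(row["height"]),
            weight=float(row["weight"]),
            surface={c[len("surface."):]: float(row[c]) for c in surface_cols
                     if np.isfinite(row[c])},
            bone={c[len("bone."):]: float(row[c]) for c in bone_cols
                  if np.isfinite(row[c])},
            has_kyphion=bool(row["has_kyphion"]),
            hump_mm=float(row["hump_mm"]),
            lateral_shape=str(row["lateral_shape"]),
            frontal_type=str(row["frontal_type"]),
            frontal_border_slope_deg=float(row["frontal_border_slope_deg"]),
            narrowest_pos=float(row["narrowest_pos"]),
        ))
    return records


# ---------------------------------------------------------------------------
# cadaver reference fixture
# ---------------------------------------------------------------------------

def _match_moments(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale a sample so its mean/SD equal the targets exactly."""
    if len(x) == 1:
        return np.array([mean])
    s = x.std(ddof=1)
    z = (x - x.mean()) / (s if s > 0 else 1.0)
    return mean + sd * z


def cadaver_fixture(seed: int = 33) -> tuple[list[SubjectRecord], dict]:
    """The 33-cadaver reference sample, with its contingency tables.

    Encodes exactly: 18 male / 15 female; frontal types A:(9,10) B:(6,4)
    C:(1,0) D:(1,1) E:(1,0); lateral V=26 / S=7; 8 kyphion-bearing subjects
    of which 7 are S-shaped and 1 carries a sub-detection-threshold hump
    (classified V).  Per-sex bone-distance sample means/SDs are matched to
    the published values exactly (moment matching).
    """
    rng = np.random.default_rng(seed)
    type_counts = {"M": {"A": 9, "B": 6, "C": 1, "D": 1, "E": 1},
                   "F": {"A": 10, "B": 4, "C": 0, "D": 1, "E": 0}}
    # lateral: S males 3, S females 4 (preserves all published marginals);
    # one additional male V subject carries the sub-threshold hump
    s_count = {"M": 3, "F": 4}

    records: list[SubjectRecord] = []
    idx = 0
    for sexcode, n_sex in (("M", 18), ("F", 15)):
        male = sexcode == "M"
        col = 0 if male else 2
        types = [t for t, k in type_counts[sexcode].items() for _ in range(k)]
        dims = {}
        for code in ("N-S", "S-R", "N-R", "d4"):
            mm, sm, mf, sf = BONE_DEFAULTS[code]
            mean, sd = (mm, sm) if male else (mf, sf)
            dims[code] = _match_moments(rng.standard_normal(n_sex), mean, sd)
        n_s = s_count[sexcode]
        shapes = ["S"] * n_s + ["V"] * (n_sex - n_s)
        kyph = [True] * n_s + [False] * (n_sex - n_s)
        if male:
            kyph[n_s] = True   # the single V-shaped kyphion bearer
        n_k = sum(kyph)
        mmk, smk, mfk, sfk = BONE_DEFAULTS["S-K"]
        mkr, skr, fkr, sfr = BONE_DEFAULTS["K-R"]
        sk_vals = _match_moments(rng.standard_normal(n_k),
                                 mmk if male else mfk, smk if male else sfk)
        kr_vals = _match_moments(rng.standard_normal(n_k),
                                 mkr if male else fkr, skr if male else sfr)
        ki = 0
        age = _truncnorm(rng, 64.9, 13.9, n_sex, lower=30.0)
        height = _truncnorm(rng, 1.66 if male else 1.55, 0.05, n_sex, lower=1.3)
        bmi = _truncnorm(rng, 21.5, 2.5, n_sex, lower=14.0)
        for j in range(n_sex):
            t = types[j]
            (wr, cr, sr) = CLASS_REGIONS[t]
            wv = rng.uniform(*wr)
            cv = rng.uniform(*cr)
            sv = rng.uniform(*sr)
            d4 = float(dims["d4"][j])
            d3 = wv * d4
            d5 = (1 - cv) * min(d3, d4)
            bone_i = {"N-S": float(dims["N-S"][j]), "S-R": float(dims["S-R"][j]),
                      "N-R": float(dims["N-R"][j]), "d3": d3, "d4": d4, "d5": d5}
            if kyph[j]:
                bone_i["S-K"] = float(max(sk_vals[ki], 1.0))
                bone_i["K-R"] = float(max(kr_vals[ki], 1.0))
                ki += 1
                hump = float(rng.uniform(0.9, 2.2)) if shapes[j] == "S" else 0.30
            else:
                hump = 0.0
            records.append(SubjectRecord(
                subject_id=f"cad{idx:03d}", sex=sexcode,
                age=float(age[j]), height=float(height[j]),
                weight=float(bmi[j] * height[j] ** 2),
                surface={}, bone=bone_i,
                has_kyphion=bool(kyph[j]), hump_mm=hump,
                lateral_shape=shapes[j], frontal_type=t,
                frontal_border_slope_deg=sv,
                narrowest_pos=float(rng.uniform(0.35, 0.65)),
            ))
            idx += 1

    tables = {
        "frontal_by_sex": type_counts,
        "lateral": {"V": 26, "S": 7},
        "kyphion": {"with": {"V": 1, "S": 7}, "without": {"V": 25, "S": 0}},
        "n_by_sex": {"M": 18, "F": 15},
    }
    return records, tables


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Scene parameters for the stylised three-view renderer."""

    image_size: tuple[int, int] = (224, 224)     # (h, w) px
    #: ruler tick spacing; None picks the smallest of 1/2/5/10/20/50 mm that
    #: renders at >= 2.5 px for the view's scale
    tick_spacing_mm: float | None = None
    noise_sd: float = 3.0                        # additive pixel noise
    background: int = 180
    channels: int = 3
    margin_px: int | None = None                 # None: ~frame/14
    ruler_x_px: int | None = None
    disk_radius: int = 2

    def validate(self) -> None:
        if min(self.image_size) < 64:
            raise ParameterError(f"image_size must be >= 64 px, got {self.image_size}")
        if self.tick_spacing_mm is not None and self.tick_spacing_mm <= 0:
            raise ParameterError("tick_spacing_mm must be positive")
        if self.channels not in (1, 3):
            raise ParameterError("channels must be 1 or 3")

    @property
    def margin(self) -> int:
        return self.margin_px if self.margin_px is not None else max(
            4, min(self.image_size) // 14)

    @property
    def ruler_x(self) -> int:
        return self.ruler_x_px if self.ruler_x_px is not None else max(
            2, self.image_size[1] // 37)


@dataclass
class RenderedView:
    """One rendered view: image + exact ground truth."""

    image: np.ndarray                    # (h, w, channels) uint8
    landmarks: LandmarkSet               # float px coordinates, exact
    calibration: CalibrationInfo
    ruler_ticks_px: list[tuple[float, float]]
    tick_spacing_mm: float
    meta: dict


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _lateral_layout(rec: SubjectRecord) -> tuple[dict[str, np.ndarray], dict]:
    """Midline landmark positions in mm; x anterior (+), y inferior (+), n at origin."""
    S = rec.surface
    cm_ = {k: S[k] * 10.0 for k in ("n-prn", "n-sn", "sn-prn", "n-r", "n-gn")}
    a, b, c = cm_["n-sn"], cm_["n-prn"], cm_["sn-prn"]
    meta = {"triangle_adjusted": False}
    # triangle n-sn-prn from its three sides; degenerate samples flattened
    if b + c < a:
        c = a - b
        meta["triangle_adjusted"] = True
    if a + c < b:
        c = b - a
        meta["triangle_adjusted"] = True
    cos_alpha = np.clip((a * a + b * b - c * c) / (2 * a * b), -1.0, 1.0)
    alpha = math.degrees(math.acos(cos_alpha))   # angle at n between sn and prn

    n = np.zeros(2)
    u_sn = _rot(np.array([0.0, 1.0]), -8.0)      # n->sn: 8 deg anterior of vertical
    sn = n + a * u_sn
    u_prn = _rot(u_sn, -alpha)                   # prn anterior of sn
    prn = n + b * u_prn
    r = n + cm_["n-r"] * u_prn                   # rhinion on the dorsum line
    perp_post = np.array([-u_prn[1], u_prn[0]])  # posterior normal of dorsum
    s = n + 0.45 * cm_["n-r"] * u_prn + 1.5 * perp_post
    g_dir_a = _rot(u_prn, S["g-n-prn"])
    g_dir_b = _rot(u_prn, -S["g-n-prn"])
    g_dir = g_dir_a if g_dir_a[1] < g_dir_b[1] else g_dir_b   # superior branch
    g = n + 20.0 * g_dir
    tr = g + np.array([-3.0, -26.0])
    u_gn = _rot(np.array([0.0, 1.0]), -4.0)
    gn = n + cm_["n-gn"] * u_gn
    pg = gn + np.array([2.5, -10.0])
    po = n + np.array([-55.0, 6.0])
    orb = n + np.array([-16.0, 4.0])
    cm_pt = 0.5 * (prn + sn) + np.array([1.0, 2.0])
    ls = sn + np.array([1.0, 8.0])
    li = sn + np.array([0.5, 18.0])
    # only the near (right) side of the paired Frankfort landmarks is visible
    pts = {"tr": tr, "g": g, "n": n, "s": s, "r": r, "prn": prn, "sn": sn,
           "pg": pg, "gn": gn, "po_R": po, "or_R": orb, "cm": cm_pt,
           "ls": ls, "li": li}
    if rec.has_kyphion:
        sk = rec.bone.get("S-K", 14.3)
        kr = rec.bone.get("K-R", 4.6)
        frac = sk / (sk + kr)
        chord = r - s
        ant = np.array([chord[1], -chord[0]])
        ant = ant / np.linalg.norm(ant)
        if ant[0] < 0:        # anterior points +x under the orientation contract
            ant = -ant
        pts["k"] = s + frac * chord + rec.hump_mm * ant
    return pts, meta


def _frontal_layout(rec: SubjectRecord, lat: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Frontal positions: x lateral (midline at 0), y shared with the lateral view."""
    S = rec.surface
    y = {k: float(lat[k][1]) for k in ("tr", "g", "n", "prn", "sn", "pg", "gn")}

    def pair(code: str, half_mm: float, yy: float) -> dict[str, np.ndarray]:
        return {f"{code}_R": np.array([-half_mm, yy]),
                f"{code}_L": np.array([half_mm, yy])}

    pts: dict[str, np.ndarray] = {
        k: np.array([0.0, y[k]]) for k in y
    }
    y_en = y["n"] + 4.0
    pts.update(pair("en", S["en-en"] * 5.0, y_en))
    pts.update(pair("ex", S["en-en"] * 5.0 + 19.0, y_en))
    pts.update(pair("mf", S["mf-mf"] * 5.0, y["n"] + 7.0))
    pts.update(pair("al", S["al-al"] * 5.0, y["sn"] - 4.0))
    pts.update(pair("ac", S["ac-ac"] * 5.0, y["sn"] - 1.0))
    pts.update(pair("mal", S["mal-mal"] * 5.0, y["sn"] - 8.0))
    pts.update(pair("zy", 62.0, y["n"] + 16.0))
    pts.update(pair("ch", 24.0, y["sn"] + 22.0))
    return pts


def _basilar_layout(rec: SubjectRecord) -> dict[str, np.ndarray]:
    S = rec.surface
    pts = {
        "prn": np.array([0.0, -20.0]),
        "cm": np.array([0.0, -12.0]),
        "sn": np.array([0.0, -5.0]),
        "al_R": np.array([-S["al-al"] * 5.0, -11.0]),
        "al_L": np.array([S["al-al"] * 5.0, -11.0]),
        "ac_R": np.array([-S["ac-ac"] * 5.0, -5.0]),
        "ac_L": np.array([S["ac-ac"] * 5.0, -5.0]),
    }
    return pts


#: polyline chains drawn per view to give the scene face-like structure
_CHAINS = {
    "lateral": [["tr", "g", "n", "s", "k", "r", "prn", "cm", "sn", "ls", "li", "pg", "gn"]],
    "frontal": [["tr", "g", "n", "prn", "sn", "pg", "gn"],
                ["ex_R", "en_R"], ["en_L", "ex_L"],
                ["mf_R", "al_R", "ac_R"], ["mf_L", "al_L", "ac_L"],
                ["ch_R", "ch_L"]],
    "basilar": [["al_R", "sn", "al_L"], ["prn", "cm", "sn"]],
}

# stable intensity per code so landmarks are visually distinguishable
def _code_intensity(code: str) -> int:
    from .landmarks import landmark_catalog

    codes = [d.code for d in landmark_catalog(include_supplementary=True)]
    i = codes.index(code) if code in codes else 0
    return 20 + (i * 7) % 110


def render_subject_views(
    rec: SubjectRecord, cfg: RenderConfig = RenderConfig(), seed: int = 0,
) -> dict[str, RenderedView]:
    """Render all three views of one subject with exact ground truth.

    Landmark pixel coordinates are an affine (fit-to-frame) placement of the
    mm-space face layout derived from the record's measurements, so measuring
    the ground-truth pixels with the returned calibration reproduces the
    record's surface distances up to the documented triangle adjustment.
    """
    from skimage.draw import disk, line

    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    out: dict[str, RenderedView] = {}

    lat_pts, lat_meta = _lateral_layout(rec)
    layouts: dict[str, tuple[dict[str, np.ndarray], dict]] = {
        "lateral": (lat_pts, lat_meta),
        "frontal": (_frontal_layout(rec, lat_pts), {}),
        "basilar": (_basilar_layout(rec), {}),
    }

    for view, (pts_mm, meta) in layouts.items():
        arr = np.stack(list(pts_mm.values()))
        xmin, ymin = arr.min(axis=0)
        xmax, ymax = arr.max(axis=0)
        m = cfg.margin
        ruler_w = cfg.ruler_x + 8
        avail_w = w - 2 * m - ruler_w
        avail_h = h - 2 * m
        if avail_w <= 0 or avail_h <= 0:
            raise RenderError(f"image {w}x{h} too small for margins")
        span_x = max(xmax - xmin, 1e-6)
        span_y = max(ymax - ymin, 1e-6)
        mm_per_px = max(span_x / avail_w, span_y / avail_h)
        if cfg.tick_spacing_mm is None:
            tick_mm = next((t for t in (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
                            if t / mm_per_px >= 2.5), None)
            if tick_mm is None:
                raise RenderError(f"{view}: no workable ruler tick spacing")
        else:
            tick_mm = cfg.tick_spacing_mm
        tick_px = tick_mm / mm_per_px
        if tick_px < 2.0:
            raise RenderError(
                f"{view}: ruler ticks {tick_px:.2f} px apart (< 2 px); scene too large")
        ox = ruler_w + m - xmin / mm_per_px
        oy = m - ymin / mm_per_px

        def to_px(p: np.ndarray) -> tuple[float, float]:
            return (float(p[0] / mm_per_px + ox), float(p[1] / mm_per_px + oy))

        px_pts = {c: to_px(p) for c, p in pts_mm.items()}
        for c, (x, y) in px_pts.items():
            if not (0 <= x < w and 0 <= y < h):
                raise RenderError(f"{view}: landmark {c} at ({x:.1f},{y:.1f}) out of frame")

        img = np.full((h, w), cfg.background, dtype=float)
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
        # face structure
        for chain in _CHAINS[view]:
            chain = [c for c in chain if c in px_pts]
            for p, q in zip(chain[:-1], chain[1:]):
                rr, cc = line(int(round(px_pts[p][1])), int(round(px_pts[p][0])),
                              int(round(px_pts[q][1])), int(round(px_pts[q][0])))
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                img[rr[ok], cc[ok]] = 120
        # landmark disks
        for c, (x, y) in px_pts.items():
            rr, cc = disk((y, x), cfg.disk_radius, shape=(h, w))
            img[rr, cc] = _code_intensity(c)
        # ruler: vertical bar with ticks at exact spacing
        img[:, cfg.ruler_x] = 30
        ticks: list[tuple[float, float]] = []
        yk = float(m)
        while yk <= h - m:
            ticks.append((float(cfg.ruler_x), yk))
            rr = int(round(yk))
            img[rr, cfg.ruler_x:cfg.ruler_x + 5] = 30
            yk += tick_px
        if len(ticks) < 3:
            raise RenderError(f"{view}: fewer than 3 ruler ticks fit in frame")

        img = np.clip(img, 0, 255).astype(np.uint8)
        if cfg.channels == 3:
            img = np.stack([img] * 3, axis=-1)
        else:
            img = img[..., None]

        ls = LandmarkSet(subject_id=rec.subject_id, view=view, points=dict(px_pts))
        cal = CalibrationInfo(view=view, mm_per_px=mm_per_px, source="ruler_ticks")
        out[view] = RenderedView(image=img, landmarks=ls, calibration=cal,
                                 ruler_ticks_px=ticks, tick_spacing_mm=tick_mm,
                                 meta=dict(meta))
    return out


def make_fixture_dataset(n: int, cfg: RenderConfig, seed: int, out_dir) -> dict:
    """Write a rendered fixture dataset (images, landmark JSON, CSV, manifest).

    Idempotent for a fixed seed: landmark JSON files are canonical and
    byte-identical across runs.  Returns the manifest dictionary.
    """
    import json
    from pathlib import Path

    import imageio.v3 as iio
    import yaml as _yaml

    from .io import write_landmark_file

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = replace(PopulationParams(), n=n, seed=seed)
    records = sample_population(params)
    files: list[str] = []
    for i, rec in enumerate(records):
        views = render_subject_views(rec, cfg, seed=seed + 1000 + i)
        for view, rv in views.items():
            stem = f"{rec.subject_id}_{view}"
            iio.imwrite(out_dir / f"{stem}.png", rv.image)
            write_landmark_file(rv.landmarks, out_dir / f"{stem}.json")
            cal_doc = {
                "view": view,
                "mm_per_px": round(rv.calibration.mm_per_px, 9),
                "tick_spacing_mm": rv.tick_spacing_mm,
                "ruler_ticks_px": [[round(x, 4), round(y, 4)]
                                   for x, y in rv.ruler_ticks_px],
            }
            with open(out_dir / f"{stem}.calibration.json", "w") as fh:
                json.dump(cal_doc, fh, sort_keys=True, indent=1)
            files.extend([f"{stem}.png", f"{stem}.json", f"{stem}.calibration.json"])
    frame = records_to_frame(records)
    frame.to_csv(out_dir / "population.csv", index=False)
    manifest = {
        "n": n,
        "seed": seed,
        "image_size": list(cfg.image_size),
        "tick_spacing_mm": cfg.tick_spacing_mm if cfg.tick_spacing_mm else "auto",
        "n_images": 3 * len(records),
        "files": sorted(files),
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        _yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
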