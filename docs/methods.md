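# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the tests do and do not establish.

## Landmark model

The catalog fixes 29 landmark points per subject: 9 midline points
(trichion, glabella, nasion, sellion, rhinion, pronasale, subnasale,
pogonion, gnathion) and 10 bilateral pairs (endocanthion, exocanthion,
maxillofrontale, alare, mid-alare, subalare, zygion, cheilion, porion,
orbitale), stored as sided codes (`al_L`/`al_R`).  The source material never
enumerates the full roster, so this is a declared, documented constant; the
mid-alare pair is included because the frontal symmetry ratios require
mid-alar right/left half-widths.  Four supplementary optional landmarks —
kyphion (present only with a dorsal hump), columella, labrale
superius/inferius — are catalog entries flagged `supplementary` and are not
counted among the 29.

Coordinates are image pixels, origin top-left, x rightward, y downward,
sub-pixel floats.  Lateral subjects face +x, superior is −y; all angle
formulas and the renderer share this contract.

## Calibration and measurement

`calibrate_scale` fits the principal axis of the ruler ticks, regresses the
projected tick positions on tick index, and takes the slope as the mean
inter-tick pixel distance; fits with perpendicular or spacing residuals
above 10 % of the spacing are rejected, as are fewer than 3 ticks.  The
measurement catalog (YAML, versioned) declares each measurement's kind,
operands, view and units: surface distances in cm, bone dimensions in mm,
angles in degrees.  Angles are interior angles at the middle operand, range
(0, 180]; the middle/lower facial height angles are defined as ∠(g, n, sn)
and ∠(n, sn, gn) — a documented choice, since only names are given in the
source.  Measurements whose operands include an absent optional landmark are
skipped rather than raised.

## Synthetic populations

`sample_population` draws, per subject: sex (male fraction 81/182 by
default), age/height Gaussians per sex, BMI ~ N(22.34, 3.0) truncated (the
published BMI dispersion of ±12.8 is not usable as an SD for a cohort
bounded [18.2, 32.7]; 3.0 is this package's realism choice), and weight =
BMI·height².  Bone distances (N–S, S–R, N–R, lower width d4) come from the
published per-sex Gaussians truncated at 0; S–K and K–R exist only for
kyphion-bearing subjects.  The frontal type is drawn from the published
frequencies (57.6/30.3/3.0/6.1/3.0 %), then (d3, d5, border slope) are
sampled inside that class's region of (w = d3/d4, concavity, slope) space
with margin to the classifier thresholds, which makes the generator↔
classifier round trip exact by construction.  The published per-sex angle
dispersions are recovered as SE·√n, since the printed ± values are only
consistent with the pooled SDs under that reading.

Surface traits follow a linear-Gaussian link

    value = μ_sex + β·(BMI − 22.34) + λ·σ·z_bone + √(1−λ²)·σ·noise_scale·ε

where z_bone is the linked bone dimension standardized within sex (derived
widths d3/d5 are standardized against the realized population so linked
means stay unbiased).  The link assignments make every regression target
identifiable from the surface: n–r and n–prn load on N–R (λ = 0.97 / 0.85;
the n–r residual SD of ≈0.5 mm models the repeatability of landmark
placement on calibrated photographs), n–sn on N–S, sn–prn on S–R, al–al and
ac–ac on d4, en–en and mf–mf on d3, mal–mal on d5.  `noise_scale=0` gives
the noiseless setting used for parameter-recovery testing.  BMI slopes
reproduce the direction and rough magnitude of the published BMI-group
contrasts (longer, narrower noses at low BMI).

Kyphion semantics: `has_kyphion` is anatomical presence (prevalence 8/33).
Given a kyphion, with probability 7/8 the hump height is drawn in
[0.9, 2.2] mm (detectable and angulated → S), otherwise in [0.20, 0.42] mm —
below the τ_k = 0.5 mm detection threshold, so the subject classifies V
while still carrying a hump.  This reproduces the reference sample's single
V-shaped kyphion-bearing subject.

The 33-cadaver fixture is deterministic: sex split 18/15, frontal type
counts A:(9,10) B:(6,4) C:(1,0) D:(1,1) E:(1,0), lateral V=26/S=7 with the
per-sex S split 3/4 (the published interior cells are internally
inconsistent; all marginals are preserved), kyphion table 1 V / 7 S among 8
bearers, and per-sex bone-distance sample moments matched exactly by affine
rescaling of a seeded draw.

## Rendering

Each view lays the landmarks out in a millimetre frame derived from the
subject's measurements: the lateral n/sn/prn triangle is built from its
three side lengths, the rhinion sits on the dorsum line at the surface n–r
distance, glabella is placed so the rendered nasofrontal angle equals the
subject's value, and the frontal view shares the lateral view's vertical
coordinates (so cross-view vertical separations agree exactly).  A
fit-to-frame affine maps mm to pixels; a ruler bar is drawn with ticks at an
exact pixel spacing (spacing auto-selected from 1/2/5/10/20/50 mm so ticks
are ≥2.5 px apart), which makes the calibration consistency identity
`tick-distance × mm/px = tick-mm` hold to float precision.  Landmarks are
drawn as small disks with stable per-code intensities on a schematic
polyline face, plus Gaussian pixel noise.

Real measurement tables are not exactly planar: the published distance and
angle means cannot be simultaneously realized by a 2D triangle, so the
renderer treats *distances* as primary.  The round-trip guarantee (measured
ground truth equals generator value within 0.5 px × mm/px) covers the
distances and the constructed nasofrontal angle; the sampled nasomental
angle remains a statistical covariate and is not forced onto the geometry.
About 7 % of subjects draw a (n–sn, n–prn, sn–prn) triple violating the
triangle inequality; the renderer then flattens the sn–prn side and flags
the view's `meta["triangle_adjusted"]`.

What the renders do **not** emulate: photographic texture, lighting,
occlusion, head-pose error, soft-tissue appearance, or labelling noise.
Tests passing on these scenes establish that the pipeline's geometry,
calibration and learning dynamics are correct — not that the CNN reaches
clinical accuracy on photographs.

## Networks

Both networks are NumPy implementations with hand-derived backward passes
(layers: stride-1 same/valid convolution via per-offset GEMM accumulation,
max-pooling with −inf padding and argmax routing, dropout, dense, global
average pooling, sigmoid/softmax heads; losses: MSE and cross-entropy;
optimizers: Adam, default lr 0.001, and plain gradient descent).  Gradient
correctness is enforced by central-difference checks at < 1e-4 relative
error (evaluated at points where biases have been jittered off the ReLU
kink, where the loss is differentiable).

The keypoint extractor follows the stated 19-layer topology: conv blocks of
(2,2,4,4,4) layers with channels (64,128,256,512,512) and pools of sizes
(3,3,3,3,5).  Stated stride-1 pooling cannot reduce 224→14, so the first
four pools use stride 2 and the fifth stride 1, honouring both the layer
count and the explicit 14×14×512 feature map.  The output head regresses
normalized coordinates through a sigmoid (a softmax over coordinates is not
meaningful; per-landmark heatmap output is not implemented).  A reduced
preset (channels 8/16/32/32/32) keeps CPU experiments tractable.
Augmentations (horizontal flip with paired-code relabelling, ±rotation,
brightness/contrast jitter, noise, shift-crop) are available and off by
default for determinism.  The backbone registry lists the comparison
architectures by name, but only the native 19-layer network is
constructible; the others raise a clear unavailable-adapter error.

The BPNN update is plain backpropagation `W ← W − f·∂E/∂W` with Adam as the
default optimizer; features and regression targets are z-scored on the
training set (constants stored in the model); zero-variance features are
dropped from scaling with a logged warning; classification heads contribute
weighted cross-entropy (weight 0.2 per head).

## Problem sizes and defaults

| quantity | default | rationale |
|---|---|---|
| τ_k (kyphion detection) | 0.5 mm | below palpable hump height; configurable |
| τ_a (S-shape angulation) | 4° | encodes the sub-threshold V-with-kyphion case |
| ρ_n, ρ_w, κ, vertical band | 0.45, 0.80, 0.15, ±10° | separate the five class templates; fully exposed |
| mAP radius | 5 px | fixed-radius correctness with 101-point interpolated AP |
| BPNN hidden sizes | (32, 16) | sufficient for the linear link; ~1e3 parameters |
| recovery experiments | 2000 train / 1000 test, 400 epochs | stable R² estimates in seconds |
| learning-sanity run | 200 images, 224², reduced width, 12 epochs | demonstrates ≥5× MAE reduction in ~5 CPU-minutes |

Statistical helpers use scipy (Welch's t with Satterthwaite df,
Kruskal–Wallis with tie correction); report percentages round half-up to one
decimal; no multiple-testing correction is applied.

## Known limitations

* The CNN is trained and validated on stylized renders only; no pretrained
  photographic backbones are bundled, and published photographic accuracy
  figures are out of scope.
* Bone dimensions are sampled marginally per sex; their joint correlation
  structure (beyond the class-conditional widths) is not modelled, and
  independent N–S/S–R/N–R draws can violate the profile triangle (the
  profile constructor clamps the dorsal angle to [100°, 180°]).
* The frontal A–E thresholds are calibrated to the synthetic templates;
  applying them to real suture geometry would require re-estimation.
* `predict_bone_morphology` infers `has_kyphion` from the lateral head when
  the record does not carry it; it is a correlate, not a detection.
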