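"""Landmark-detection CNN: normalization, the 19-layer architecture, training,
and inference.

The network is a VGG-style stack - 16 stride-1 3x3 convolution layers in five
blocks, five max-pooling layers (the first four stride 2, the last stride 1,
so a 224x224x3 input becomes a 14x14x512 feature map), dropout after each
pool, global average pooling, and 3 fully connected layers - trained with
Adam (learning rate 0.001) on mean squared error over landmark coordinates
normalized to [0, 1].  A sigmoid output head keeps predictions inside the
frame; per-landmark heatmap output is not implemented (coordinate regression
is the supported mode).

Everything runs on the NumPy layer core in :mod:`nasoform.nn`; the
scalar-loop :func:`conv_forward_reference` is the slow, obviously-correct
form of the convolution used as an oracle for the vectorised layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError, ParameterError
from .landmarks import LandmarkSet, View, codes_for_view

relu = nn.relu


def normalize_image(image: np.ndarray, sigma: float) -> np.ndarray:
    """Normalize pixel values: out = (in/255 - 0.5) / sigma, elementwise."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    img = np.asarray(image, float)
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ParameterError("pixel values must lie in [0, 255]")
    return (img / 255.0 - 0.5) / sigma


def denormalize_image(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Inverse of :func:`normalize_image` (exact up to float round-off)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    return (np.asarray(arr, float) * sigma + 0.5) * 255.0


def conv_forward_reference(
    input_map: np.ndarray,
    weights: np.ndarray,
    bias: float = 0.0,
    activation: Literal["relu", "identity"] = "identity",
) -> np.ndarray:
    """Scalar-loop valid convolution of a single-channel map (oracle form).

    out[a, b] = act( sum_i sum_j w[i, j] * x[a+i, b+j] + bias ),
    with output side = input side - filter side + 1.
    """
    x = np.asarray(input_map, float)
    w = np.asarray(weights, float)
    if x.ndim != 2 or w.ndim != 2:
        raise ValueError("reference convolution expects 2D input and filter")
    m, mk = w.shape
    if m > x.shape[0] or mk > x.shape[1]:
        raise ValueError(
            f"filter {w.shape} larger than input {x.shape}")
    if activation not in ("relu", "identity"):
        raise ValueError(f"unknown activation {activation!r}")
    ho = x.shape[0] - m + 1
    wo = x.shape[1] - mk + 1
    out = np.empty((ho, wo))
    for a in range(ho):
        for b in range(wo):
            acc = bias
            for i in range(m):
                for j in range(mk):
                    acc += w[i, j] * x[a + i, b + j]
            out[a, b] = max(0.0, acc) if activation == "relu" else acc
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentations (all off by default)."""

    hflip_prob: float = 0.0          # horizontal flip with paired-code relabel
    max_rotation_deg: float = 0.0    # uniform in +/- this
    brightness: float = 0.0          # additive, fraction of 255
    contrast: float = 0.0            # multiplicative jitter, +/- fraction
    noise_sd: float = 0.0            # additive Gaussian, pixel units
    max_shift_px: int = 0            # random crop-shift with coordinate adjust


PAPER19_CHANNELS = (64, 128, 256, 512, 512)
REDUCED_CHANNELS = (8, 16, 32, 32, 32)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training configuration of the keypoint network."""

    input_shape: tuple[int, int, int] = (224, 224, 3)
    view: View = "lateral"
    landmark_codes: tuple[str, ...] = ()     # default: catalog codes for view
    backbone: str = "paper19"
    channels: tuple[int, ...] = PAPER19_CHANNELS
    convs_per_block: tuple[int, ...] = (2, 2, 4, 4, 4)
    pool_sizes: tuple[int, ...] = (3, 3, 3, 3, 5)
    pool_strides: tuple[int, ...] = (2, 2, 2, 2, 1)
    dense: tuple[int, ...] = (256, 128)      # hidden dense sizes; +1 output layer
    dropout: float = 0.25
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 100
    validation_split: float = 0.2
    sigma: float | None = None               # default: training-set pixel SD
    output_mode: str = "coords"
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def codes(self) -> tuple[str, ...]:
        if self.landmark_codes:
            return self.landmark_codes
        codes = codes_for_view(self.view)
        if self.view == "lateral":
            # a lateral photograph shows the near (right) side only
            codes = tuple(c for c in codes if not c.endswith("_L"))
        return codes

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if not 0.0 < self.validation_split < 1.0:
            raise ConfigurationError("validation_split must be in (0, 1)")
        if not (len(self.channels) == len(self.convs_per_block)
                == len(self.pool_sizes) == len(self.pool_strides)):
            raise ConfigurationError("block specs must have equal lengths")
        if self.output_mode != "coords":
            raise ConfigurationError(
                f"output mode {self.output_mode!r} not supported; use 'coords'")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if not self.codes():
            raise ConfigurationError(f"no landmark codes for view {self.view!r}")

    def reduced(self) -> "NetworkConfig":
        """Same topology with narrow blocks (for CPU-scale experiments)."""
        return replace(self, channels=REDUCED_CHANNELS, dense=(64, 32))


def extractor_output_side(input_side: int, pool_strides: Sequence[int]) -> int:
    """Spatial side after the pooling stack (ceil division per stride)."""
    side = input_side
    for s in pool_strides:
        side = -(-side // s)
    return side


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class KeypointModel:
    """The assembled network plus its normalization constant and config."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.sigma = cfg.sigma if cfg.sigma is not None else 1.0
        h, w, c = cfg.input_shape
        extractor: list[nn.Layer] = []
        c_in = c
        for c_out, n_conv, pk, ps in zip(cfg.channels, cfg.convs_per_block,
                                         cfg.pool_sizes, cfg.pool_strides):
            for _ in range(n_conv):
                extractor.append(nn.Conv2D(c_in, c_out, k=3, padding="same", rng=rng))
                extractor.append(nn.ReLU())
                c_in = c_out
            extractor.append(nn.MaxPool2D(pk, ps))
            extractor.append(nn.Dropout(cfg.dropout, rng))
        self.extractor = nn.Sequential(extractor)
        n_out = 2 * len(cfg.codes())
        head: list[nn.Layer] = [nn.GlobalAvgPool()]
        d_in = cfg.channels[-1]
        for d in cfg.dense:
            head.append(nn.Dense(d_in, d, rng=rng))
            head.append(nn.ReLU())
            d_in = d
        head.append(nn.Dense(d_in, n_out, rng=rng))
        head.append(nn.Sigmoid())
        self.head = nn.Sequential(head)
        self.net = nn.Sequential(self.extractor.layers + self.head.layers)

    # -- introspection ----------------------------------------------------

    def layer_summary(self) -> dict:
        h, w, c = self.cfg.input_shape
        side = extractor_output_side(h, self.cfg.pool_strides)
        return {
            "conv_layers": sum(self.cfg.convs_per_block),
            "dense_layers": len(self.cfg.dense) + 1,
            "pool_layers": len(self.cfg.pool_sizes),
            "dropout_layers": len(self.cfg.pool_sizes),
            "extractor_output_shape": (side, side, self.cfg.channels[-1]),
            "n_params": self.net.n_params(),
            "output_dim": 2 * len(self.cfg.codes()),
        }

    def extract_features(self, images: np.ndarray) -> np.ndarray:
        """Run the feature extractor only (NHWC normalized input)."""
        return self.extractor.forward(images.astype(np.float32), train=False)

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(images.astype(np.float32), train=train)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: parameter arrays + embedded config + sigma."""
        cfg_doc = asdict(self.cfg)
        cfg_doc["augment"] = asdict(self.cfg.augment)
        np.savez(path, *self.net.params,
                 _meta=np.frombuffer(
                     json.dumps({"cfg": cfg_doc, "sigma": self.sigma}).encode(),
                     dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "KeypointModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            cfg_doc = meta["cfg"]
            cfg_doc["augment"] = AugmentConfig(**cfg_doc["augment"])
            for key in ("input_shape", "landmark_codes", "channels",
                        "convs_per_block", "pool_sizes", "pool_strides", "dense"):
                cfg_doc[key] = tuple(cfg_doc[key])
            cfg = NetworkConfig(**cfg_doc)
            model = cls(cfg, np.random.default_rng(0))
            model.sigma = meta["sigma"]
            arrays = [data[k] for k in data.files if k != "_meta"]
            for p, a in zip(model.net.params, arrays):
                p[...] = a
        return model


_BACKBONES: dict[str, Callable[[NetworkConfig, np.random.Generator], KeypointModel]] = {}


def register_backbone(name: str, builder) -> None:
    _BACKBONES[name] = builder


def _unavailable(name: str):
    def build(cfg, rng):
        raise ConfigurationError(
            f"backbone {name!r} is a comparison adapter without a bundled "
            "implementation; use 'paper19'")
    return build


register_backbone("paper19", lambda cfg, rng: KeypointModel(cfg, rng))
for _name in ("convnet", "inceptionv3", "mobilenet", "densenet", "vgg19"):
    register_backbone(_name, _unavailable(_name))


def list_backbones() -> tuple[str, ...]:
    return tuple(sorted(_BACKBONES))


def build_keypoint_network(
    cfg: NetworkConfig, seed: int = 0
) -> tuple[KeypointModel, dict]:
    """Build the configured network; returns (model, layer summary)."""
    cfg.validate()
    if cfg.backbone not in _BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {cfg.backbone!r}; available: {list_backbones()}")
    model = _BACKBONES[cfg.backbone](cfg, np.random.default_rng(seed))
    return model, model.layer_summary()


# ---------------------------------------------------------------------------
# data plumbing: coordinates <-> targets, resizing, augmentation
# ---------------------------------------------------------------------------

def _coords_matrix(ls: LandmarkSet, codes: Sequence[str]) -> np.ndarray:
    pts = []
    for c in codes:
        p = ls.get(c)
        if p is None:
            raise DataError(f"subject {ls.subject_id}: landmark {c!r} missing")
        pts.append(p)
    return np.asarray(pts, float)


def _targets_from_coords(coords: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    h, w = shape_hw
    t = coords / np.array([w - 1.0, h - 1.0])
    return t.reshape(-1)


def _coords_from_targets(t: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    h, w = shape_hw
    return t.reshape(-1, 2) * np.array([w - 1.0, h - 1.0])


def resize_with_padding(
    image: np.ndarray, target_hw: tuple[int, int]
) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Aspect-preserving resize plus edge padding to the target size.

    Returns (resized image, scale, (pad_top, pad_left)); a source coordinate
    maps to ``coord * scale + pad``.
    """
    from skimage.transform import resize as sk_resize

    h, w = image.shape[:2]
    th, tw = target_hw
    scale = min(th / h, tw / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    resized = sk_resize(image.astype(float), (nh, nw) + image.shape[2:],
                        order=1, mode="edge", anti_aliasing=False,
                        preserve_range=True)
    pad_top = (th - nh) // 2
    pad_left = (tw - nw) // 2
    out = np.zeros((th, tw) + image.shape[2:], dtype=float)
    out[...] = np.median(resized)
    out[pad_top:pad_top + nh, pad_left:pad_left + nw] = resized
    return out, scale, (pad_top, pad_left)


def _flip_index(codes: Sequence[str]) -> np.ndarray:
    """Landmark permutation under a horizontal flip (swap _L/_R codes)."""
    idx = np.arange(len(codes))
    pos = {c: i for i, c in enumerate(codes)}
    for i, c in enumerate(codes):
        if c.endswith("_L"):
            other = c[:-2] + "_R"
        elif c.endswith("_R"):
            other = c[:-2] + "_L"
        else:
            continue
        if other in pos:
            idx[i] = pos[other]
    return idx


def augment_batch(
    images: np.ndarray, coords: np.ndarray, codes: Sequence[str],
    acfg: AugmentConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured augmentations to a batch (uint8-scale images).

    ``coords`` has shape (B, L, 2); coordinates are adjusted consistently
    with every spatial transform.
    """
    from skimage.transform import rotate as sk_rotate

    images = images.astype(float).copy()
    coords = coords.copy()
    b, h, w = images.shape[:3]
    flip_idx = _flip_index(codes)
    for i in range(b):
        if acfg.hflip_prob > 0 and rng.random() < acfg.hflip_prob:
            images[i] = images[i][:, ::-1]
            coords[i, :, 0] = (w - 1.0) - coords[i, :, 0]
            coords[i] = coords[i][flip_idx]
        if acfg.max_rotation_deg > 0:
            ang = rng.uniform(-acfg.max_rotation_deg, acfg.max_rotation_deg)
            images[i] = sk_rotate(images[i], ang, mode="edge", preserve_range=True)
            # image rotation by +ang (CCW in row/col space) moves content;
            # rotate coordinates about the centre accordingly
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            a = math.radians(ang)
            x = coords[i, :, 0] - cx
            y = coords[i, :, 1] - cy
            coords[i, :, 0] = math.cos(a) * x + math.sin(a) * y + cx
            coords[i, :, 1] = -math.sin(a) * x + math.cos(a) * y + cy
        if acfg.max_shift_px > 0:
            dx = rng.integers(-acfg.max_shift_px, acfg.max_shift_px + 1)
            dy = rng.integers(-acfg.max_shift_px, acfg.max_shift_px + 1)
            images[i] = np.roll(images[i], (dy, dx), axis=(0, 1))
            coords[i, :, 0] += dx
            coords[i, :, 1] += dy
        if acfg.contrast > 0:
            f = 1.0 + rng.uniform(-acfg.contrast, acfg.contrast)
            images[i] = (images[i] - 127.5) * f + 127.5
        if acfg.brightness > 0:
            images[i] += 255.0 * rng.uniform(-acfg.brightness, acfg.brightness)
        if acfg.noise_sd > 0:
            images[i] += rng.normal(0, acfg.noise_sd, images[i].shape)
    np.clip(images, 0, 255, out=images)
    np.clip(coords[..., 0], 0, w - 1, out=coords[..., 0])
    np.clip(coords[..., 1], 0, h - 1, out=coords[..., 1])
    return images, coords


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    """Per-epoch losses and validation MAE in pixels."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae_px: list[float] = field(default_factory=list)


def _mae_px(model: KeypointModel, x: np.ndarray, t: np.ndarray) -> float:
    h, w, _ = model.cfg.input_shape
    pred = model.forward(x, train=False)
    scale = np.tile(np.array([w - 1.0, h - 1.0]), t.shape[1] // 2)
    return float(np.mean(np.abs((pred - t) * scale)))


def train_keypoint_model(
    dataset: Sequence[tuple[np.ndarray, LandmarkSet]],
    cfg: NetworkConfig,
    seed: int = 0,
) -> tuple[KeypointModel, TrainingHistory]:
    """Train the keypoint network on (image, ground-truth landmarks) pairs.

    Images must match ``cfg.input_shape``; pixel values in [0, 255].  The
    normalization sigma defaults to the pixel standard deviation of the
    training split (in 0-1 units).  Deterministic given ``seed``.
    """
    cfg.validate()
    if len(dataset) == 0:
        raise DataError("empty dataset")
    codes = cfg.codes()
    h, w, c = cfg.input_shape
    images = np.stack([np.asarray(img, float) for img, _ in dataset])
    if images.shape[1:] != (h, w, c):
        raise DataError(
            f"images have shape {images.shape[1:]}, config wants {(h, w, c)}")
    coords = np.stack([_coords_matrix(ls, codes) for _, ls in dataset])

    rng = np.random.default_rng(seed)
    model, _ = build_keypoint_network(cfg, seed=seed)

    n = len(dataset)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_split * n))) if n > 1 else 0
    val_idx = order[:n_val]
    tr_idx = order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = val_idx, val_idx

    if cfg.sigma is None:
        model.sigma = float(np.std(images[tr_idx] / 255.0))
        if model.sigma <= 0:
            model.sigma = 1.0
    else:
        model.sigma = cfg.sigma

    def prep(img_batch: np.ndarray) -> np.ndarray:
        return normalize_image(img_batch, model.sigma).astype(np.float32)

    targets = np.stack([_targets_from_coords(cd, (h, w)) for cd in coords])
    x_val = prep(images[val_idx]) if n_val else None
    t_val = targets[val_idx] if n_val else None

    opt = nn.make_optimizer(cfg.optimizer, model.net.params, cfg.learning_rate)
    hist = TrainingHistory()
    acfg = cfg.augment
    augmenting = any([acfg.hflip_prob, acfg.max_rotation_deg, acfg.brightness,
                      acfg.contrast, acfg.noise_sd, acfg.max_shift_px])
    for epoch in range(cfg.epochs):
        ep_order = rng.permutation(len(tr_idx))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(tr_idx), cfg.batch_size):
            bidx = tr_idx[ep_order[start:start + cfg.batch_size]]
            bimg, bcoord = images[bidx], coords[bidx]
            if augmenting:
                bimg, bcoord = augment_batch(bimg, bcoord, codes, acfg, rng)
            x = prep(bimg)
            t = np.stack([_targets_from_coords(cd, (h, w)) for cd in bcoord])
            out = model.net.forward(x, train=True)
            loss, dout = nn.mse_loss(out, t.astype(np.float32))
            model.net.backward(dout)
            opt.step(model.net.grads)
            ep_loss += loss
            nb += 1
        hist.train_loss.append(ep_loss / nb)
        if x_val is not None:
            out = model.forward(x_val, train=False)
            vloss, _ = nn.mse_loss(out, t_val.astype(np.float32))
            hist.val_loss.append(vloss)
            hist.val_mae_px.append(_mae_px(model, x_val, t_val))
    return model, hist


def predict_landmarks(model: KeypointModel, image: np.ndarray,
                      view: View | None = None) -> LandmarkSet:
    """Detect all catalog landmarks of the model's view on one image.

    Inputs of other sizes are resized preserving aspect ratio and padded;
    predicted coordinates are mapped back into the original frame and
    clamped to the image bounds.
    """
    cfg = model.cfg
    view = view or cfg.view
    if view != cfg.view:
        raise DataError(f"model was trained for view {cfg.view!r}, got {view!r}")
    h, w, c = cfg.input_shape
    img = np.asarray(image, float)
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[2] != c:
        raise DataError(f"expected {c} channels, got {img.shape[2]}")
    oh, ow = img.shape[:2]
    if (oh, ow) != (h, w):
        resized, scale, (pt, pl) = resize_with_padding(img, (h, w))
    else:
        resized, scale, (pt, pl) = img, 1.0, (0, 0)
    x = normalize_image(resized[None], model.sigma).astype(np.float32)
    out = model.forward(x, train=False)[0]
    pts = _coords_from_targets(out, (h, w))
    pts[:, 0] = (pts[:, 0] - pl) / scale
    pts[:, 1] = (pts[:, 1] - pt) / scale
    pts[:, 0] = np.clip(pts[:, 0], 0, ow - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, oh - 1)
    codes = cfg.codes()
    return LandmarkSet(
        subject_id="detected", view=view,
        points={cd: (float(px), float(py)) for cd, (px, py) in zip(codes, pts)},
        confidence={cd: 1.0 for cd in codes},
    )


def finite_difference_gradcheck(model, x: np.ndarray, target: np.ndarray,
                                eps: float = 1e-5, **kw) -> float:
    """Max relative error between analytic and central-difference gradients.

    Accepts a :class:`KeypointModel` or a bare layer stack.  Small nets only.
    """
    net = model.net if isinstance(model, KeypointModel) else model
    return nn.finite_difference_gradcheck(net, x, target, eps=eps, **kw)
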