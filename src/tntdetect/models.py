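"""The two learned components: patch classifier and attention U-Net segmenter.

The classifier decides whether a sliding-window patch contains a TNT; it is a
convolutional backbone feeding a 512/170/70 dense head with 60% dropout
between the dense layers and a sigmoid output.  The segmenter is a U-Net
whose encoder doubles feature channels while halving spatial dimensions at
each level, with a mirrored decoder (2x2 up-convolutions, skip concatenation)
whose skips are gated by additive attention; it is trained with the composite
BCE + Dice + active-contour loss and emits a per-pixel TNT probability map
that is rescaled to an 8-bit heatmap.

Both models come in two tiers.  The transfer-learning tier
(``vgg16_pretrained`` / ``resnet_pretrained``) requires a deep-learning
runtime with downloadable ImageNet weights and raises a clear error when that
is unavailable; the self-contained tier (``small_cnn`` / ``small_encoder``)
trains from scratch on the in-package numpy layer library and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .config import ClassifierConfig, ConfigError, SegmenterConfig
from .types import ValidationError

__all__ = [
    "PatchHeatmap", "TNTClassifier", "TNTSegmenter",
    "build_classifier", "train_classifier",
    "build_segmenter", "train_segmenter",
    "composite_loss", "predict_heatmap", "dice_coefficient",
    "PretrainedUnavailableError",
]


class PretrainedUnavailableError(RuntimeError):
    """Raised when a pretrained backbone is requested without the runtime."""


@dataclass
class PatchHeatmap:
    """8-bit TNT-probability map for one patch, anchored in the parent image."""

    pixels: np.ndarray
    origin: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError("heatmap must be 2D")
        if arr.min() < 0 or arr.max() > 255:
            raise ValidationError("heatmap values must be in [0,255]")
        self.pixels = arr.astype(np.uint8)


def _as_nhwc(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim == 3:
        x = x[:, :, :, None]
    return x


# ----------------------------------------------------------------------------
# Patch classifier


class TNTClassifier:
    """Patch-level TNT presence classifier (probability per patch)."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.input_size % config.pool_to != 0:
            raise ConfigError("input_size must be a multiple of pool_to")
        factor = config.input_size // config.pool_to
        ch = config.base_channels
        layers: List[nn.Layer] = [nn.AvgPool(factor)]
        cin, side = 1, config.pool_to
        for cout in (ch, 2 * ch, 2 * ch):
            layers += [nn.Conv2D(cin, cout, 3, rng), nn.ReLU(), nn.MaxPool2()]
            cin, side = cout, side // 2
        layers.append(nn.Flatten())
        fin = side * side * cin
        for width in config.head_sizes:
            layers += [nn.Dense(fin, width, rng), nn.ReLU(),
                       nn.Dropout(config.dropout_rate, rng)]
            fin = width
        layers += [nn.Dense(fin, 1, rng), nn.Sigmoid()]
        self.net = nn.Sequential(layers)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Probabilities in [0,1] for (N, size, size[, 1]) patches."""
        x = _as_nhwc(patches)
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValidationError(
                f"expected {self.config.input_size}-px patches, got {x.shape[1:3]}")
        return self.net.forward(x, train=False)[:, 0]

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return (self.predict_proba(patches) >=
                self.config.decision_threshold).astype(int)


def build_classifier(config: ClassifierConfig) -> TNTClassifier:
    """Construct a patch classifier per the configuration.

    ``vgg16_pretrained`` needs an ImageNet-initialised VGG16 backbone, which
    requires a deep-learning runtime and downloaded weights; when that is not
    available an explicit error points at the ``small_cnn`` fallback.
    """
    if config.backbone == "vgg16_pretrained":
        raise PretrainedUnavailableError(
            "the vgg16_pretrained backbone needs a deep-learning runtime with "
            "ImageNet weights, which is not available in this installation; "
            "use backbone='small_cnn' instead")
    return TNTClassifier(config)


def train_classifier(
    handle: TNTClassifier,
    patches: np.ndarray,
    labels: np.ndarray,
    config: Optional[ClassifierConfig] = None,
) -> Tuple[TNTClassifier, Dict[str, List[float]]]:
    """Train with Adam on binary cross-entropy; returns (handle, history).

    Deterministic under the configured seed.  Requires at least one example
    of each class.
    """
    config = config or handle.config
    x = _as_nhwc(patches)
    y = np.asarray(labels, dtype=np.float32).reshape(-1)
    if x.shape[0] == 0:
        raise ValidationError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(handle.net.param_layers(), lr=config.learning_rate)
    history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            p = handle.net.forward(xb, train=True)[:, 0]
            loss, grad = nn.bce_loss(p, yb)
            handle.net.backward(grad[:, None])
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int(((p >= config.decision_threshold) == (yb > 0.5)).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
    return handle, history


# ----------------------------------------------------------------------------
# Composite segmentation loss


def composite_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    return_grad: bool = False,
):
    """``w_bce*BCE + w_dice*(1-Dice) + w_ac*AC`` on a probability map.

    The AC term combines a boundary-length energy with inside/outside region
    energies for a binary target (inside level 1, outside 0), normalized per
    pixel.  With ``return_grad`` the gradient w.r.t. ``pred`` is also
    returned.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValidationError(
            f"pred shape {pred.shape} != target shape {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValidationError("pred must hold probabilities in [0,1]")
    w_bce, w_dice, w_ac = weights
    total, grad = 0.0, np.zeros_like(pred)
    if w_bce > 0:
        l, g = nn.bce_loss(pred, target)
        total += w_bce * l
        grad += w_bce * g
    if w_dice > 0:
        l, g = nn.dice_loss(pred, target)
        total += w_dice * l
        grad += w_dice * g
    if w_ac > 0:
        l, g = nn.active_contour_loss(pred, target)
        total += w_ac * l
        grad += w_ac * g
    if return_grad:
        return float(total), grad
    return float(total)


# ----------------------------------------------------------------------------
# Attention U-Net segmenter


class TNTSegmenter:
    """U-Net with optional additive attention gates on the skip connections."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        depth, ch = config.depth, config.base_channels
        self.enc_blocks: List[List[nn.Layer]] = []
        self.pools: List[nn.MaxPool2] = []
        cin = 1
        enc_channels = []
        for d in range(depth):
            cout = ch * (2**d)  # channels double at each level
            self.enc_blocks.append([
                nn.Conv2D(cin, cout, 3, rng), nn.ReLU(),
                nn.Conv2D(cout, cout, 3, rng), nn.ReLU(),
            ])
            enc_channels.append(cout)
            self.pools.append(nn.MaxPool2())
            cin = cout
        cbott = ch * (2**depth)
        self.bottleneck: List[nn.Layer] = [
            nn.Conv2D(cin, cbott, 3, rng), nn.ReLU(),
            nn.Conv2D(cbott, cbott, 3, rng), nn.ReLU(),
        ]
        self.dec: List[dict] = []
        cup = cbott
        for d in reversed(range(depth)):
            cskip = enc_channels[d]
            stage = {
                "up": nn.Upsample2(),
                # 2x2 up-convolution halving the feature channels
                "upconv": nn.Conv2D(cup, cskip, 2, rng),
                "gate": (nn.AttentionGate(cskip, rng)
                         if config.use_attention else None),
                "convs": [nn.Conv2D(2 * cskip, cskip, 3, rng), nn.ReLU(),
                          nn.Conv2D(cskip, cskip, 3, rng), nn.ReLU()],
            }
            self.dec.append(stage)
            cup = cskip
        self.head: List[nn.Layer] = [nn.Conv2D(cup, 1, 1, rng), nn.Sigmoid()]

    # -- plumbing ---------------------------------------------------------

    def param_layers(self) -> List[nn.Layer]:
        out: List[nn.Layer] = []
        for block in self.enc_blocks:
            out += [l for l in block if l.params]
        out += [l for l in self.bottleneck if l.params]
        for stage in self.dec:
            out.append(stage["upconv"])
            if stage["gate"] is not None:
                out += stage["gate"].sublayers
            out += [l for l in stage["convs"] if l.params]
        out += [l for l in self.head if l.params]
        return out

    def _check_size(self, side: int) -> None:
        f = 2**self.config.depth
        if side % f != 0:
            raise ValidationError(
                f"crop side {side} not divisible by 2^depth={f}; pad to "
                f"{int(np.ceil(side / f)) * f}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _as_nhwc(x)
        self._check_size(x.shape[1])
        self._check_size(x.shape[2])
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for stage, skip in zip(self.dec, reversed(skips)):
            x = stage["up"].forward(x, train)
            x = stage["upconv"].forward(x, train)
            gated = (skip if stage["gate"] is None
                     else stage["gate"].forward(skip, x, train))
            x = np.concatenate([gated, x], axis=3)
            for layer in stage["convs"]:
                x = layer.forward(x, train)
        for layer in self.head:
            x = layer.forward(x, train)
        return x[..., 0]

    def backward(self, dprob: np.ndarray) -> None:
        dy = dprob[..., None]
        for layer in reversed(self.head):
            dy = layer.backward(dy)
        dskips = []
        for stage in reversed(self.dec):
            for layer in reversed(stage["convs"]):
                dy = layer.backward(dy)
            cskip = dy.shape[3] // 2
            dgated, dx = dy[..., :cskip], dy[..., cskip:]
            if stage["gate"] is None:
                dskip = dgated
            else:
                dskip, dg = stage["gate"].backward(dgated)
                dx = dx + dg
            dskips.append(dskip)
            dx = stage["upconv"].backward(dx)
            dy = stage["up"].backward(dx)
        for layer in reversed(self.bottleneck):
            dy = layer.backward(dy)
        for block, pool, dskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy) + dskip
            for layer in reversed(block):
                dy = layer.backward(dy)

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities, same spatial shape as the input crops."""
        return self.forward(crops, train=False)


def build_segmenter(config: SegmenterConfig) -> TNTSegmenter:
    """Construct the segmenter; pretrained encoders need an absent runtime."""
    if config.encoder == "resnet_pretrained":
        raise PretrainedUnavailableError(
            "the resnet_pretrained encoder needs a deep-learning runtime with "
            "ImageNet weights, which is not available in this installation; "
            "use encoder='small_encoder' instead")
    return TNTSegmenter(config)


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Hard Dice overlap 2|A∩B|/(|A|+|B|) between two binary masks."""
    a = np.asarray(pred_mask) > 0.5
    b = np.asarray(true_mask) > 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def train_segmenter(
    handle: TNTSegmenter,
    image_crops: np.ndarray,
    mask_crops: np.ndarray,
    config: Optional[SegmenterConfig] = None,
) -> Tuple[TNTSegmenter, Dict[str, List[float]]]:
    """Train the U-Net with the composite loss; returns (handle, history)."""
    config = config or handle.config
    x = _as_nhwc(image_crops)[..., 0]
    t = np.asarray(mask_crops, dtype=np.float32)
    if t.ndim == 2:
        t = t[None]
    if x.shape != t.shape:
        raise ValidationError(
            f"crop shape {x.shape} != mask shape {t.shape}")
    if x.shape[0] == 0:
        raise ValidationError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(handle.param_layers(), lr=config.learning_rate)
    history: Dict[str, List[float]] = {"loss": [], "dice": []}
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        inter = union = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb = x[idx], t[idx]
            p = handle.forward(xb, train=True)
            loss, grad = composite_loss(p, tb, config.loss_weights,
                                        return_grad=True)
            handle.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            hard = p >= 0.5
            inter += float((hard & (tb > 0.5)).sum())
            union += float(hard.sum() + (tb > 0.5).sum())
        history["loss"].append(epoch_loss / n)
        history["dice"].append(2.0 * inter / union if union else 1.0)
    return handle, history


def save_classifier(path: str, handle: TNTClassifier) -> None:
    """Write classifier weights (<path>.npz) and config snapshot (<path>.json)."""
    import dataclasses
    nn.save_params(path, handle.net.param_layers(),
                   {"kind": "classifier", **dataclasses.asdict(handle.config)})


def load_classifier(path: str) -> TNTClassifier:
    import dataclasses
    import json
    with open(path + ".json") as fh:
        meta = json.load(fh)
    meta.pop("kind", None)
    fields = {f.name for f in dataclasses.fields(ClassifierConfig)}
    meta = {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta.items() if k in fields}
    handle = TNTClassifier(ClassifierConfig(**meta))
    nn.load_params(path, handle.net.param_layers())
    return handle


def save_segmenter(path: str, handle: TNTSegmenter) -> None:
    """Write segmenter weights (<path>.npz) and config snapshot (<path>.json)."""
    import dataclasses
    nn.save_params(path, handle.param_layers(),
                   {"kind": "segmenter", **dataclasses.asdict(handle.config)})


def load_segmenter(path: str) -> TNTSegmenter:
    import dataclasses
    import json
    with open(path + ".json") as fh:
        meta = json.load(fh)
    meta.pop("kind", None)
    fields = {f.name for f in dataclasses.fields(SegmenterConfig)}
    meta = {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta.items() if k in fields}
    handle = TNTSegmenter(SegmenterConfig(**meta))
    nn.load_params(path, handle.param_layers())
    return handle


def predict_heatmap(handle: TNTSegmenter, patch: np.ndarray,
                    origin: Tuple[int, int] = (0, 0)) -> PatchHeatmap:
    """Run the segmenter on one patch and rescale to an 8-bit heatmap.

    Probabilities map to gray levels by ``round(p * 255)``; e.g. p=0.9216
    lands exactly on the counting threshold 235.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValidationError("patch must be a single 2D crop")
    p = handle.predict_proba(patch[None])[0]
    return PatchHeatmap(pixels=np.rint(p * 255).astype(np.uint8), origin=origin)
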