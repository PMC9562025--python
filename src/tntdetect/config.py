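"""Parameter sets for every pipeline stage, plus the global seed-splitting rule.

Every tunable the pipeline uses lives in one of the dataclasses below, so a
single :class:`PipelineConfig` (optionally loaded from YAML) fully determines
a run.  Defaults follow the published operating point of the method: sliding
windows of 512/256 px, 60% dropout, heatmap threshold 235, elliptical 5x5
kernel, contour area band 400-2500 px, Richardson-Lucy PSF 7x7 with sigma 20,
and an imaging resolution of 0.335 um/pixel (6.7 um camera pixels at 20x).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PhantomSpec",
    "ExpertErrorModel",
    "DeconvolutionParams",
    "PatchLabelRule",
    "ClassifierConfig",
    "SegmenterConfig",
    "DetectParams",
    "MatchCriterion",
    "PipelineConfig",
    "split_seed",
    "config_hash",
    "ConfigError",
]

#: Default physical resolution, um per pixel (20x objective, 6.7 um camera pixel).
DEFAULT_RESOLUTION_UM_PER_PX = 0.335

#: Fixed component indices used by :func:`split_seed`.  The global integer
#: seed expands to independent per-component streams through
#: ``np.random.SeedSequence(seed, spawn_key=(index,))``; the mapping below is
#: part of the reproducibility contract and must not be reordered.
SEED_COMPONENTS = {
    "phantom": 0,
    "experts": 1,
    "patching": 2,
    "classifier": 3,
    "segmenter": 4,
    "pipeline": 5,
    "evaluate": 6,
}


class ConfigError(ValueError):
    """Raised when a parameter set violates its invariants."""


def split_seed(seed: int, component: str) -> int:
    """Derive the per-component integer seed from the global seed.

    Deterministic and stable across runs/platforms; the returned value is
    always in ``[0, 2**31)`` so it is safe for any RNG constructor.
    """
    try:
        idx = SEED_COMPONENTS[component]
    except KeyError:
        raise ConfigError(
            f"unknown seed component {component!r}; known: {sorted(SEED_COMPONENTS)}"
        ) from None
    ss = np.random.SeedSequence(int(seed), spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _check_range(name: str, rng: Sequence[float], lo=None) -> None:
    _check(len(rng) == 2, f"{name} must be a (min, max) pair")
    _check(rng[0] <= rng[1], f"{name}: min {rng[0]} > max {rng[1]}")
    if lo is not None:
        _check(rng[0] >= lo, f"{name}: min {rng[0]} < {lo}")


@dataclass
class PhantomSpec:
    """Synthetic micrograph description.

    The phantom emulates sparse adherent cells imaged in phase contrast
    (bright rim, darker interior) at 30-40% confluence, connected by thin
    bright TNT lines (width <= 1 um, i.e. <= 3 px at 0.335 um/px; length
    10-100+ um), over a noisy background with optional smooth illumination
    gradient, per-tile stitching shadows and dish scratches.
    """

    image_height_px: int = 768
    image_width_px: int = 768
    n_cells: int = 20
    cell_radius_um_range: Tuple[float, float] = (8.0, 14.0)
    tnt_probability_per_cell_pair: float = 0.2
    tnt_width_px_range: Tuple[int, int] = (2, 3)
    tnt_length_um_range: Tuple[float, float] = (10.0, 100.0)
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    noise_sd: float = 0.03
    illumination_gradient_amplitude: float = 0.0
    tile_grid: Optional[Tuple[int, int]] = None
    tile_shadow_amplitude: float = 0.25
    n_scratches: int = 0
    # intensity levels (float image in [0, 1])
    background_level: float = 0.45
    cell_rim_level: float = 0.92
    cell_interior_level: float = 0.30
    tnt_level: float = 0.70
    scratch_level: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.image_height_px > 0 and self.image_width_px > 0,
               "image dimensions must be positive")
        _check(self.n_cells >= 0, "n_cells must be non-negative")
        _check_range("cell_radius_um_range", self.cell_radius_um_range, lo=0.0)
        _check(0.0 <= self.tnt_probability_per_cell_pair <= 1.0,
               "tnt_probability_per_cell_pair must be in [0,1]")
        _check_range("tnt_width_px_range", self.tnt_width_px_range, lo=1)
        _check_range("tnt_length_um_range", self.tnt_length_um_range, lo=0.0)
        _check(self.resolution_um_per_px > 0, "resolution must be positive")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.illumination_gradient_amplitude >= 0,
               "illumination_gradient_amplitude must be >= 0")
        _check(self.n_scratches >= 0, "n_scratches must be >= 0")
        # TNT definition: width strictly below 1 um at the stated resolution.
        max_width_px = int(np.ceil(1.0 / self.resolution_um_per_px))
        _check(self.tnt_width_px_range[1] <= max_width_px,
               f"TNT width {self.tnt_width_px_range[1]} px exceeds the 1 um "
               f"definition bound ({max_width_px} px at "
               f"{self.resolution_um_per_px} um/px)")

    @property
    def max_tnt_width_px(self) -> int:
        return int(np.ceil(1.0 / self.resolution_um_per_px))


@dataclass
class ExpertErrorModel:
    """Stochastic model of a human annotator marking TNT lines.

    Each expert independently misses each true line with probability
    ``miss_probability``, adds ``Poisson(false_mark_rate)`` spurious lines per
    image, and jitters retained endpoints by isotropic Gaussian noise of
    ``endpoint_jitter_px``.
    """

    miss_probability: float = 0.2
    false_mark_rate: float = 1.0
    endpoint_jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(0.0 <= self.miss_probability <= 1.0,
               "miss_probability must be in [0,1]")
        _check(self.false_mark_rate >= 0, "false_mark_rate must be >= 0")
        _check(self.endpoint_jitter_px >= 0, "endpoint_jitter_px must be >= 0")


@dataclass
class DeconvolutionParams:
    """Richardson-Lucy settings: truncated-Gaussian PSF and iteration count.

    sigma=20 over a 7x7 support makes the PSF nearly uniform on its support;
    it is built literally (truncate, then normalize to sum 1).
    """

    kernel_size: int = 7
    sigma: float = 20.0
    iterations: int = 30

    def __post_init__(self) -> None:
        _check(self.kernel_size > 0 and self.kernel_size % 2 == 1,
               "kernel_size must be an odd positive integer")
        _check(self.sigma > 0, "sigma must be > 0")
        _check(self.iterations >= 1, "iterations must be >= 1")


@dataclass
class PatchLabelRule:
    """Positive-labelling rule for a sliding window.

    A window is positive iff it contains at least ``min_tnt_pixels`` labelled
    TNT pixels AND their centroid falls inside the central square covering a
    ``center_fraction`` of the window side — so a TNT cut by the window edge
    does not label the window.
    """

    min_tnt_pixels: int = 50
    center_fraction: float = 0.5

    def __post_init__(self) -> None:
        _check(self.min_tnt_pixels >= 1, "min_tnt_pixels must be positive")
        _check(0.0 < self.center_fraction <= 1.0,
               "center_fraction must be in (0,1]")


@dataclass
class ClassifierConfig:
    """Patch classifier: a convolutional backbone with a 512/170/70 dense head.

    ``backbone='vgg16_pretrained'`` reproduces the transfer-learning setup
    (ImageNet-initialised convolutional stack) and requires the optional deep
    learning runtime; ``'small_cnn'`` is the self-contained backbone trained
    from scratch.  Dropout of ``dropout_rate`` sits between each pair of dense
    layers.
    """

    backbone: str = "small_cnn"
    head_sizes: Tuple[int, ...] = (512, 170, 70)
    dropout_rate: float = 0.6
    input_size: int = 512
    decision_threshold: float = 0.5
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    pool_to: int = 64  # small_cnn internal working resolution
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.backbone in ("vgg16_pretrained", "small_cnn"),
               f"unknown backbone {self.backbone!r}")
        _check(len(self.head_sizes) > 0, "head_sizes must be non-empty")
        _check(0.0 <= self.dropout_rate < 1.0, "dropout_rate must be in [0,1)")
        _check(0.0 < self.decision_threshold < 1.0,
               "decision_threshold must be in (0,1)")
        _check(self.input_size >= self.pool_to,
               "input_size must be >= pool_to")


@dataclass
class SegmenterConfig:
    """Attention U-Net segmenter configuration.

    The encoder halves spatial dimensions and doubles feature channels per
    level; the decoder mirrors it with 2x2 up-convolutions and skip
    connections, gated by additive attention when ``use_attention``.  The
    training loss is ``w_bce*BCE + w_dice*(1-Dice) + w_ac*AC`` with the active
    contour term combining boundary length and inside/outside region energies.
    """

    encoder: str = "small_encoder"
    use_attention: bool = True
    loss_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    depth: int = 2
    base_channels: int = 8
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    crop_size: int = 64
    n_train_crops: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.encoder in ("resnet_pretrained", "small_encoder"),
               f"unknown encoder {self.encoder!r}")
        _check(len(self.loss_weights) == 3, "loss_weights must be (w_bce, w_dice, w_ac)")
        _check(all(w >= 0 for w in self.loss_weights),
               "loss weights must be >= 0")
        _check(any(w > 0 for w in self.loss_weights),
               "at least one loss weight must be > 0")
        _check(self.depth >= 1, "depth must be >= 1")


@dataclass
class DetectParams:
    """TNT counting parameters (heatmap threshold, kernel, area band)."""

    intensity_threshold: int = 235
    kernel_size: Tuple[int, int] = (5, 5)
    area_min_px: float = 400.0
    area_max_px: float = 2500.0
    overlap_reduction: str = "max"
    close_gaps: bool = False  # optional gap-closing dilation, off by default

    def __post_init__(self) -> None:
        _check(0 <= self.intensity_threshold <= 255,
               "intensity_threshold must be in [0,255]")
        _check(self.area_min_px < self.area_max_px,
               "area_min_px must be < area_max_px")
        _check(self.overlap_reduction in ("max", "mean"),
               "overlap_reduction must be 'max' or 'mean'")


@dataclass
class MatchCriterion:
    """Prediction-to-truth matching rule used when scoring detections.

    A predicted structure is a true positive when at least ``min_fraction``
    of its pixels lie within ``distance_px`` of a not-yet-matched true line.
    """

    min_fraction: float = 0.3
    distance_px: float = 5.0

    def __post_init__(self) -> None:
        _check(0.0 < self.min_fraction <= 1.0, "min_fraction must be in (0,1]")
        _check(self.distance_px > 0, "distance_px must be > 0")


# ----------------------------------------------------------------------------
# Whole-pipeline configuration


@dataclass
class PipelineConfig:
    """Nested configuration for the full synth -> count -> evaluate pipeline."""

    seed: int = 0
    out_dir: str = "tntdetect_run"
    verbosity: int = 1
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    # label chain default: a single RL iteration (unsharp-mask regime); see
    # preprocess.LABEL_CHAIN_DECONVOLUTION
    deconvolution: DeconvolutionParams = field(
        default_factory=lambda: DeconvolutionParams(iterations=1))
    patch_rule: PatchLabelRule = field(default_factory=PatchLabelRule)
    coarse_size: int = 512
    fine_size: int = 256
    stride: int = 64
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    detect: DetectParams = field(default_factory=DetectParams)
    match: MatchCriterion = field(default_factory=MatchCriterion)

    _SECTIONS = {
        "phantom": PhantomSpec,
        "deconvolution": DeconvolutionParams,
        "patch_rule": PatchLabelRule,
        "classifier": ClassifierConfig,
        "segmenter": SegmenterConfig,
        "detect": DetectParams,
        "match": MatchCriterion,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a (YAML-loaded) nested dict; unknown keys are rejected."""
        data = dict(data or {})
        kwargs = {}
        scalar_fields = {f.name for f in dataclasses.fields(cls)} - set(cls._SECTIONS)
        for key in list(data):
            if key in cls._SECTIONS:
                section = data.pop(key) or {}
                section_cls = cls._SECTIONS[key]
                known = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(section) - known
                _check(not unknown,
                       f"unknown keys in section {key!r}: {sorted(unknown)}")
                sec = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in section.items()}
                kwargs[key] = section_cls(**sec)
            elif key in scalar_fields:
                kwargs[key] = data.pop(key)
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg) -> str:
    """Short stable hash of a (dataclass) configuration, for output stamping."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        payload = dataclasses.asdict(cfg)
    else:
        payload = cfg
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
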