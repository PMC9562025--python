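"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["MicrographImage", "BinaryMask", "TNTLine", "PhantomTruth", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates an operation's precondition."""


@dataclass
class MicrographImage:
    """A 2D grayscale micrograph with physical-resolution and tile metadata.

    ``pixels`` is either 8-bit (0-255) or float in [0,1].  ``tile_grid``
    describes the stitched acquisition as (rows, cols, tile_h, tile_w); when
    omitted the image is treated as a single untiled field.
    """

    pixels: np.ndarray
    resolution_um_per_px: float = 0.335
    tile_grid: Optional[Tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"image must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels.astype(np.float64))):
            raise ValidationError("image pixels must be finite")
        if self.resolution_um_per_px <= 0:
            raise ValidationError("resolution must be positive")
        if self.tile_grid is not None:
            rows, cols, th, tw = self.tile_grid
            h, w = self.pixels.shape
            if rows * th < h - th or cols * tw < w - tw:
                raise ValidationError("tile grid does not cover the image")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        """Pixels as float64 in [0,1] regardless of storage dtype."""
        if np.issubdtype(self.pixels.dtype, np.integer):
            return self.pixels.astype(np.float64) / 255.0
        return self.pixels.astype(np.float64)

    def as_uint8(self) -> np.ndarray:
        if np.issubdtype(self.pixels.dtype, np.integer):
            return self.pixels.astype(np.uint8)
        return np.rint(np.clip(self.pixels, 0.0, 1.0) * 255).astype(np.uint8)


@dataclass
class BinaryMask:
    """A {0,1} pixel mask aligned to an image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError(f"mask must be 2D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be in {0,1}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def check_matches(self, other_shape: Tuple[int, int]) -> None:
        if tuple(self.shape) != tuple(other_shape):
            raise ValidationError(
                f"mask shape {self.shape} does not match image shape {other_shape}")


@dataclass
class TNTLine:
    """A TNT annotation: polyline vertices (k,2) in (row, col) plus width."""

    vertices: np.ndarray
    width_px: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValidationError("polyline needs at least 2 (row,col) vertices")
        self.vertices = v

    @property
    def endpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.vertices[0], self.vertices[-1]

    @property
    def midpoint(self) -> np.ndarray:
        """Midpoint by arc length along the polyline."""
        v = self.vertices
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        total = float(seg.sum())
        if total == 0:
            return v[0]
        half = total / 2.0
        acc = 0.0
        for i, s in enumerate(seg):
            if acc + s >= half:
                t = (half - acc) / s if s > 0 else 0.0
                return v[i] + t * (v[i + 1] - v[i])
            acc += s
        return v[-1]

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


@dataclass
class PhantomTruth:
    """Exact ground truth attached to a synthetic micrograph."""

    cell_mask: np.ndarray
    tnt_lines: List[TNTLine] = field(default_factory=list)
    tnt_mask: Optional[BinaryMask] = None

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.max())

    @property
    def n_tnts(self) -> int:
        return len(self.tnt_lines)
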