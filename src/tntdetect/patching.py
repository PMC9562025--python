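"""Hierarchical sliding-window patch extraction and labelling.

A full micrograph is scanned with a coarse window (512 px, stride 10 at the
published operating point) and each window is labelled positive when it holds
enough labelled TNT pixels *and* their centroid sits near the window center —
so a TNT split across adjacent windows does not produce a misleading positive.
Positive coarse windows are re-scanned at a fine scale (256 px), producing the
two training sets for the two classifier instances and the crops the
segmenter trains on.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PatchLabelRule
from .types import BinaryMask, MicrographImage, ValidationError

__all__ = [
    "PatchRecord",
    "slide_windows",
    "label_patch",
    "extract_hierarchical",
    "balance_patches",
    "thin_positives",
    "save_patch_dataset",
]


@dataclass
class PatchRecord:
    """One window: origin, side length, hierarchy level and its label."""

    origin: Tuple[int, int]
    size: int
    level: str  # "coarse" | "fine"
    label: Optional[int] = None
    parent: Optional[Tuple[int, int]] = None  # origin of enclosing coarse patch

    def slices(self) -> Tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.size), slice(c, c + self.size)


def slide_windows(image_shape: Tuple[int, int], size: int,
                  stride: int) -> List[Tuple[int, int]]:
    """All window origins on a stride grid, fully inside the image.

    Origins are multiples of ``stride`` with ``origin + size <= bound``,
    enumerated in row-major order; the count is
    ``(floor((H-size)/stride)+1) * (floor((W-size)/stride)+1)``.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    h, w = image_shape
    if size > h or size > w:
        warnings.warn(f"window size {size} exceeds image shape {image_shape}; "
                      "no windows generated", stacklevel=2)
        return []
    rows = range(0, h - size + 1, stride)
    cols = range(0, w - size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def label_patch(mask_window: BinaryMask, rule: PatchLabelRule) -> int:
    """Apply the positive-labelling rule to one mask window.

    Returns 1 iff the window holds at least ``rule.min_tnt_pixels`` set pixels
    and their centroid lies inside the central square of side
    ``rule.center_fraction * size``.
    """
    pix = mask_window.pixels
    if pix.shape[0] != pix.shape[1]:
        raise ValidationError("patch mask must be square")
    size = pix.shape[0]
    rr, cc = np.nonzero(pix)
    if len(rr) < rule.min_tnt_pixels:
        return 0
    centroid = (rr.mean(), cc.mean())
    half_span = rule.center_fraction * size / 2.0
    center = (size - 1) / 2.0
    inside = (abs(centroid[0] - center) <= half_span
              and abs(centroid[1] - center) <= half_span)
    return int(inside)


def extract_hierarchical(
    image: MicrographImage,
    mask: BinaryMask,
    coarse_size: int = 512,
    fine_size: int = 256,
    stride: int = 10,
    rule: Optional[PatchLabelRule] = None,
    fine_rule: Optional[PatchLabelRule] = None,
    fine_stride: Optional[int] = None,
) -> Tuple[List[PatchRecord], List[PatchRecord]]:
    """Scan coarse windows everywhere, fine windows only inside coarse positives.

    Both levels are labelled with the same rule shape (``fine_rule`` defaults
    to half the coarse pixel minimum).  Fine origins are absolute image
    coordinates; duplicates arising from overlapping coarse parents are kept
    once (first parent wins).
    """
    mask.check_matches(image.shape)
    rule = rule or PatchLabelRule()
    fine_rule = fine_rule or PatchLabelRule(
        min_tnt_pixels=max(1, rule.min_tnt_pixels // 2),
        center_fraction=rule.center_fraction)
    fine_stride = fine_stride if fine_stride is not None else stride

    coarse: List[PatchRecord] = []
    for origin in slide_windows(image.shape, coarse_size, stride):
        rec = PatchRecord(origin=origin, size=coarse_size, level="coarse")
        rs, cs = rec.slices()
        rec.label = label_patch(BinaryMask(mask.pixels[rs, cs]), rule)
        coarse.append(rec)

    fine: List[PatchRecord] = []
    seen = set()
    for parent in coarse:
        if parent.label != 1:
            continue
        pr, pc = parent.origin
        sub_shape = (coarse_size, coarse_size)
        for (r, c) in slide_windows(sub_shape, fine_size, fine_stride):
            origin = (pr + r, pc + c)
            if origin in seen:
                continue
            seen.add(origin)
            rec = PatchRecord(origin=origin, size=fine_size, level="fine",
                              parent=parent.origin)
            rs, cs = rec.slices()
            rec.label = label_patch(BinaryMask(mask.pixels[rs, cs]), fine_rule)
            fine.append(rec)
    return coarse, fine


def balance_patches(records: Sequence[PatchRecord], ratio: float = 1.0,
                    seed: int = 0) -> List[PatchRecord]:
    """Subsample negatives to ``ratio`` negatives per positive.

    All positives are kept.  With no positives, up to ``int(ratio)`` negatives
    are returned so training never sees an empty set silently.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    rng = np.random.default_rng(seed)
    n_neg = int(round(ratio * max(len(pos), 1)))
    if len(neg) > n_neg:
        idx = rng.choice(len(neg), size=n_neg, replace=False)
        neg = [neg[i] for i in sorted(idx)]
    return pos + neg


def thin_positives(records: Sequence[PatchRecord],
                   min_separation: Optional[int] = None) -> List[PatchRecord]:
    """Optional non-max thinning of near-duplicate positive windows.

    Dense strides produce stacks of positives whose origins differ by a few
    pixels.  Positives closer than ``min_separation`` (Chebyshev distance;
    default: the window stride is unknown here, so half the window side) to
    an already-kept positive are dropped; negatives pass through untouched.
    """
    kept: List[PatchRecord] = []
    out: List[PatchRecord] = []
    for rec in records:
        if rec.label != 1:
            out.append(rec)
            continue
        sep = min_separation if min_separation is not None else rec.size // 2
        close = any(max(abs(rec.origin[0] - k.origin[0]),
                        abs(rec.origin[1] - k.origin[1])) < sep
                    for k in kept)
        if not close:
            kept.append(rec)
            out.append(rec)
    return out


def patch_pixels(image: MicrographImage, record: PatchRecord) -> np.ndarray:
    """Float [0,1] crop of the image under a patch record."""
    rs, cs = record.slices()
    return image.as_float()[rs, cs]


def save_patch_dataset(out_dir: str, image: MicrographImage, mask: BinaryMask,
                       records: Sequence[PatchRecord]) -> pd.DataFrame:
    """Write PNG crops plus a manifest CSV; returns the manifest frame."""
    import imageio.v3 as iio
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    img8 = image.as_uint8()
    for i, rec in enumerate(records):
        rs, cs = rec.slices()
        patch_id = f"{rec.level}_{i:05d}"
        iio.imwrite(os.path.join(out_dir, f"{patch_id}.png"), img8[rs, cs])
        iio.imwrite(os.path.join(out_dir, f"{patch_id}_mask.png"),
                    (mask.pixels[rs, cs] * 255).astype(np.uint8))
        rows.append({
            "patch_id": patch_id,
            "origin_row": rec.origin[0], "origin_col": rec.origin[1],
            "size": rec.size, "level": rec.level, "label": rec.label,
            "parent_id": "" if rec.parent is None else f"{rec.parent[0]}_{rec.parent[1]}",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
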