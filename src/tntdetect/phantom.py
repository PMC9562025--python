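"""Synthetic phase-contrast phantom generator with exact ground truth.

The phantom stylizes what the detection pipeline actually exploits in real
phase-contrast micrographs of adherent cultures at 30-40% confluence: cells
appear as bright-rimmed ellipses with darker interiors on a noisy mid-gray
background, and TNTs as thin (<=3 px ~ <1 um) straight-to-angular bright lines
spanning the intercellular gap, attached to the cell boundary with a narrow
(tapered) base.  Confounders that real dishes contribute — uneven
illumination, per-tile stitching shadows and long plastic scratches — can be
switched on individually.  Every image comes with its exact cell label mask,
the TNT polyline list and the rasterized TNT pixel mask, plus (optionally)
simulated noisy expert annotations, so downstream stages are testable without
any acquired data.
"""

from __future__ import annotations

import json
import os
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

from .config import ConfigError, ExpertErrorModel, PhantomSpec
from .types import BinaryMask, MicrographImage, PhantomTruth, TNTLine

__all__ = [
    "generate_phantom",
    "simulate_expert_marks",
    "rasterize_polylines",
    "distance_to_polyline",
    "tile_shadow_field",
    "save_phantom",
    "load_phantom",
]


# ----------------------------------------------------------------------------
# Geometry helpers


def distance_to_polyline(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point (n,2) to a polyline (k,2).

    Exact point-to-segment distances, minimized over segments.
    """
    points = np.asarray(points, dtype=np.float64)
    vertices = np.asarray(vertices, dtype=np.float64)
    best = np.full(len(points), np.inf)
    for a, b in zip(vertices[:-1], vertices[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(points - proj, axis=1)
        np.minimum(best, d, out=best)
    return best


def rasterize_polylines(
    shape: Tuple[int, int],
    lines: Sequence[TNTLine],
    taper_px: float = 3.0,
    taper_width_px: float = 2.0,
) -> BinaryMask:
    """Rasterize polylines at their stated widths into a binary mask.

    A pixel is set iff its center lies within ``width/2`` of the polyline.
    Within ``taper_px`` of either endpoint the effective width narrows to
    ``min(width, taper_width_px)``, giving the narrow base at the cell
    membrane.  Computed with exact point-to-segment distances on a local
    bounding box per line.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for line in lines:
        half = line.width_px / 2.0
        v = line.vertices
        r0 = max(int(np.floor(v[:, 0].min() - half - 1)), 0)
        r1 = min(int(np.ceil(v[:, 0].max() + half + 1)) + 1, h)
        c0 = max(int(np.floor(v[:, 1].min() - half - 1)), 0)
        c1 = min(int(np.ceil(v[:, 1].max() + half + 1)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
        d = distance_to_polyline(pts, v)
        hit = d <= half
        if taper_px > 0 and line.width_px > taper_width_px:
            d_end = np.minimum(
                np.linalg.norm(pts - v[0], axis=1),
                np.linalg.norm(pts - v[-1], axis=1),
            )
            near_base = d_end <= taper_px
            hit &= ~(near_base & (d > taper_width_px / 2.0))
        sub = mask[r0:r1, c0:c1].ravel()
        sub[hit] = 1
        mask[r0:r1, c0:c1] = sub.reshape(r1 - r0, c1 - c0)
    return BinaryMask(mask)


def tile_shadow_field(
    shape: Tuple[int, int], tile_grid: Tuple[int, int], amplitude: float
) -> np.ndarray:
    """Multiplicative per-tile shading field, darkest at tile edges/corners.

    Each tile carries a smooth quadratic vignette ``1 - a*((2u-1)^2+(2v-1)^2)/2``
    flipped so the *edges* darken (stitching shadows): the field is 1 at the
    tile center and ``1 - amplitude`` at the corners.
    """
    h, w = shape
    rows, cols = tile_grid
    th = int(np.ceil(h / rows))
    tw = int(np.ceil(w / cols))
    u = (np.arange(h) % th + 0.5) / th  # position within tile, (0,1)
    v = (np.arange(w) % tw + 0.5) / tw
    fu = (2.0 * u - 1.0) ** 2
    fv = (2.0 * v - 1.0) ** 2
    field = 1.0 - amplitude * (fu[:, None] + fv[None, :]) / 2.0
    return field


# ----------------------------------------------------------------------------
# Cell placement


def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping ellipses; returns the label image."""
    h, w = spec.image_height_px, spec.image_width_px
    px = spec.resolution_um_per_px
    r_lo, r_hi = (r / px for r in spec.cell_radius_um_range)
    label = np.zeros((h, w), dtype=np.int32)
    placed = 0
    attempts = 0
    max_attempts = max(200, spec.n_cells * 60)
    gap = 4  # minimum pixel gap between cells
    while placed < spec.n_cells and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(0.6 * a, a)
        cy = rng.uniform(a + 2, h - a - 2)
        cx = rng.uniform(a + 2, w - a - 2)
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, a + gap, b + gap, shape=(h, w), rotation=theta)
        if np.any(label[rr, cc] > 0):
            continue
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        placed += 1
        label[rr, cc] = placed
    return label


def _cell_boundary_point(label: np.ndarray, cell_id: int, center: np.ndarray,
                         toward: np.ndarray) -> np.ndarray:
    """March from a cell's center toward a target; return the last point inside.

    The returned point lies on (within 1 px of) the cell boundary.
    """
    h, w = label.shape
    direction = toward - center
    norm = np.linalg.norm(direction)
    if norm == 0:
        return center.copy()
    direction = direction / norm
    last_inside = center.copy()
    for step in np.arange(0.0, norm, 0.5):
        p = center + step * direction
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < h and 0 <= c < w):
            break
        if label[r, c] == cell_id:
            last_inside = p
        elif label[r, c] != cell_id and np.linalg.norm(p - center) > 1:
            break
    return last_inside


def _centers(label: np.ndarray) -> np.ndarray:
    n = int(label.max())
    out = np.zeros((n, 2))
    for i in range(1, n + 1):
        rr, cc = np.nonzero(label == i)
        out[i - 1] = (rr.mean(), cc.mean())
    return out


def _path_crosses_other_cell(label: np.ndarray, vertices: np.ndarray,
                             exclude: Tuple[int, int]) -> bool:
    for a, b in zip(vertices[:-1], vertices[1:]):
        n = max(int(np.linalg.norm(b - a) * 2), 2)
        for t in np.linspace(0, 1, n):
            p = a + t * (b - a)
            r, c = int(round(p[0])), int(round(p[1]))
            if 0 <= r < label.shape[0] and 0 <= c < label.shape[1]:
                v = label[r, c]
                if v > 0 and v not in exclude:
                    return True
    return False


def _sample_tnts(spec: PhantomSpec, label: np.ndarray,
                 rng: np.random.Generator) -> List[TNTLine]:
    n = int(label.max())
    if n < 2 or spec.tnt_probability_per_cell_pair == 0:
        return []
    px = spec.resolution_um_per_px
    l_lo, l_hi = (l / px for l in spec.tnt_length_um_range)
    centers = _centers(label)
    lines: List[TNTLine] = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() >= spec.tnt_probability_per_cell_pair:
                continue
            p_i = _cell_boundary_point(label, i + 1, centers[i], centers[j])
            p_j = _cell_boundary_point(label, j + 1, centers[j], centers[i])
            gap = np.linalg.norm(p_j - p_i)
            if not (l_lo <= gap <= l_hi):
                continue
            width = int(rng.integers(spec.tnt_width_px_range[0],
                                     spec.tnt_width_px_range[1] + 1))
            vertices = np.array([p_i, p_j])
            # occasionally angular: bend at the midpoint, never sinusoidal
            if rng.random() < 0.3:
                mid = (p_i + p_j) / 2.0
                d = (p_j - p_i) / gap
                perp = np.array([-d[1], d[0]])
                offset = rng.uniform(-0.15, 0.15) * gap
                bent = mid + offset * perp
                cand = np.array([p_i, bent, p_j])
                if not _path_crosses_other_cell(label, cand, (i + 1, j + 1)):
                    vertices = cand
            if _path_crosses_other_cell(label, vertices, (i + 1, j + 1)):
                continue
            lines.append(TNTLine(vertices=vertices, width_px=width))
    return lines


# ----------------------------------------------------------------------------
# Image composition


def _compose_image(spec: PhantomSpec, label: np.ndarray, tnt_mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = label.shape
    img = np.full((h, w), spec.background_level, dtype=np.float64)

    if spec.illumination_gradient_amplitude > 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(angle) * (yy / max(h - 1, 1) - 0.5)
                + np.sin(angle) * (xx / max(w - 1, 1) - 0.5))
        img *= 1.0 + spec.illumination_gradient_amplitude * ramp

    # scratches first: long faint straight lines crossing the whole image,
    # width 1-2 px, deliberately confusable with TNTs
    for _ in range(spec.n_scratches):
        angle = rng.uniform(0, np.pi)
        d = np.array([np.sin(angle), np.cos(angle)])
        p0 = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        span = float(np.hypot(h, w))
        line = TNTLine(np.array([p0 - span * d, p0 + span * d]),
                       width_px=float(rng.integers(1, 3)))
        m = rasterize_polylines((h, w), [line], taper_px=0.0).pixels
        img[m == 1] = spec.scratch_level

    # cells: darker interior, bright rim (phase-contrast stylization)
    interior = label > 0
    img[interior] = spec.cell_interior_level
    from scipy import ndimage as ndi
    eroded = ndi.binary_erosion(interior, iterations=2)
    rim = interior & ~eroded
    img[rim] = spec.cell_rim_level

    # TNT lines at intensity intermediate between background and cell rim
    img[tnt_mask == 1] = spec.tnt_level

    if spec.tile_grid is not None:
        img *= tile_shadow_field((h, w), spec.tile_grid,
                                 spec.tile_shadow_amplitude)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))

    return np.rint(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> Tuple[MicrographImage, PhantomTruth]:
    """Generate one synthetic micrograph and its exact ground truth.

    Deterministic: the same spec (including seed) yields bit-identical output.
    """
    if not isinstance(spec, PhantomSpec):
        raise ConfigError("spec must be a PhantomSpec")
    rng = np.random.default_rng(spec.seed)
    label = _place_cells(spec, rng)
    lines = _sample_tnts(spec, label, rng)
    tnt_mask = rasterize_polylines((spec.image_height_px, spec.image_width_px), lines)
    pixels = _compose_image(spec, label, tnt_mask.pixels, rng)
    tile_grid = None
    if spec.tile_grid is not None:
        rows, cols = spec.tile_grid
        tile_grid = (rows, cols,
                     int(np.ceil(spec.image_height_px / rows)),
                     int(np.ceil(spec.image_width_px / cols)))
    image = MicrographImage(pixels=pixels,
                            resolution_um_per_px=spec.resolution_um_per_px,
                            tile_grid=tile_grid)
    truth = PhantomTruth(cell_mask=label, tnt_lines=lines, tnt_mask=tnt_mask)
    return image, truth


# ----------------------------------------------------------------------------
# Simulated expert annotation


def simulate_expert_marks(
    truth: PhantomTruth,
    model: ExpertErrorModel,
    n_experts: int,
    image_shape: Tuple[int, int] | None = None,
) -> List[List[TNTLine]]:
    """Simulate noisy per-expert line annotations of the true TNT set.

    Each expert keeps each true line with probability ``1 - miss_probability``,
    jitters every vertex of kept lines by isotropic Gaussian noise, and adds
    ``Poisson(false_mark_rate)`` spurious straight lines.
    """
    if n_experts < 1:
        raise ConfigError("n_experts must be >= 1")
    if image_shape is None:
        image_shape = truth.cell_mask.shape
    h, w = image_shape
    out: List[List[TNTLine]] = []
    for e in range(n_experts):
        seed = np.random.SeedSequence(model.seed, spawn_key=(e,))
        rng = np.random.default_rng(seed)
        marks: List[TNTLine] = []
        for line in truth.tnt_lines:
            if rng.random() < model.miss_probability:
                continue
            v = line.vertices.copy()
            if model.endpoint_jitter_px > 0:
                v = v + rng.normal(0.0, model.endpoint_jitter_px, size=v.shape)
            marks.append(TNTLine(vertices=v, width_px=line.width_px))
        n_false = rng.poisson(model.false_mark_rate)
        for _ in range(n_false):
            mid = np.array([rng.uniform(0, h), rng.uniform(0, w)])
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(30, 150)
            d = np.array([np.sin(angle), np.cos(angle)]) * length / 2.0
            marks.append(TNTLine(np.array([mid - d, mid + d]), width_px=2.0))
        out.append(marks)
    return out


# ----------------------------------------------------------------------------
# Disk I/O (all plain formats: TIFF images, CSV lines, JSON spec)


def save_phantom(out_dir: str, image: MicrographImage, truth: PhantomTruth,
                 spec: PhantomSpec) -> None:
    """Write the phantom artifact set: image, cell labels, mask, lines, spec."""
    os.makedirs(out_dir, exist_ok=True)
    tifffile.imwrite(os.path.join(out_dir, "image.tif"), image.as_uint8())
    tifffile.imwrite(os.path.join(out_dir, "cells.tif"),
                     truth.cell_mask.astype(np.uint16))
    tifffile.imwrite(os.path.join(out_dir, "tnt_mask.tif"),
                     (truth.tnt_mask.pixels * 255).astype(np.uint8))
    rows = []
    for tnt_id, line in enumerate(truth.tnt_lines):
        for k, (r, c) in enumerate(line.vertices):
            rows.append({"tnt_id": tnt_id, "vertex_index": k,
                         "row": r, "col": c, "width_px": line.width_px})
    pd.DataFrame(rows, columns=["tnt_id", "vertex_index", "row", "col",
                                "width_px"]).to_csv(
        os.path.join(out_dir, "tnt_lines.csv"), index=False)
    import dataclasses
    with open(os.path.join(out_dir, "spec.json"), "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, default=str)


def load_phantom(out_dir: str) -> Tuple[MicrographImage, PhantomTruth, PhantomSpec]:
    """Read back a phantom written by :func:`save_phantom`."""
    with open(os.path.join(out_dir, "spec.json")) as fh:
        raw = json.load(fh)
    for key in ("cell_radius_um_range", "tnt_width_px_range",
                "tnt_length_um_range", "tile_grid"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    spec = PhantomSpec(**raw)
    pixels = tifffile.imread(os.path.join(out_dir, "image.tif"))
    cells = tifffile.imread(os.path.join(out_dir, "cells.tif")).astype(np.int32)
    tnt = tifffile.imread(os.path.join(out_dir, "tnt_mask.tif"))
    df = pd.read_csv(os.path.join(out_dir, "tnt_lines.csv"))
    lines = []
    for tnt_id, grp in df.groupby("tnt_id"):
        grp = grp.sort_values("vertex_index")
        lines.append(TNTLine(vertices=grp[["row", "col"]].to_numpy(),
                             width_px=float(grp["width_px"].iloc[0])))
    tile_grid = None
    if spec.tile_grid is not None:
        rows_, cols_ = spec.tile_grid
        tile_grid = (rows_, cols_, int(np.ceil(pixels.shape[0] / rows_)),
                     int(np.ceil(pixels.shape[1] / cols_)))
    image = MicrographImage(pixels=pixels,
                            resolution_um_per_px=spec.resolution_um_per_px,
                            tile_grid=tile_grid)
    truth = PhantomTruth(cell_mask=cells, tnt_lines=lines,
                         tnt_mask=BinaryMask((tnt > 127).astype(np.uint8)))
    return image, truth, spec
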