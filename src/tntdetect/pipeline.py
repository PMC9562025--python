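"""End-to-end orchestration: synth -> labels -> patches -> train -> count -> score.

``run_pipeline`` composes the individually invokable stage functions below,
so a driver (or test) can run any prefix of the pipeline and obtain the same
artifacts.  Every stage draws its randomness from the global seed through the
fixed component-splitting rule in :mod:`tntdetect.config`, and every written
artifact is stamped with the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from . import detect, evaluate, models, patching, phantom, preprocess
from .config import (ClassifierConfig, DetectParams, PipelineConfig,
                     SegmenterConfig, config_hash, split_seed)
from .types import BinaryMask, MicrographImage, PhantomTruth

__all__ = [
    "PipelineResult", "run_pipeline", "desk_scale_config",
    "stage_synth", "stage_labels", "stage_patches", "stage_train",
    "stage_predict", "stage_count", "stage_score", "sample_training_crops",
]

logger = logging.getLogger("tntdetect")


def _setup_logging(out_dir: Optional[str], verbosity: int) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG)
    handlers: List[logging.Handler] = [logging.StreamHandler()]
    if out_dir:
        handlers.append(logging.FileHandler(os.path.join(out_dir, "run.log")))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    tcr: detect.TCRReport
    metrics: evaluate.DetectionMetrics
    detections: List[detect.TNTDetection]
    heatmap: detect.Heatmap
    label_mask: BinaryMask
    n_coarse: int
    n_fine: int
    config_hash: str
    seed: int


def desk_scale_config(seed: int = 1, out_dir: str = "tntdetect_run") -> PipelineConfig:
    """The desk-scale end-to-end study condition.

    An easy 768x768 phantom — 20 cells, ~8 high-contrast TNTs of 30-70 um
    (lengths whose gradient-outline contour areas sit comfortably inside the
    400-2500 px counting band), no scratches, tiles or illumination gradient —
    processed with the self-contained model tier at sizes that train in
    minutes on one CPU: sliding-window stride 64, classifier 30 epochs,
    segmenter 120 epochs on 64 crops of 64 px.
    """
    from .config import PhantomSpec  # local import keeps module load light
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        phantom=PhantomSpec(
            image_height_px=768, image_width_px=768, n_cells=20,
            tnt_probability_per_cell_pair=0.3,
            tnt_length_um_range=(30.0, 60.0),
            noise_sd=0.02, n_scratches=0),
        stride=64,
        classifier=ClassifierConfig(epochs=40, learning_rate=1e-3),
        segmenter=SegmenterConfig(epochs=120, n_train_crops=96),
        detect=DetectParams(close_gaps=True),
    )


# ----------------------------------------------------------------------------
# Stages


def stage_synth(config: PipelineConfig) -> Tuple[MicrographImage, PhantomTruth]:
    """Generate the phantom with the pipeline-derived phantom seed."""
    spec = dataclasses.replace(config.phantom,
                               seed=split_seed(config.seed, "phantom"))
    image, truth = phantom.generate_phantom(spec)
    logger.info("synth: %dx%d image, %d cells, %d TNTs",
                *image.shape, truth.n_cells, truth.n_tnts)
    return image, truth


def stage_labels(config: PipelineConfig, image: MicrographImage,
                 truth: PhantomTruth) -> Tuple[MicrographImage, BinaryMask]:
    """Shading correction (when tiled) and the label-correction chain.

    The manual full-width inking step is emulated from the true line list,
    so the produced mask is what an annotator following the protocol would
    have obtained.
    """
    if image.tile_grid is not None:
        image = preprocess.correct_shading(image)
        logger.info("labels: tile shading corrected")
    detail = preprocess.detail_image(image, config.deconvolution)
    unmarked = preprocess.binarize_detail(detail)
    marked = preprocess.ink_marks(unmarked, truth.tnt_lines, margin_px=2.0)
    mask = preprocess.make_label_mask(
        image, MicrographImage(marked.pixels,
                               resolution_um_per_px=image.resolution_um_per_px),
        config.deconvolution)
    logger.info("labels: %d TNT-labelled pixels", int(mask.pixels.sum()))
    return image, mask


def stage_patches(config: PipelineConfig, image: MicrographImage,
                  mask: BinaryMask):
    """Hierarchical window extraction at the configured sizes and stride."""
    coarse, fine = patching.extract_hierarchical(
        image, mask, coarse_size=config.coarse_size,
        fine_size=config.fine_size, stride=config.stride,
        rule=config.patch_rule)
    n_pos = sum(r.label for r in fine)
    logger.info("patches: %d coarse (%d pos), %d fine (%d pos)",
                len(coarse), sum(r.label for r in coarse), len(fine), n_pos)
    return coarse, fine


def sample_training_crops(
    image: MicrographImage, mask: BinaryMask,
    records: Sequence[patching.PatchRecord],
    crop_size: int, n_crops: int, seed: int,
    positive_fraction: float = 0.75,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample square training crops for the segmenter.

    Positive crops center on a labelled TNT pixel inside a positive patch;
    negative crops are windows free of labelled pixels.  Returns
    (crops, mask_crops) as float arrays in [0,1] / {0,1}.
    """
    rng = np.random.default_rng(seed)
    img = image.as_float()
    h, w = img.shape
    half = crop_size // 2
    pos_pixels = []
    for rec in records:
        if rec.label != 1:
            continue
        rs, cs = rec.slices()
        rr, cc = np.nonzero(mask.pixels[rs, cs])
        pos_pixels.extend(zip(rr + rs.start, cc + cs.start))
    crops, targets = [], []
    n_pos = int(round(n_crops * positive_fraction)) if pos_pixels else 0
    for _ in range(n_pos):
        r, c = pos_pixels[rng.integers(len(pos_pixels))]
        r = int(np.clip(r - half + rng.integers(-half // 2, half // 2 + 1),
                        0, h - crop_size))
        c = int(np.clip(c - half + rng.integers(-half // 2, half // 2 + 1),
                        0, w - crop_size))
        crops.append(img[r:r + crop_size, c:c + crop_size])
        targets.append(mask.pixels[r:r + crop_size, c:c + crop_size])
    tries = 0
    while len(crops) < n_crops and tries < n_crops * 20:
        tries += 1
        r = int(rng.integers(0, h - crop_size + 1))
        c = int(rng.integers(0, w - crop_size + 1))
        m = mask.pixels[r:r + crop_size, c:c + crop_size]
        if n_pos and m.sum() > 0:
            continue
        crops.append(img[r:r + crop_size, c:c + crop_size])
        targets.append(m)
    return (np.stack(crops).astype(np.float32),
            np.stack(targets).astype(np.float32))


def stage_train(config: PipelineConfig, image: MicrographImage,
                mask: BinaryMask, fine_records) -> Tuple[
                    models.TNTClassifier, models.TNTSegmenter]:
    """Train the fine-scale patch classifier and the segmenter."""
    t0 = time.time()
    cls_cfg = dataclasses.replace(config.classifier,
                                  input_size=config.fine_size,
                                  seed=split_seed(config.seed, "classifier"))
    balanced = patching.balance_patches(
        fine_records, ratio=1.0, seed=split_seed(config.seed, "patching"))
    x = np.stack([patching.patch_pixels(image, r) for r in balanced])
    y = np.array([r.label for r in balanced])
    classifier = models.build_classifier(cls_cfg)
    classifier, cls_hist = models.train_classifier(classifier, x, y, cls_cfg)
    logger.info("train: classifier %d patches, final acc %.3f (%.1fs)",
                len(y), cls_hist["accuracy"][-1], time.time() - t0)

    t0 = time.time()
    seg_cfg = dataclasses.replace(config.segmenter,
                                  seed=split_seed(config.seed, "segmenter"))
    crops, targets = sample_training_crops(
        image, mask, fine_records, crop_size=seg_cfg.crop_size,
        n_crops=seg_cfg.n_train_crops, seed=seg_cfg.seed + 7)
    segmenter = models.build_segmenter(seg_cfg)
    segmenter, seg_hist = models.train_segmenter(segmenter, crops, targets,
                                                 seg_cfg)
    logger.info("train: segmenter %d crops, final dice %.3f (%.1fs)",
                len(crops), seg_hist["dice"][-1], time.time() - t0)
    return classifier, segmenter


def stage_predict(config: PipelineConfig, image: MicrographImage,
                  classifier: models.TNTClassifier,
                  segmenter: models.TNTSegmenter,
                  fine_records) -> detect.Heatmap:
    """Classify fine windows, segment the positives, stitch the heatmap."""
    img = image.as_float()
    patches, origins = [], []
    for rec in fine_records:
        rs, cs = rec.slices()
        patches.append(img[rs, cs])
        origins.append(rec.origin)
    heatmaps = []
    if patches:
        x = np.stack(patches)
        probs = []
        for start in range(0, len(x), 16):  # bound memory
            probs.append(classifier.predict_proba(x[start:start + 16]))
        probs = np.concatenate(probs)
        keep = probs >= classifier.config.decision_threshold
        logger.info("predict: %d/%d fine windows classified TNT-positive",
                    int(keep.sum()), len(keep))
        for flag, patch, origin in zip(keep, patches, origins):
            if flag:
                heatmaps.append(models.predict_heatmap(segmenter, patch,
                                                       origin=origin))
    return detect.stitch_heatmaps(heatmaps, image.shape,
                                  config.detect.overlap_reduction)


def stage_count(config: PipelineConfig, image: MicrographImage,
                heatmap: detect.Heatmap) -> Tuple[
                    List[detect.TNTDetection], int]:
    """Threshold the heatmap, count TNT contours and cells."""
    mask = detect.threshold_heatmap(heatmap, config.detect.intensity_threshold)
    detections = detect.count_tnts(mask, config.detect,
                                   image.resolution_um_per_px)
    n_cells = detect.count_cells(image, method="builtin_blob")
    logger.info("count: %d TNT detections, %d cells", len(detections), n_cells)
    return detections, n_cells


def stage_score(config: PipelineConfig, truth: PhantomTruth,
                detections: Sequence[detect.TNTDetection],
                n_cells: int) -> Tuple[detect.TCRReport,
                                       evaluate.DetectionMetrics]:
    """Match detections to the true lines; compute metrics and the TCRs."""
    tp, fp, fn, _ = evaluate.match_detections(detections, truth.tnt_lines,
                                              config.match)
    metrics = evaluate.detection_metrics(tp, fp, fn)
    n_cells_safe = max(n_cells, 1)
    tcr_true, tcr100_true = detect.compute_tcr(truth.n_tnts, n_cells_safe)
    tcr_pred, tcr100_pred = detect.compute_tcr(len(detections), n_cells_safe)
    report = detect.TCRReport(
        n_tnts_true=truth.n_tnts, n_tnts_pred=len(detections),
        n_cells=n_cells, tcr_true=tcr_true, tcr_pred=tcr_pred,
        tcr100_true=tcr100_true, tcr100_pred=tcr100_pred)
    logger.info("score: P=%.3f R=%.3f f1=%.3f; TCRx100 true %.2f pred %.2f",
                metrics.precision, metrics.recall, metrics.f1,
                report.tcr100_true, report.tcr100_pred)
    return report, metrics


# ----------------------------------------------------------------------------
# Full run


def run_pipeline(config: PipelineConfig,
                 write_artifacts: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write the artifact bundle."""
    out_dir = config.out_dir if write_artifacts else None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    _setup_logging(out_dir, config.verbosity)
    chash = config_hash(config)
    logger.info("run: seed=%d config=%s", config.seed, chash)

    image, truth = stage_synth(config)
    image, label_mask = stage_labels(config, image, truth)
    coarse, fine = stage_patches(config, image, label_mask)
    classifier, segmenter = stage_train(config, image, label_mask, fine)
    heatmap = stage_predict(config, image, classifier, segmenter, fine)
    detections, n_cells = stage_count(config, image, heatmap)
    tcr, metrics = stage_score(config, truth, detections, n_cells)

    result = PipelineResult(
        tcr=tcr, metrics=metrics, detections=list(detections),
        heatmap=heatmap, label_mask=label_mask,
        n_coarse=len(coarse), n_fine=len(fine),
        config_hash=chash, seed=config.seed)

    if out_dir:
        stamp = {"seed": config.seed, "config_hash": chash}
        tifffile.imwrite(os.path.join(out_dir, "image.tif"), image.as_uint8())
        tifffile.imwrite(os.path.join(out_dir, "label_mask.tif"),
                         (label_mask.pixels * 255).astype(np.uint8))
        tifffile.imwrite(os.path.join(out_dir, "heatmap.tif"), heatmap.pixels)
        models.save_classifier(os.path.join(out_dir, "classifier"), classifier)
        models.save_segmenter(os.path.join(out_dir, "segmenter"), segmenter)
        det_rows = [{"tnt_id": i, "area_px": d.area_px, "area_um2": d.area_um2,
                     "bbox_r0": d.bbox[0], "bbox_c0": d.bbox[1],
                     "bbox_r1": d.bbox[2], "bbox_c1": d.bbox[3]}
                    for i, d in enumerate(detections)]
        pd.DataFrame(det_rows, columns=["tnt_id", "area_px", "area_um2",
                                        "bbox_r0", "bbox_c0", "bbox_r1",
                                        "bbox_c1"]).to_csv(
            os.path.join(out_dir, "detections.csv"), index=False)
        with open(os.path.join(out_dir, "tcr_report.json"), "w") as fh:
            json.dump({**stamp, **dataclasses.asdict(tcr)}, fh, indent=2)
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump({**stamp, **dataclasses.asdict(metrics)}, fh, indent=2)
        manifest = patching.save_patch_dataset(
            os.path.join(out_dir, "patches"), image, label_mask,
            [r for r in fine if r.label == 1][:50])
        logger.info("run: artifacts in %s (%d positive patch crops)",
                    out_dir, len(manifest))
    return result
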