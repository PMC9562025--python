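"""Evaluation: expert consensus, detection matching, and the statistics.

The expert-consensus rule mirrors the four-reviewer protocol: structures
marked by a clear majority are accepted as actual TNTs, structures marked by
exactly half the panel are flagged for joint review, and structures marked
by fewer are rejected.  Predicted structures are scored against true line
annotations with an explicit geometric matching rule (a prediction is a true
positive when enough of its pixels lie near an unmatched true line), from
which precision (PPV), recall (sensitivity) and the f-1 score follow.
Agreement between annotators uses Cohen's kappa; TNT-to-cell ratios are
compared with a pooled two-sample t-test; and human-vs-model counts across
image sets with a fixed two-way ANOVA (right-tailed F).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon as draw_polygon

from .config import MatchCriterion
from .detect import TNTDetection
from .phantom import distance_to_polyline
from .types import TNTLine, ValidationError

__all__ = [
    "ConsensusResult", "DetectionMetrics",
    "consensus", "match_detections", "detection_metrics", "f1_from_pr",
    "cohens_kappa", "pairwise_kappa_matrix", "tcr_ttest", "counts_anova",
    "write_detection_report", "write_tcr_report",
]


# ----------------------------------------------------------------------------
# Expert consensus


@dataclass
class ConsensusResult:
    """Partition of candidate structures by expert vote count."""

    accepted: Set[int]
    flagged_for_review: Set[int]
    rejected: Set[int]
    votes: Dict[int, int] = field(default_factory=dict)
    midpoints: Dict[int, np.ndarray] = field(default_factory=dict)
    members: Dict[int, List[Tuple[int, int]]] = field(default_factory=dict)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def consensus(candidate_marks: Sequence[Sequence[TNTLine]],
              n_experts: Optional[int] = None,
              match_radius_px: float = 10.0) -> ConsensusResult:
    """Cross-match per-expert marks and partition structures by vote count.

    Marks from different experts whose polyline midpoints lie within
    ``match_radius_px`` (single linkage) are treated as the same candidate
    structure.  With four experts, the published rule applies: >= 3 votes
    accepted, exactly 2 flagged for joint review, <= 1 rejected.  For other
    panel sizes the generalized rule is: strict majority accepted, exactly
    half flagged, minority rejected.
    """
    if n_experts is None:
        n_experts = len(candidate_marks)
    if len(candidate_marks) != n_experts:
        raise ValidationError(
            f"got {len(candidate_marks)} expert sets, expected {n_experts}")
    flat: List[Tuple[int, int, np.ndarray]] = []  # (expert, mark_idx, midpoint)
    for e, marks in enumerate(candidate_marks):
        for m, line in enumerate(marks):
            flat.append((e, m, line.midpoint))
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if np.linalg.norm(flat[i][2] - flat[j][2]) <= match_radius_px:
                uf.union(i, j)
    clusters: Dict[int, List[int]] = {}
    for i in range(len(flat)):
        clusters.setdefault(uf.find(i), []).append(i)

    result = ConsensusResult(accepted=set(), flagged_for_review=set(),
                             rejected=set())
    for sid, (_, idxs) in enumerate(sorted(clusters.items())):
        experts = {flat[i][0] for i in idxs}
        votes = len(experts)
        result.votes[sid] = votes
        result.midpoints[sid] = np.mean([flat[i][2] for i in idxs], axis=0)
        result.members[sid] = [(flat[i][0], flat[i][1]) for i in idxs]
        if votes > n_experts / 2:
            result.accepted.add(sid)
        elif votes == n_experts / 2:
            result.flagged_for_review.add(sid)
        else:
            result.rejected.add(sid)
    return result


# ----------------------------------------------------------------------------
# Detection matching and metrics


def _detection_pixels(det: TNTDetection) -> np.ndarray:
    """(n,2) pixel coordinates inside a detection's contour polygon."""
    rr, cc = draw_polygon(det.contour[:, 0], det.contour[:, 1])
    if len(rr) == 0:  # degenerate (sub-pixel) polygon: use its vertices
        verts = np.rint(det.contour).astype(int)
        return np.unique(verts, axis=0)
    return np.column_stack([rr, cc])


def match_detections(
    pred: Sequence[TNTDetection],
    truth: Sequence[TNTLine],
    criterion: Optional[MatchCriterion] = None,
) -> Tuple[int, int, int, Dict[int, int]]:
    """Greedy one-to-one matching of predictions to true lines.

    A prediction matches an unmatched true line when at least
    ``criterion.min_fraction`` of its pixels lie within
    ``criterion.distance_px`` of that line.  Returns (tp, fp, fn,
    assignment) with ``assignment[pred_idx] = truth_idx``.
    """
    criterion = criterion or MatchCriterion()
    assignment: Dict[int, int] = {}
    matched_truth: Set[int] = set()
    for pi, det in enumerate(pred):
        pixels = _detection_pixels(det).astype(np.float64)
        best_frac, best_ti = 0.0, -1
        for ti, line in enumerate(truth):
            if ti in matched_truth:
                continue
            d = distance_to_polyline(pixels, line.vertices)
            frac = float((d <= criterion.distance_px).mean())
            if frac > best_frac:
                best_frac, best_ti = frac, ti
        if best_ti >= 0 and best_frac >= criterion.min_fraction:
            assignment[pi] = best_ti
            matched_truth.add(best_ti)
    tp = len(assignment)
    fp = len(pred) - tp
    fn = len(truth) - len(matched_truth)
    return tp, fp, fn, assignment


@dataclass
class DetectionMetrics:
    """Precision (PPV), recall (sensitivity) and f-1 from TP/FP/FN counts."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def detection_metrics(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Compute PPV, sensitivity and f-1 = 2*P*R/(P+R).

    Undefined ratios (zero denominators) report 0 with the ``undefined``
    flag set.
    """
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    undefined = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, True
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, precision=precision,
                            recall=recall, f1=f1, undefined=undefined)


def f1_from_pr(precision: float, recall: float) -> float:
    """f-1 score directly from precision (PPV) and recall (sensitivity)."""
    if precision < 0 or recall < 0:
        raise ValidationError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ----------------------------------------------------------------------------
# Statistics


def cohens_kappa(marks_a: Sequence[int], marks_b: Sequence[int]) -> float:
    """Two-rater Cohen's kappa on binary judgment vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)``; when both raters are constant and
    identical (p_e = 1) agreement is perfect and kappa is defined as 1.
    """
    a = np.asarray(marks_a).astype(int)
    b = np.asarray(marks_b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("kappa needs two equal-length 1D vectors")
    if a.size == 0:
        raise ValidationError("kappa needs at least one judgment")
    po = float((a == b).mean())
    pe = 0.0
    for v in np.union1d(a, b):
        pe += float((a == v).mean()) * float((b == v).mean())
    if pe >= 1.0 - 1e-12:
        return 1.0
    return (po - pe) / (1.0 - pe)


def pairwise_kappa_matrix(mark_vectors: Sequence[Sequence[int]]) -> np.ndarray:
    """Symmetric matrix of pairwise Cohen's kappa over all rater pairs."""
    n = len(mark_vectors)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cohens_kappa(mark_vectors[i],
                                                 mark_vectors[j])
    return out


def tcr_ttest(tcr100_true: Sequence[float], tcr100_pred: Sequence[float],
              equal_var: bool = True) -> Tuple[float, float, float]:
    """Two-sample two-tailed t-test between true and predicted TCRs.

    Student's pooled-variance form by default (``equal_var``), Welch
    otherwise.  Returns (t, df, p).  Two identical constant samples give
    t = 0, p = 1.
    """
    x = np.asarray(tcr100_true, dtype=np.float64)
    y = np.asarray(tcr100_pred, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs at least 2 values")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        se = np.sqrt(vx / nx + vy / ny)
        if se == 0:
            df = nx + ny - 2
        else:
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if se == 0:
        t = 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    else:
        t = float((x.mean() - y.mean()) / se)
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), float(df), p


def counts_anova(counts: pd.DataFrame) -> Tuple[float, float, float, float]:
    """Fixed two-way ANOVA (no replication) on source x image_set counts.

    ``counts`` holds one count per (source, image_set) cell, with columns
    ``source`` (e.g. human/model), ``image_set`` and ``count``.  Returns
    (F_source, F_set, p_source, p_set) with right-tailed p-values from the
    F distribution.
    """
    required = {"source", "image_set", "count"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    table = counts.pivot_table(index="source", columns="image_set",
                               values="count", aggfunc="first")
    if table.isna().any().any():
        raise ValidationError("missing cells in the source x image_set table")
    x = table.to_numpy(dtype=np.float64)
    a, b = x.shape  # a sources, b image sets
    if a < 2 or b < 2:
        raise ValidationError("need at least 2 levels per factor")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_source = b * float(((row_means - grand) ** 2).sum())
    ss_set = a * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_source - ss_set
    df_source, df_set = a - 1, b - 1
    df_err = df_source * df_set
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_source = 0.0 if ss_source == 0 else np.inf
        f_set = 0.0 if ss_set == 0 else np.inf
    else:
        f_source = (ss_source / df_source) / ms_err
        f_set = (ss_set / df_set) / ms_err
    p_source = float(stats.f.sf(f_source, df_source, df_err))
    p_set = float(stats.f.sf(f_set, df_set, df_err))
    return float(f_source), float(f_set), p_source, p_set


# ----------------------------------------------------------------------------
# Report writers (CSV layouts mirror the published result tables)


def write_detection_report(path: str, rows: Sequence[dict]) -> pd.DataFrame:
    """Per-image-set detection metrics CSV.

    Columns: image_set, n_true, precision, recall, n_fp, f1.
    """
    df = pd.DataFrame(rows, columns=["image_set", "n_true", "precision",
                                     "recall", "n_fp", "f1"])
    df.to_csv(path, index=False)
    return df


def write_tcr_report(path: str, rows: Sequence[dict]) -> pd.DataFrame:
    """Per-image-set TCR CSV.

    Columns: image_set, n_true, n_pred, n_cells, tcr100_true, tcr100_pred.
    """
    df = pd.DataFrame(rows, columns=["image_set", "n_true", "n_pred",
                                     "n_cells", "tcr100_true", "tcr100_pred"])
    df.to_csv(path, index=False)
    return df
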