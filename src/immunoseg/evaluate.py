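"""Confidence filtering, IOU-matched assignment, and detection metrics.

A predicted cell is a true positive when it can be paired one-to-one with a
ground-truth cell of the *same class* at raster IOU at least ``theta``
(default 0.25), after discarding predictions with confidence not strictly
above ``tau`` (default 0.3).  The assignment is the maximum-cardinality
one-to-one matching over admissible (same-class, IOU >= theta) pairs; among
maximum-cardinality matchings the one with the largest total IOU is chosen,
so the result is order-independent and reproducible.

Per-class counts are pooled over frames before ratios are formed
(micro-averaging).  Sensitivity is ``tp / (tp + fn)``.  True negatives are
undefined for instance detection, so "specificity" is operationalized as
the positive predictive value ``tp / (tp + fp)`` over that class's
predictions; every report states this definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from immunoseg.model import (
    CohortDataset,
    ImageFrame,
    LocalMask,
    local_iou,
    local_mask,
)

__all__ = [
    "MatchSet", "ClassMetrics", "EvalSummary",
    "filter_confidence", "match_instances", "class_metrics",
    "overall_metrics", "cross_evaluate",
    "SPECIFICITY_DEFINITION",
]

SPECIFICITY_DEFINITION = (
    "specificity = tp / (tp + fp), the positive predictive value over the "
    "class's predictions (true negatives are undefined for instance detection)"
)


@dataclass
class MatchSet:
    """One-to-one truth-prediction assignment for a single frame."""

    frame_id: str
    pairs: list[tuple[int, int, float]]  # (truth_id, pred_id, iou)
    unmatched_truth: list[int]           # false negatives
    unmatched_pred: list[int]            # false positives
    truth_classes: dict[int, str] = field(default_factory=dict)
    pred_classes: dict[int, str] = field(default_factory=dict)
    theta: float = 0.25


@dataclass
class ClassMetrics:
    """Pooled detection metrics for one cell class."""

    cell_class: str
    tp: int
    fp: int
    fn: int
    n_truth: int
    n_pred: int
    iou_mean: float  # NaN when tp == 0
    iou_sd: float

    @property
    def sensitivity(self) -> float:
        """tp / (tp + fn); NaN when the class has no truth cells."""
        return self.tp / self.n_truth if self.n_truth else math.nan

    @property
    def specificity(self) -> float:
        """tp / (tp + fp) (PPV); NaN when the class has no predictions."""
        return self.tp / self.n_pred if self.n_pred else math.nan

    @property
    def defined(self) -> bool:
        return self.n_truth > 0 or self.n_pred > 0


@dataclass
class EvalSummary:
    """Per-class metrics plus cell-weighted and class-unweighted averages."""

    per_class: dict[str, ClassMetrics]
    sensitivity: float          # weighted by truth cells: sum tp / sum n_truth
    specificity: float          # weighted by predictions: sum tp / sum n_pred
    iou_mean: float             # over all matched pairs
    sensitivity_unweighted: float
    specificity_unweighted: float
    iou_mean_unweighted: float
    tau: float
    theta: float
    specificity_definition: str = SPECIFICITY_DEFINITION


def filter_confidence(frame: ImageFrame, tau: float = 0.3) -> ImageFrame:
    """Retain instances with confidence strictly greater than ``tau``."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"confidence threshold {tau} outside [0, 1]")
    kept = [inst for inst in frame.instances if inst.confidence > tau]
    return replace(frame, instances=kept)


def match_instances(
    truth: ImageFrame, pred: ImageFrame, theta: float = 0.25
) -> MatchSet:
    """Maximum-cardinality same-class matching at IOU >= ``theta``.

    Among maximum-cardinality matchings, total IOU is maximized (solved as a
    linear assignment with a cardinality-dominant weight offset).  Unmatched
    truth cells are false negatives; unmatched predictions false positives.
    """
    if (truth.width_px, truth.height_px) != (pred.width_px, pred.height_px):
        raise ValueError(
            f"frame dimensions differ: truth {truth.width_px}x{truth.height_px} "
            f"vs pred {pred.width_px}x{pred.height_px}"
        )
    t_inst, p_inst = truth.instances, pred.instances
    nt, np_ = len(t_inst), len(p_inst)
    pairs: list[tuple[int, int, float]] = []
    matched_t: set[int] = set()
    matched_p: set[int] = set()
    if nt and np_:
        t_masks = [local_mask(inst, truth) for inst in t_inst]
        p_masks = [local_mask(inst, pred) for inst in p_inst]
        # cardinality-dominant weights: C exceeds any achievable total IOU,
        # so maximizing sum(C + iou) maximizes pair count first
        C = float(nt + np_ + 1)
        cost = np.zeros((nt, np_))
        admissible = np.zeros((nt, np_), dtype=bool)
        iou_mat = np.zeros((nt, np_))
        for i, (ti, tm) in enumerate(zip(t_inst, t_masks)):
            for j, (pj, pm) in enumerate(zip(p_inst, p_masks)):
                if ti.cell_class != pj.cell_class:
                    continue
                if not _bbox_overlap(tm, pm):
                    continue
                v = local_iou(tm, pm)
                if v >= theta:
                    admissible[i, j] = True
                    iou_mat[i, j] = v
                    cost[i, j] = -(C + v)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if admissible[i, j]:
                pairs.append((t_inst[i].id, p_inst[j].id, float(iou_mat[i, j])))
                matched_t.add(i)
                matched_p.add(j)
    pairs.sort()
    return MatchSet(
        frame_id=truth.frame_id,
        pairs=pairs,
        unmatched_truth=[s.id for i, s in enumerate(t_inst) if i not in matched_t],
        unmatched_pred=[s.id for j, s in enumerate(p_inst) if j not in matched_p],
        truth_classes={s.id: s.cell_class for s in t_inst},
        pred_classes={s.id: s.cell_class for s in p_inst},
        theta=theta,
    )


def _bbox_overlap(a: LocalMask, b: LocalMask) -> bool:
    return (
        a.row0 < b.row0 + b.data.shape[0]
        and b.row0 < a.row0 + a.data.shape[0]
        and a.col0 < b.col0 + b.data.shape[1]
        and b.col0 < a.col0 + a.data.shape[1]
    )


def class_metrics(
    matchsets: Iterable[MatchSet], classes: Sequence[str] | None = None
) -> list[ClassMetrics]:
    """Pool counts over frames, then form per-class ratios.

    ``classes`` fixes the class list (and order); by default every class seen
    in truth or predictions is reported.  A class absent from both sides is
    reported with n=0 and NaN ratios rather than silently dropped.
    """
    matchsets = list(matchsets)
    frame_ids = [m.frame_id for m in matchsets]
    if len(set(frame_ids)) != len(frame_ids):
        raise ValueError("matchsets must come from disjoint frames")
    seen: list[str] = []
    for m in matchsets:
        for cls in list(m.truth_classes.values()) + list(m.pred_classes.values()):
            if cls not in seen:
                seen.append(cls)
    if classes is None:
        classes = seen
    out = []
    for cls in classes:
        tp = fp = fn = n_truth = n_pred = 0
        ious: list[float] = []
        for m in matchsets:
            t_ids = {i for i, c in m.truth_classes.items() if c == cls}
            p_ids = {i for i, c in m.pred_classes.items() if c == cls}
            n_truth += len(t_ids)
            n_pred += len(p_ids)
            for t_id, p_id, v in m.pairs:
                if m.truth_classes[t_id] == cls:
                    tp += 1
                    ious.append(v)
            fn += len(t_ids & set(m.unmatched_truth))
            fp += len(p_ids & set(m.unmatched_pred))
        arr = np.asarray(ious)
        out.append(
            ClassMetrics(
                cell_class=cls,
                tp=tp, fp=fp, fn=fn,
                n_truth=n_truth, n_pred=n_pred,
                iou_mean=float(arr.mean()) if tp else math.nan,
                iou_sd=float(arr.std(ddof=1)) if tp > 1 else math.nan,
            )
        )
    return out


def overall_metrics(
    per_class: Sequence[ClassMetrics], tau: float = 0.3, theta: float = 0.25
) -> EvalSummary:
    """Cell-weighted and class-unweighted averages across classes.

    The weighted sensitivity weights classes by truth-cell count (hence it
    equals pooled tp over pooled truth cells); weighted specificity weights
    by prediction count; weighted IOU averages over all matched pairs.
    """
    informative = [c for c in per_class if c.defined]
    if not informative:
        raise ValueError("all classes are empty; no metrics to average")
    sum_tp = sum(c.tp for c in per_class)
    sum_truth = sum(c.n_truth for c in per_class)
    sum_pred = sum(c.n_pred for c in per_class)
    sens_vals = [c.sensitivity for c in per_class if c.n_truth]
    spec_vals = [c.specificity for c in per_class if c.n_pred]
    iou_vals = [c.iou_mean for c in per_class if c.tp]
    return EvalSummary(
        per_class={c.cell_class: c for c in per_class},
        sensitivity=sum_tp / sum_truth if sum_truth else math.nan,
        specificity=sum_tp / sum_pred if sum_pred else math.nan,
        iou_mean=(
            sum(c.iou_mean * c.tp for c in per_class if c.tp) / sum_tp
            if sum_tp else math.nan
        ),
        sensitivity_unweighted=float(np.mean(sens_vals)) if sens_vals else math.nan,
        specificity_unweighted=float(np.mean(spec_vals)) if spec_vals else math.nan,
        iou_mean_unweighted=float(np.mean(iou_vals)) if iou_vals else math.nan,
        tau=tau,
        theta=theta,
    )


def cross_evaluate(
    truth_cohort: CohortDataset,
    pred_cohort: CohortDataset,
    theta: float = 0.25,
    tau: float = 0.3,
) -> EvalSummary:
    """Full pipeline over aligned frames: filter -> match -> pooled metrics.

    Frames are aligned by ``frame_id``; the truth cohort may come from a
    different fixation/panel cohort than the predictions (cross-dataset
    evaluation), but every frame id must appear on both sides.
    """
    t_frames = {f.frame_id: f for f in truth_cohort.frames}
    p_frames = {f.frame_id: f for f in pred_cohort.frames}
    missing = sorted(set(t_frames) ^ set(p_frames))
    if missing:
        raise ValueError(f"frame ids not present in both cohorts: {missing}")
    matchsets = []
    for fid in sorted(t_frames):
        pred = filter_confidence(p_frames[fid], tau)
        matchsets.append(match_instances(t_frames[fid], pred, theta))
    return overall_metrics(class_metrics(matchsets), tau=tau, theta=theta)
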