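"""Evaluation of detection and reconstruction quality.

Detection quality is the usual mask-level precision / recall / F1 with
greedy one-to-one IoU matching.  Reconstruction quality follows the
branch-level protocol: a reconstructed branch is *correct* when its
pixel IoU with the ground-truth branch exceeds 0.9; Acc_r is the
percentage of ground-truth branches reconstructed correctly, mIoU the
mean branch IoU (percent), and E_a / E_r the mean absolute (px) and
mean relative (%) errors of the estimated branch diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chains import BranchChain
from .raster import mask_iou


@dataclass(frozen=True)
class PerBranch:
    branch_id: int
    chain_id: int | None
    iou: float
    d_r: float | None  # reconstructed diameter, px
    d_g: float | None  # ground-truth diameter, px
    correct: bool


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    acc_r: float  # %
    miou: float  # %
    e_a: float  # px
    e_r: float  # %
    per_branch: tuple[PerBranch, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "acc_r": self.acc_r,
            "miou": self.miou,
            "e_a": self.e_a,
            "e_r": self.e_r,
            "per_branch": [
                {
                    "branch_id": p.branch_id,
                    "chain_id": p.chain_id,
                    "iou": p.iou,
                    "d_r": p.d_r,
                    "d_g": p.d_g,
                    "correct": p.correct,
                }
                for p in self.per_branch
            ],
        }


def _greedy_match(pred_masks, true_masks) -> list[tuple[int, int, float]]:
    """One-to-one matching by decreasing IoU; returns (pred, true, iou)."""
    ious = []
    for i, p in enumerate(pred_masks):
        for j, t in enumerate(true_masks):
            iou = mask_iou(p, t)
            if iou > 0.0:
                ious.append((iou, i, j))
    ious.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for iou, i, j in ious:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j, iou))
    return matches


def detection_prf(
    predicted: list[np.ndarray], truth: list[np.ndarray], match_iou: float = 0.5
) -> tuple[float, float, float]:
    """Precision, recall and F1 of mask detection.

    Predictions and truths are matched greedily one-to-one by decreasing
    IoU; a match with IoU ≥ ``match_iou`` is a true positive.  Undefined
    ratios (no predictions / no truths) are reported as 0.
    """
    matches = _greedy_match(predicted, truth)
    tp = sum(1 for _, _, iou in matches if iou >= match_iou)
    fp = len(predicted) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def branch_correct(chain_mask: np.ndarray, gt_branch_mask: np.ndarray) -> bool:
    """Strict correctness rule: pixel IoU with the ground truth > 0.9."""
    if not np.asarray(gt_branch_mask, dtype=bool).any():
        raise ValueError("branch_correct: empty ground-truth mask")
    return mask_iou(chain_mask, gt_branch_mask) > 0.9


def acc_r(correct_count: int, total: int) -> float:
    """Reconstruction accuracy in percent: 100 · R_b / G_b."""
    if total <= 0:
        raise ValueError("acc_r: total branch count must be positive")
    return 100.0 * correct_count / total


def miou(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean pixel IoU over (reconstructed, truth) mask pairs, percent."""
    if not pairs:
        raise ValueError("miou: empty pair list")
    return 100.0 * float(np.mean([mask_iou(r, g) for r, g in pairs]))


def chain_diameter(chain: BranchChain) -> float:
    """Branch diameter estimate: length-weighted mean of the member
    rectangles' short sides (weights = long sides)."""
    if not chain.member_rects:
        raise ValueError("chain_diameter: chain has no member rectangles")
    shorts = np.array([r.short_len for r in chain.member_rects])
    weights = np.array([r.long_len for r in chain.member_rects])
    if weights.sum() == 0.0:
        return float(shorts.mean())
    return float(np.average(shorts, weights=weights))


def diameter_errors(d_r: list[float], d_g: list[float]) -> tuple[float, float]:
    """Mean absolute error (px) and mean relative error (%) of diameters."""
    d_r = np.asarray(d_r, dtype=float)
    d_g = np.asarray(d_g, dtype=float)
    if d_r.shape != d_g.shape or d_r.ndim != 1:
        raise ValueError("diameter_errors: lists must have equal length")
    if d_r.size == 0:
        raise ValueError("diameter_errors: empty lists")
    if np.any(d_g <= 0.0):
        raise ValueError("diameter_errors: ground-truth diameters must be positive")
    abs_err = np.abs(d_r - d_g)
    return float(abs_err.mean()), float(100.0 * (abs_err / d_g).mean())


def evaluate_reconstruction(
    chains: list[BranchChain],
    gt_masks: dict[int, np.ndarray],
    gt_diameters: dict[int, float] | None = None,
    match_iou: float = 0.5,
    correct_iou: float = 0.9,
) -> MetricsReport:
    """Score reconstructed chains against ground-truth branches.

    Chains and branches are matched greedily one-to-one by mask IoU;
    every ground-truth branch contributes to Acc_r and mIoU (an
    unmatched branch scores IoU 0).  Diameter errors are computed over
    matched pairs with a known ground-truth diameter.
    """
    branch_ids = sorted(gt_masks)
    chain_masks = [c.mask for c in chains]
    if any(m is None for m in chain_masks):
        raise ValueError("all chains must carry rendered masks")
    matches = _greedy_match(chain_masks, [gt_masks[b] for b in branch_ids])
    by_branch = {branch_ids[j]: (i, iou) for i, j, iou in matches}

    per_branch: list[PerBranch] = []
    d_r_list: list[float] = []
    d_g_list: list[float] = []
    for b in branch_ids:
        if b in by_branch:
            i, iou = by_branch[b]
            d_r = chains[i].diameter_px
            d_g = gt_diameters.get(b) if gt_diameters else None
            correct = iou > correct_iou
            if d_g is not None:
                d_r_list.append(d_r)
                d_g_list.append(d_g)
            per_branch.append(PerBranch(b, chains[i].id, iou, d_r, d_g, correct))
        else:
            per_branch.append(PerBranch(b, None, 0.0, None, None, False))

    p, r, f1 = detection_prf(chain_masks, [gt_masks[b] for b in branch_ids], match_iou)
    accr = acc_r(sum(pb.correct for pb in per_branch), len(branch_ids))
    mean_iou = 100.0 * float(np.mean([pb.iou for pb in per_branch]))
    if d_g_list:
        e_a, e_r = diameter_errors(d_r_list, d_g_list)
    else:
        e_a, e_r = float("nan"), float("nan")
    return MetricsReport(
        precision=p, recall=r, f1=f1, acc_r=accr, miou=mean_iou,
        e_a=e_a, e_r=e_r, per_branch=tuple(per_branch),
    )
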