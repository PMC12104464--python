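"""Training objectives.

Six components, summed with unit weights into the total objective:

* ``sup_p`` / ``sup_r`` / ``sup_f`` — soft Dice between each branch's
  confidence map and the one-hot ground truth, labeled items only.  The
  reverse branch is supervised through prediction-map inversion
  (softmax of the negated scores against the *unmodified* truth); a
  ground-truth-inversion variant is available as an ablation.
* ``dc`` — direction consistency on the inconsistent part: each branch's
  low-confidence predictions are pulled (squared distance) toward the
  other branch's stop-gradient high-confidence predictions.
* ``cps`` — confidence-gated pairwise cross-pseudo supervision on the
  consistent part: below mean confidence 0.95 only the two
  high-confidence cross terms are used; at or above it, all six pairwise
  terms between the three branches.
* ``feat`` — squared distance between channel-compressed encoder and
  decoder feature maps at matching levels, for the positive and reverse
  branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .decoupling import DecoupleMasks

DICE_EPS = 1e-5
CPS_CONFIDENCE_GATE = 0.95


@dataclass
class LossBundle:
    """Named scalar loss components and their (unweighted) sum."""

    sup_p: float = 0.0
    sup_r: float = 0.0
    sup_f: float = 0.0
    cps: float = 0.0
    dc: float = 0.0
    feat: float = 0.0

    @property
    def total(self) -> float:
        return self.sup_p + self.sup_r + self.sup_f + self.cps + self.dc + self.feat

    def as_dict(self) -> dict[str, float]:
        return {"sup_p": self.sup_p, "sup_r": self.sup_r, "sup_f": self.sup_f,
                "cps": self.cps, "dc": self.dc, "feat": self.feat, "total": self.total}


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label map (B, H, W) -> one-hot (B, C, H, W) float32."""
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label values out of range")
    eye = np.eye(n_classes, dtype=np.float32)
    return np.ascontiguousarray(eye[labels].transpose(0, 3, 1, 2))


def dice_loss(p: Tensor, gt_onehot: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss averaged over classes and batch items.

    1 - (2 sum(P*g) + eps) / (sum(P) + sum(g) + eps), sums over pixels,
    per class and item.
    """
    if p.shape[0] == 0:
        return Tensor(np.float32(0.0))
    g = Tensor(gt_onehot.astype(np.float32))
    inter = (p * g).sum(axis=(2, 3))
    denom = p.sum(axis=(2, 3)) + g.sum(axis=(2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return (1.0 - dice).mean()


def supervised_losses(outputs, labels: np.ndarray, labeled_count: int,
                      gt_inversion: bool = False) -> tuple[Tensor, Tensor, Tensor]:
    """Per-branch supervised Dice on the labeled half of the batch.

    ``outputs`` is a PerspectiveOutputs; ``labels`` are the integer maps of
    the first ``labeled_count`` batch items.  With ``gt_inversion`` the
    reverse branch instead inverts the one-hot truth and scores
    softmax(O_rev) against it (ablation arm).
    """
    zero = Tensor(np.float32(0.0))
    if labeled_count == 0:
        return zero, zero, zero
    n_classes = outputs.P_pos.shape[1]
    sl = slice(0, labeled_count)
    gt = one_hot(labels[:labeled_count], n_classes)
    sup_p = dice_loss(outputs.P_pos[sl], gt)
    if outputs.O_rev is None:
        sup_r = zero
    elif gt_inversion:
        inv_gt = 1.0 - gt if n_classes == 2 else gt[:, ::-1]
        p_rev_raw = ad.softmax_channels(outputs.O_rev[sl])
        sup_r = dice_loss(p_rev_raw, inv_gt)
    else:
        sup_r = dice_loss(outputs.P_rev[sl], gt)
    sup_f = dice_loss(outputs.P_fus[sl], gt) if outputs.P_fus is not None else zero
    return sup_p, sup_r, sup_f


def direction_consistency_loss(h_pos: Tensor, l_pos: Tensor,
                               h_rev: Tensor, l_rev: Tensor,
                               masks: DecoupleMasks) -> Tensor:
    """L2(lP_rev, detach(hP_pos)) + L2(lP_pos, detach(hP_rev)).

    Each term is the mean squared difference over the pixels of its
    high-confidence mask and all classes; the stop-gradient (detach) side
    contributes no parameter updates.  Empty masks contribute 0.
    """
    n_classes = h_pos.shape[1]
    total = Tensor(np.float32(0.0))
    n_pos = int(masks.high_pos.sum())
    if n_pos:
        d = l_rev - h_pos.detach()
        total = total + (d * d).sum() / float(n_pos * n_classes)
    n_rev = int(masks.high_rev.sum())
    if n_rev:
        d = l_pos - h_rev.detach()
        total = total + (d * d).sum() / float(n_rev * n_classes)
    return total


def masked_cross_entropy(scores: Tensor, pseudo_labels: np.ndarray,
                         mask: np.ndarray) -> Tensor:
    """Per-pixel CE of softmax(scores) against integer pseudo-labels.

    Averaged over the pixels selected by ``mask``; pseudo-labels carry no
    gradient by construction (they are plain integer arrays).
    """
    n = int(mask.sum())
    if n == 0:
        return Tensor(np.float32(0.0))
    n_classes = scores.shape[1]
    ls = ad.log_softmax_channels(scores)
    weight = one_hot(pseudo_labels, n_classes) * mask[:, None].astype(np.float32)
    return -(ls * Tensor(weight)).sum() / float(n)


def mean_confidence(p_pos, p_rev) -> float:
    """m of the CPS gate: batch-pixel mean of the two branches' averaged max confidence."""
    a = p_pos.data if isinstance(p_pos, Tensor) else np.asarray(p_pos)
    b = p_rev.data if isinstance(p_rev, Tensor) else np.asarray(p_rev)
    return float((a.max(axis=1) + b.max(axis=1)).mean() / 2.0)


def cps_loss(outputs, masks: DecoupleMasks, m_confidence: float,
             batch_slice: slice = slice(None),
             pairs: Sequence[str] = ("P-R", "P-F", "R-F")) -> tuple[Tensor, int]:
    """Confidence-gated pairwise cross-pseudo supervision on the consistent part.

    Returns (loss, number_of_CE_terms).  ``batch_slice`` selects the items
    (normally the unlabeled half) the masks were computed on.  Below the
    0.95 gate only the two P-R high-confidence terms are used, each
    restricted to consistent pixels where the comparator branch is
    strictly more confident; at or above the gate all six pairwise terms
    over the full consistent part apply (restricted to the enabled
    ``pairs``, the ablation axis).
    """
    zero = Tensor(np.float32(0.0))
    if not masks.consistent.any():
        return zero, 0
    o_pos = outputs.O_pos[batch_slice]
    o_rev = outputs.O_rev_neg[batch_slice] if outputs.O_rev is not None else None
    o_fus = outputs.O_fus[batch_slice] if outputs.O_fus is not None else None
    p_pos = outputs.P_pos.data[batch_slice]
    p_rev = outputs.P_rev.data[batch_slice] if outputs.P_rev is not None else None
    p_fus = outputs.P_fus.data[batch_slice] if outputs.P_fus is not None else None
    pl_pos = p_pos.argmax(axis=1)
    pl_rev = p_rev.argmax(axis=1) if p_rev is not None else None
    pl_fus = p_fus.argmax(axis=1) if p_fus is not None else None
    con = masks.consistent
    loss, n_terms = zero, 0

    if m_confidence < CPS_CONFIDENCE_GATE:
        if o_rev is None:
            return zero, 0
        # high-confidence sub-masks of the consistent part: the comparator
        # branch must be strictly more confident than the supervised one
        max_pos, max_rev = p_pos.max(axis=1), p_rev.max(axis=1)
        rev_wins = con & (max_rev > max_pos)
        pos_wins = con & (max_pos > max_rev)
        loss = loss + masked_cross_entropy(o_pos, pl_rev, rev_wins)
        loss = loss + masked_cross_entropy(o_rev, pl_pos, pos_wins)
        n_terms = 2
        return loss, n_terms

    if "P-R" in pairs and o_rev is not None:
        loss = loss + masked_cross_entropy(o_pos, pl_rev, con)
        loss = loss + masked_cross_entropy(o_rev, pl_pos, con)
        n_terms += 2
    if "P-F" in pairs and o_fus is not None:
        loss = loss + masked_cross_entropy(o_pos, pl_fus, con)
        loss = loss + masked_cross_entropy(o_fus, pl_pos, con)
        n_terms += 2
    if "R-F" in pairs and o_fus is not None and o_rev is not None:
        loss = loss + masked_cross_entropy(o_rev, pl_fus, con)
        loss = loss + masked_cross_entropy(o_fus, pl_rev, con)
        n_terms += 2
    return loss, n_terms


def channel_compress(feature_map: Tensor, p: float = 2.0) -> Tensor:
    """Mean over channels of |f|^p -> (B, 1, H, W), non-negative."""
    return feature_map.abs_pow(p).mean(axis=1, keepdims=True)


def feature_consistency_loss(enc_pyramid: Sequence[Tensor], dec_pyramid: Sequence[Tensor],
                             p: float = 2.0, reduction: str = "mean") -> Tensor:
    """Squared distance between compressed encoder/decoder maps per level.

    Levels are paired from full resolution upward; the encoder bottleneck
    (which has no decoder counterpart) is excluded.  ``reduction``
    "mean" divides each level's term by its pixel count; "sum" keeps the
    raw sum.
    """
    n_levels = len(dec_pyramid)
    if n_levels == 0 or len(enc_pyramid) < n_levels:
        raise ValueError("pyramid level-count mismatch")
    total = Tensor(np.float32(0.0))
    for e, d in zip(enc_pyramid[:n_levels], dec_pyramid):
        if e.shape[2:] != d.shape[2:]:
            raise ValueError(f"spatial mismatch {e.shape} vs {d.shape}")
        diff = channel_compress(e, p) - channel_compress(d, p)
        term = (diff * diff).sum()
        if reduction == "mean":
            term = term / float(np.prod(diff.shape))
        total = total + term
    return total


def total_loss(sup_p: Tensor, sup_r: Tensor, sup_f: Tensor,
               cps: Tensor, dc: Tensor, feat: Tensor,
               weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
               ) -> tuple[Tensor, LossBundle]:
    """Unweighted (by default) sum of all components.

    weights apply to (sup, cps, dc, feat) for experimentation; the default
    (1,1,1,1) is the published objective.  Raises on NaN components.
    """
    comps = {"sup_p": sup_p, "sup_r": sup_r, "sup_f": sup_f,
             "cps": cps, "dc": dc, "feat": feat}
    for name, t in comps.items():
        if not np.isfinite(t.data):
            raise FloatingPointError(f"loss component {name} is not finite")
    w_sup, w_cps, w_dc, w_feat = weights
    total = w_sup * (sup_p + sup_r + sup_f) + w_cps * cps + w_dc * dc + w_feat * feat
    bundle = LossBundle(**{k: float(v.data) for k, v in comps.items()})
    return total, bundle
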