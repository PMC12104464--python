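"""Dynamic threshold and consistent/inconsistent pixel decoupling.

The confidence threshold gamma starts at the uninformative value 1/C and
is updated each iteration, per branch, as an exponential moving average
of the batch's mean maximum-class confidence with an interpolation
weight lambda = i / i_max that grows linearly over training.  The final
threshold is the smaller of the two branch thresholds, so more pixels
qualify as "consistent" early in training and the bar rises as the
branches become confident.

A pixel is *consistent* when the max-class confidence of BOTH branches
strictly exceeds gamma; all remaining pixels form the inconsistent part,
which is further split per branch into high-confidence regions (where
that branch's max confidence strictly beats the other branch's) used by
the direction-consistency loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor


def _as_array(p) -> np.ndarray:
    return p.data if isinstance(p, Tensor) else np.asarray(p)


@dataclass(frozen=True)
class ThresholdState:
    """Running dynamic-threshold state (checkpointable)."""

    gamma: float
    gamma_pos: float
    gamma_rev: float
    iteration: int
    i_max: int

    @classmethod
    def initial(cls, n_classes: int, i_max: int) -> "ThresholdState":
        if i_max <= 0:
            raise ValueError("i_max must be positive")
        g0 = 1.0 / n_classes
        return cls(gamma=g0, gamma_pos=g0, gamma_rev=g0, iteration=0, i_max=i_max)

    def as_dict(self) -> dict:
        return {"gamma": self.gamma, "gamma_pos": self.gamma_pos,
                "gamma_rev": self.gamma_rev, "iteration": self.iteration, "i_max": self.i_max}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdState":
        return cls(gamma=float(d["gamma"]), gamma_pos=float(d["gamma_pos"]),
                   gamma_rev=float(d["gamma_rev"]), iteration=int(d["iteration"]),
                   i_max=int(d["i_max"]))


@dataclass(frozen=True)
class DecoupleMasks:
    """Boolean per-pixel partition produced by :func:`decouple`."""

    consistent: np.ndarray     # B x H x W
    inconsistent: np.ndarray   # complement of consistent
    high_pos: np.ndarray       # within inconsistent: max P_pos > max P_rev
    high_rev: np.ndarray       # within inconsistent: max P_rev > max P_pos


def batch_confidence_stat(p: np.ndarray | Tensor) -> float:
    """Mean over batch items of the per-pixel max-class confidence mean."""
    arr = _as_array(p)
    return float(arr.max(axis=1).mean())


def update_threshold(state: ThresholdState, p_pos, p_rev) -> ThresholdState:
    """One EMA step of the dynamic threshold (new state; inputs untouched)."""
    if state.iteration >= state.i_max:
        raise ValueError("threshold already updated i_max times")
    i = state.iteration + 1
    lam = i / state.i_max
    s_pos = batch_confidence_stat(p_pos)
    s_rev = batch_confidence_stat(p_rev)
    g_pos = (1 - lam) * state.gamma_pos + lam * s_pos
    g_rev = (1 - lam) * state.gamma_rev + lam * s_rev
    return replace(state, gamma=min(g_pos, g_rev), gamma_pos=g_pos,
                   gamma_rev=g_rev, iteration=i)


def decouple(p_pos, p_rev, gamma: float) -> DecoupleMasks:
    """Partition pixels by whether both branches beat the threshold."""
    a, b = _as_array(p_pos), _as_array(p_rev)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    max_pos = a.max(axis=1)
    max_rev = b.max(axis=1)
    consistent = (max_pos > gamma) & (max_rev > gamma)
    inconsistent = ~consistent
    high_pos = inconsistent & (max_pos > max_rev)
    high_rev = inconsistent & (max_rev > max_pos)
    return DecoupleMasks(consistent, inconsistent, high_pos, high_rev)


def split_confidence(p_pos: Tensor, p_rev: Tensor, masks: DecoupleMasks):
    """High/low-confidence confidence-map splits on the inconsistent part.

    Returns (hP_pos, lP_pos, hP_rev, lP_rev) as full-shape maps that are
    zero outside their masks.  At a pixel where the positive branch wins
    (high_pos), hP_pos carries P_pos and lP_rev carries P_rev — the pair
    the direction-consistency loss pulls together; symmetrically for
    high_rev.  Gradients flow through the confidence maps; the masks are
    constants.
    """
    hm_pos = Tensor(masks.high_pos[:, None, :, :].astype(np.float32))
    hm_rev = Tensor(masks.high_rev[:, None, :, :].astype(np.float32))
    h_pos = p_pos * hm_pos
    l_rev = p_rev * hm_pos
    h_rev = p_rev * hm_rev
    l_pos = p_pos * hm_rev
    return h_pos, l_pos, h_rev, l_rev
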