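"""Adversarial, adjacent-voxel-difference and L1 loss terms.

Every function accepts either plain NumPy arrays (returning a float) or
autodiff :class:`~dosegan.nn.Var` nodes (returning a ``Var``), so the same
formulas serve both metric-style evaluation and gradient-based training.

The discriminator objective is binary cross-entropy with logits, evaluated
through the softplus identity ``-log sigma(x) = softplus(-x)`` for
numerical stability.  The adjacent-voxel-difference (AVD) term penalises
the squared mismatch between consecutive-slice dose differences of ground
truth and prediction along the transverse, coronal and sagittal axes; it
preserves dose-gradient (edge) structure that plain L1 blurs.  Reductions
default to means so that the loss weights keep their meaning when the crop
size changes; ``reduction="sum"`` restores the literal summed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Var


@dataclass
class LossWeights:
    """Weights of the composite generator objective."""

    adversarial: float = 1.0
    avd: float = 10.0
    l1: float = 100.0

    def __post_init__(self):
        if min(self.adversarial, self.avd, self.l1) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.adversarial == self.avd == self.l1 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class LossReport:
    """Scalar loss terms for one optimisation step / epoch."""

    d_gt: float
    d_pre: float
    d_total: float
    g_adv: float
    g_avd: float
    g_l1: float
    g_total: float

    FIELDS = ("d_gt", "d_pre", "d_total", "g_adv", "g_avd", "g_l1", "g_total")

    def as_dict(self):
        return {k: getattr(self, k) for k in self.FIELDS}


def _is_var(x) -> bool:
    return isinstance(x, Var)


def _softplus_np(x):
    return np.logaddexp(0.0, x)


def _check_nonempty(x, name):
    data = x.data if _is_var(x) else np.asarray(x)
    if data.size == 0:
        raise ValueError(f"{name} is empty")
    return data


def discriminator_loss(logits_gt, logits_pred):
    """BCE-with-logits discriminator objective.

    ``L_D_GT = -mean log sigma(logit_gt)`` (real patches labelled 1),
    ``L_D_Pre = -mean log(1 - sigma(logit_pred))`` (fake labelled 0),
    ``L_D`` their average.  Returns ``(L_D_GT, L_D_Pre, L_D)``.
    """
    _check_nonempty(logits_gt, "logits_gt")
    _check_nonempty(logits_pred, "logits_pred")
    if _is_var(logits_gt) or _is_var(logits_pred):
        lgt, lpr = nn.as_var(logits_gt), nn.as_var(logits_pred)
        l_gt = nn.mean(nn.softplus(nn.neg(lgt)))
        l_pre = nn.mean(nn.softplus(lpr))
        l_d = nn.scale(nn.add(l_gt, l_pre), 0.5)
        return l_gt, l_pre, l_d
    l_gt = float(np.mean(_softplus_np(-np.asarray(logits_gt, dtype=np.float64))))
    l_pre = float(np.mean(_softplus_np(np.asarray(logits_pred, dtype=np.float64))))
    return l_gt, l_pre, 0.5 * (l_gt + l_pre)


def generator_adversarial_loss(logits_pred):
    """Non-saturating adversarial term: ``-mean log sigma(logit_pred)``."""
    _check_nonempty(logits_pred, "logits_pred")
    if _is_var(logits_pred):
        return nn.mean(nn.softplus(nn.neg(logits_pred)))
    return float(np.mean(_softplus_np(-np.asarray(logits_pred, dtype=np.float64))))


def avd_loss(gt, pred, reduction: str = "mean"):
    """Adjacent-voxel-difference loss over the three anatomical axes.

    For each axis, the difference between consecutive-slice differences of
    ground truth and prediction is squared and accumulated; ``mean``
    divides by the total number of adjacent pairs.
    """
    gt_d = _check_nonempty(gt, "gt")
    pred_d = _check_nonempty(pred, "pred")
    if gt_d.shape != pred_d.shape:
        raise ValueError(f"shape mismatch {gt_d.shape} vs {pred_d.shape}")
    spatial_axes = tuple(range(gt_d.ndim - 3, gt_d.ndim))
    for ax in spatial_axes:
        if gt_d.shape[ax] < 2:
            raise ValueError(f"axis {ax} must have length >= 2 for AVD")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")

    if _is_var(pred) or _is_var(gt):
        gt_v, pred_v = nn.as_var(gt), nn.as_var(pred)
        terms, count = [], 0
        for ax in spatial_axes:
            diff = nn.sub(nn.axis_diff(gt_v, ax), nn.axis_diff(pred_v, ax))
            terms.append(nn.total(nn.square(diff)))
            count += diff.data.size
        acc = terms[0]
        for t in terms[1:]:
            acc = nn.add(acc, t)
        return nn.scale(acc, 1.0 / count) if reduction == "mean" else acc

    gt_d = gt_d.astype(np.float64)
    pred_d = pred_d.astype(np.float64)
    acc, count = 0.0, 0
    for ax in spatial_axes:
        diff = np.diff(gt_d, axis=ax) - np.diff(pred_d, axis=ax)
        acc += float(np.sum(diff**2))
        count += diff.size
    return acc / count if reduction == "mean" else acc


def l1_term(gt, pred, reduction: str = "mean"):
    """L1 distance between ground-truth and predicted dose."""
    gt_d = _check_nonempty(gt, "gt")
    pred_d = _check_nonempty(pred, "pred")
    if gt_d.shape != pred_d.shape:
        raise ValueError(f"shape mismatch {gt_d.shape} vs {pred_d.shape}")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if _is_var(pred) or _is_var(gt):
        diff = nn.absolute(nn.sub(nn.as_var(gt), nn.as_var(pred)))
        return nn.mean(diff) if reduction == "mean" else nn.total(diff)
    diff = np.abs(gt_d.astype(np.float64) - pred_d.astype(np.float64))
    return float(diff.mean()) if reduction == "mean" else float(diff.sum())


def total_generator_loss(adv, avd, l1, weights: LossWeights | None = None):
    """Weighted sum  w_adv * L_adv + w_avd * L_avd + w_l1 * L_1."""
    w = weights or LossWeights()
    if any(_is_var(t) for t in (adv, avd, l1)):
        acc = nn.scale(nn.as_var(adv), w.adversarial)
        acc = nn.add(acc, nn.scale(nn.as_var(avd), w.avd))
        acc = nn.add(acc, nn.scale(nn.as_var(l1), w.l1))
        return acc
    return w.adversarial * float(adv) + w.avd * float(avd) + w.l1 * float(l1)
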