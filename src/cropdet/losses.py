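"""Bounding-box regression losses and classification losses.

The regression family runs from plain IoU through GIoU, EIoU and SIoU to
SIMIoU, the composite loss this package centres on.  SIMIoU combines three
ingredients: a powered *inner IoU* (overlap of both boxes rescaled about
their own centres by a ratio), the squared distances between the two pairs
of matching corners measured in image-normalized units, and a CIoU-style
aspect-ratio consistency penalty:

    L = 1 - inner_iou**theta + (d1/2 + d2/2)**theta + 0.5 * alpha * gamma

with ``gamma = (4/pi^2) (arctan(w_g/h_g) - arctan(w/h))^2`` and
``alpha = gamma / ((1 - IoU) + gamma)``.  The exponent ``theta`` sharpens
the penalty for badly wrong boxes.

Every function accepts :class:`~cropdet.boxes.Box` objects, length-4
sequences, or arrays shaped ``(..., 4)`` in corner format, and is
differentiable when fed autodiff tensors, so the same code drives both
scalar evaluation and gradient-based training.

Conventions for degenerate inputs (all eps-guarded with ``eps = 1e-9``):
two zero-area boxes have IoU 0; coincident centres make the SIoU angle and
distance terms vanish; a perfect match with equal aspect ratios has a zero
aspect penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .boxes import Box, boxes_to_array
from .nn import Tensor

__all__ = [
    "LossParams", "SiouTerms", "SimiouTerms",
    "iou", "giou", "eiou_loss", "siou_terms", "siou_loss",
    "inner_iou", "simiou_loss", "focal_loss", "elementwise_losses",
    "box_loss", "LOSS_NAMES",
]

_EPS = 1e-9


@dataclass
class LossParams:
    """Every tunable knob of the loss family in one record.

    theta:        exponent applied to the inner-IoU and corner terms (>= 0)
    inner_ratio:  scale factor for the inner-IoU box rescale (> 0);
                  1.0 reduces inner IoU to plain IoU
    focal_alpha:  class-balance weight of the focal loss, in (0, 1)
    focal_gamma:  hard-example exponent of the focal loss (>= 0)
    shape_theta:  SIoU shape-term exponent (the original SIoU uses 4)
    eps:          small positive guard for denominators
    """

    theta: float = 1.0
    inner_ratio: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    shape_theta: float = 4.0
    eps: float = _EPS

    def __post_init__(self):
        if not all(np.isfinite([self.theta, self.inner_ratio, self.focal_alpha,
                                self.focal_gamma, self.shape_theta, self.eps])):
            raise ValueError("loss parameters must be finite")
        if self.theta < 0 or self.focal_gamma < 0 or self.shape_theta < 0:
            raise ValueError("exponents must be nonnegative")
        if self.inner_ratio <= 0:
            raise ValueError("inner_ratio must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class SiouTerms:
    """Intermediate quantities of the SIoU loss (dimensionless)."""

    lambda_angle: float
    delta_dist: float
    omega_shape: float
    sigma_center: float
    c_h: float          # centre y-offset, drives the angle term
    c_w: float          # centre x-offset
    enclose_w: float    # enclosing-box width, denominator of rho_x
    enclose_h: float    # enclosing-box height, denominator of rho_y
    rho_x: float
    rho_y: float
    gamma_dist: float
    w_w: float
    w_h: float


@dataclass
class SimiouTerms:
    inner_iou: float
    d1: float
    d2: float
    gamma_aspect: float
    alpha_balance: float
    img_w: float
    img_h: float


def _coerce(a):
    if isinstance(a, Tensor):
        return a
    return Tensor(boxes_to_array(a))


def _split(a):
    return a[..., 0], a[..., 1], a[..., 2], a[..., 3]


def _maybe_item(x, scalar_in: bool):
    v = x.data if isinstance(x, Tensor) else x
    return float(v) if (scalar_in and np.ndim(v) == 0) else v


def _is_scalar_pair(a, b) -> bool:
    def one(x):
        if isinstance(x, Box):
            return True
        arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
        return arr.ndim == 1
    return one(a) and one(b)


# ---------------------------------------------------------------------------
# core vectorized formulas (operate on tensors, keep the graph)
# ---------------------------------------------------------------------------

def _iou_t(a: Tensor, b: Tensor, eps: float = _EPS):
    ax1, ay1, ax2, ay2 = _split(a)
    bx1, by1, bx2, by2 = _split(b)
    iw = nn.maximum(nn.minimum(ax2, bx2) - nn.maximum(ax1, bx1), 0.0)
    ih = nn.maximum(nn.minimum(ay2, by2) - nn.maximum(ay1, by1), 0.0)
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    # max-guard keeps iou(a, a) exactly 1 while sending 0-area pairs to 0
    return inter / nn.maximum(union, eps), union


def _enclose_t(a: Tensor, b: Tensor):
    ax1, ay1, ax2, ay2 = _split(a)
    bx1, by1, bx2, by2 = _split(b)
    cw = nn.maximum(ax2, bx2) - nn.minimum(ax1, bx1)
    ch = nn.maximum(ay2, by2) - nn.minimum(ay1, by1)
    return cw, ch


def _giou_t(a: Tensor, b: Tensor, eps: float = _EPS):
    v, union = _iou_t(a, b, eps)
    cw, ch = _enclose_t(a, b)
    enclose = cw * ch
    # degenerate enclosing box (both boxes collapse to a point/segment):
    # the penalty is defined as zero and GIoU falls back to IoU
    penalty = (enclose - union) / nn.maximum(enclose, eps)
    return v - penalty


def _centers_t(a: Tensor):
    ax1, ay1, ax2, ay2 = _split(a)
    return 0.5 * (ax1 + ax2), 0.5 * (ay1 + ay2), ax2 - ax1, ay2 - ay1


def _eiou_t(a: Tensor, b: Tensor, eps: float = _EPS):
    v, _ = _iou_t(a, b, eps)
    acx, acy, aw, ah = _centers_t(a)
    bcx, bcy, bw, bh = _centers_t(b)
    cw, ch = _enclose_t(a, b)
    c2 = cw * cw + ch * ch
    center = ((acx - bcx) ** 2 + (acy - bcy) ** 2) / (c2 + eps)
    width = (aw - bw) ** 2 / (cw * cw + eps)
    height = (ah - bh) ** 2 / (ch * ch + eps)
    return 1.0 - v + center + width + height


def _siou_t(a: Tensor, b: Tensor, shape_theta: float = 4.0, eps: float = _EPS):
    """SIoU loss, vectorized; the angle/distance terms vanish smoothly at
    coincident centres (sigma below eps)."""
    v, _ = _iou_t(a, b, eps)
    acx, acy, aw, ah = _centers_t(a)
    bcx, bcy, bw, bh = _centers_t(b)
    dx = bcx - acx
    dy = bcy - acy
    sigma2 = dx * dx + dy * dy
    sigma = nn.sqrt(sigma2 + eps * eps)
    degenerate = (sigma2.data if isinstance(sigma2, Tensor) else np.asarray(sigma2)) < eps
    sin_alpha = nn.clip(nn.absolute(dy) / sigma, 0.0, 1.0)
    lam = 1.0 - 2.0 * nn.sin(nn.arcsin(sin_alpha) - math.pi / 4.0) ** 2
    lam = nn.where(degenerate, 0.0 * lam, lam)
    gamma = 2.0 - lam
    cw, ch = _enclose_t(a, b)
    rho_x = (dx / (cw + eps)) ** 2
    rho_y = (dy / (ch + eps)) ** 2
    rho_x = nn.where(degenerate, 0.0 * rho_x, rho_x)
    rho_y = nn.where(degenerate, 0.0 * rho_y, rho_y)
    delta = (1.0 - nn.exp(-gamma * rho_x)) + (1.0 - nn.exp(-gamma * rho_y))
    w_w = nn.absolute(aw - bw) / (nn.maximum(aw, bw) + eps)
    w_h = nn.absolute(ah - bh) / (nn.maximum(ah, bh) + eps)
    omega = (1.0 - nn.exp(-w_w)) ** shape_theta + (1.0 - nn.exp(-w_h)) ** shape_theta
    loss = 1.0 - v + (delta + omega) * 0.5
    extras = dict(lam=lam, gamma=gamma, delta=delta, omega=omega, sigma=sigma,
                  rho_x=rho_x, rho_y=rho_y, w_w=w_w, w_h=w_h, dx=dx, dy=dy,
                  cw=cw, ch=ch)
    return loss, extras


def _scale_about_center_t(a: Tensor, ratio: float) -> Tensor:
    acx, acy, aw, ah = _centers_t(a)
    hw = aw * (0.5 * ratio)
    hh = ah * (0.5 * ratio)
    return nn.stack([acx - hw, acy - hh, acx + hw, acy + hh], axis=-1)


def _inner_iou_t(a: Tensor, b: Tensor, ratio: float, eps: float = _EPS):
    if ratio <= 0:
        raise ValueError("inner-IoU ratio must be positive")
    v, _ = _iou_t(_scale_about_center_t(a, ratio), _scale_about_center_t(b, ratio), eps)
    return v


def _simiou_t(a: Tensor, b: Tensor, params: LossParams,
              img_w: float = 1.0, img_h: float = 1.0,
              corner_norm: str = "half"):
    """SIMIoU loss on corner-format boxes.

    Coordinates are first normalized by the image extent so the corner
    distances d1, d2 are dimensionless ("both h and w equal one").

    corner_norm: "half"  — canonical form, penalty (d1/2 + d2/2)**theta;
                 "shape" — variant normalizing by (h^2 + w^2) and (h*w),
                           which coincide at 2 and 1 after normalization,
                           giving (d1/2 + d2)**theta.
    """
    if img_w <= 0 or img_h <= 0:
        raise ValueError("image extent must be positive")
    eps = params.eps
    scale = Tensor(np.array([1.0 / img_w, 1.0 / img_h, 1.0 / img_w, 1.0 / img_h]))
    a = a * scale
    b = b * scale
    inner = _inner_iou_t(a, b, params.inner_ratio, eps)
    ax1, ay1, ax2, ay2 = _split(a)
    bx1, by1, bx2, by2 = _split(b)
    d1 = (ax1 - bx1) ** 2 + (ay1 - by1) ** 2
    d2 = (ax2 - bx2) ** 2 + (ay2 - by2) ** 2
    if corner_norm == "half":
        corner = (d1 * 0.5 + d2 * 0.5) ** params.theta
    elif corner_norm == "shape":
        corner = (d1 * 0.5 + d2) ** params.theta
    else:
        raise ValueError(f"unknown corner_norm {corner_norm!r}")
    aw, ah = ax2 - ax1, ay2 - ay1
    bw, bh = bx2 - bx1, by2 - by1
    gamma = (4.0 / math.pi ** 2) * (nn.arctan(bw / (bh + eps)) - nn.arctan(aw / (ah + eps))) ** 2
    v, _ = _iou_t(a, b, eps)
    # alpha is 0/0 for a perfect match with equal aspect ratios; the guard
    # resolves it to 0 (no aspect penalty)
    alpha = gamma / ((1.0 - v) + gamma + eps)
    loss = 1.0 - inner ** params.theta + corner + 0.5 * alpha * gamma
    extras = dict(inner=inner, d1=d1, d2=d2, gamma=gamma, alpha=alpha)
    return loss, extras


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def iou(a, b, eps: float = _EPS):
    """Intersection over union, Jaccard overlap of two boxes, in [0, 1]."""
    scalar = _is_scalar_pair(a, b)
    v, _ = _iou_t(_coerce(a), _coerce(b), eps)
    return _maybe_item(v, scalar)


def giou(a, b, eps: float = _EPS):
    """Generalized IoU: IoU minus the normalized dead area of the smallest
    enclosing box, in (-1, 1]."""
    scalar = _is_scalar_pair(a, b)
    v = _giou_t(_coerce(a), _coerce(b), eps)
    return _maybe_item(v, scalar)


def eiou_loss(a, b, eps: float = _EPS):
    """EIoU loss: 1 - IoU plus centre-distance, width and height penalties,
    each normalized by the enclosing box."""
    scalar = _is_scalar_pair(a, b)
    v = _eiou_t(_coerce(a), _coerce(b), eps)
    return _maybe_item(v, scalar)


def siou_terms(a, b, params: LossParams | None = None) -> SiouTerms:
    """The named intermediates of the SIoU loss for a single box pair."""
    params = params or LossParams()
    ta, tb = _coerce(a), _coerce(b)
    _, e = _siou_t(ta, tb, params.shape_theta, params.eps)

    def f(x):
        return float(x.data if isinstance(x, Tensor) else x)

    return SiouTerms(
        lambda_angle=f(e["lam"]), delta_dist=f(e["delta"]), omega_shape=f(e["omega"]),
        sigma_center=f(e["sigma"]), c_h=abs(f(e["dy"])), c_w=abs(f(e["dx"])),
        enclose_w=f(e["cw"]), enclose_h=f(e["ch"]),
        rho_x=f(e["rho_x"]), rho_y=f(e["rho_y"]), gamma_dist=f(e["gamma"]),
        w_w=f(e["w_w"]), w_h=f(e["w_h"]),
    )


def siou_loss(a, b, params: LossParams | None = None):
    """SIoU loss: 1 - IoU + (angle-weighted distance + shape penalty) / 2."""
    params = params or LossParams()
    scalar = _is_scalar_pair(a, b)
    v, _ = _siou_t(_coerce(a), _coerce(b), params.shape_theta, params.eps)
    return _maybe_item(v, scalar)


def inner_iou(a, b, ratio: float = 1.0, eps: float = _EPS):
    """IoU of both boxes rescaled about their own centres by `ratio`."""
    scalar = _is_scalar_pair(a, b)
    v = _inner_iou_t(_coerce(a), _coerce(b), ratio, eps)
    return _maybe_item(v, scalar)


def simiou_loss(a, b, params: LossParams | None = None,
                img_w: float = 1.0, img_h: float = 1.0,
                corner_norm: str = "half"):
    """The SIMIoU composite loss (see module docstring)."""
    params = params or LossParams()
    scalar = _is_scalar_pair(a, b)
    ta, tb = _coerce(a), _coerce(b)
    for t in (ta, tb):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite box coordinates")
    v, _ = _simiou_t(ta, tb, params, img_w, img_h, corner_norm)
    return _maybe_item(v, scalar)


def simiou_terms(a, b, params: LossParams | None = None,
                 img_w: float = 1.0, img_h: float = 1.0) -> SimiouTerms:
    params = params or LossParams()
    _, e = _simiou_t(_coerce(a), _coerce(b), params, img_w, img_h)

    def f(x):
        return float(x.data if isinstance(x, Tensor) else x)

    return SimiouTerms(inner_iou=f(e["inner"]), d1=f(e["d1"]), d2=f(e["d2"]),
                       gamma_aspect=f(e["gamma"]), alpha_balance=f(e["alpha"]),
                       img_w=1.0, img_h=1.0)


def focal_loss(p_t, params: LossParams | None = None):
    """Focal loss -alpha_t (1 - p_t)^gamma log(p_t) on the probability of
    the true class; down-weights easy examples, emphasizes rare classes."""
    params = params or LossParams()
    scalar = not isinstance(p_t, Tensor) and np.ndim(p_t) == 0
    p = p_t if isinstance(p_t, Tensor) else Tensor(np.asarray(p_t, dtype=float))
    p = nn.clip(p, params.eps, 1.0)
    v = -params.focal_alpha * (1.0 - p) ** params.focal_gamma * nn.log(p)
    return _maybe_item(v, scalar)


def elementwise_losses(y_true, y_pred, eps: float = _EPS) -> dict[str, float]:
    """MSE (mean squared error), L1 (summed absolute error), cross entropy
    and binary cross entropy between prediction and target vectors."""
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between targets and predictions")
    p = np.clip(yhat, eps, 1.0 - eps)
    out = {
        "mse": float(np.mean((y - yhat) ** 2)),
        "l1": float(np.sum(np.abs(y - yhat))),
        "ce": float(-np.sum(y * np.log(p))),
        "bce": float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))),
    }
    return out


# ---------------------------------------------------------------------------
# loss registry for training and the convergence harness
# ---------------------------------------------------------------------------

LOSS_NAMES = ("giou", "eiou", "siou", "simiou")


def box_loss(name: str, a, b, params: LossParams | None = None,
             img_w: float = 1.0, img_h: float = 1.0):
    """Evaluate a named box regression loss; `a`, `b` may be autodiff
    tensors of shape (..., 4), in which case the result carries gradients."""
    params = params or LossParams()
    if name == "giou":
        return 1.0 - _giou_t(_coerce(a), _coerce(b), params.eps)
    if name == "eiou":
        return _eiou_t(_coerce(a), _coerce(b), params.eps)
    if name == "siou":
        v, _ = _siou_t(_coerce(a), _coerce(b), params.shape_theta, params.eps)
        return v
    if name == "simiou":
        v, _ = _simiou_t(_coerce(a), _coerce(b), params, img_w, img_h)
        return v
    raise ValueError(f"unknown loss {name!r}; choose one of {LOSS_NAMES}")
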