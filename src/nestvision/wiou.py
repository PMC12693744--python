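"""Wise-IoU box-regression losses (v1 distance weighting, v3 focusing).

WIoU-v1 scales the plain IoU loss by a distance penalty computed from the
centers of the predicted and target boxes, normalised by the diagonal of
their smallest enclosing box:

    L_WIoU1 = exp( ((cx_p - cx_g)^2 + (cy_p - cy_g)^2) / (W_g^2 + H_g^2) ) * L_IoU

WIoU-v3 multiplies that by a dynamic, non-monotonic focusing coefficient.
The "anomaly degree" of an anchor is beta = L_IoU / mean_L_IoU, where the
mean is an exponential moving average over batches; the coefficient is

    r = beta / (delta * alpha^(beta - delta))

which equals 1 exactly at beta = delta, vanishes at beta = 0, and decays
for very anomalous anchors, so the loss concentrates gradient on
ordinary-quality anchors rather than on outliers.  The EMA denominator is a
constant with respect to any differentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .geometry import Box, enclosing_box, iou_loss

__all__ = [
    "WiouParams",
    "EmaState",
    "AnchorPair",
    "wiou_v1",
    "update_ema",
    "anomaly_degree",
    "focusing_coefficient",
    "wiou_v3",
    "focusing_table",
]


@dataclass(frozen=True)
class WiouParams:
    alpha: float = 1.9
    delta: float = 3.0
    ema_decay: float = 0.9

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not 0.0 < self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in (0, 1)")


@dataclass(frozen=True)
class EmaState:
    """Running mean of the batch IoU loss (the L_IoU bar of the anomaly ratio)."""

    mean_iou_loss: float = 0.0
    initialised: bool = False


@dataclass(frozen=True)
class AnchorPair:
    pred: Box
    target: Box


def wiou_v1(pair: AnchorPair) -> float:
    """Distance-weighted IoU loss of one anchor/target pair."""
    cxp, cyp = pair.pred.center
    cxg, cyg = pair.target.center
    enc = enclosing_box(pair.pred, pair.target)
    d2 = (cxp - cxg) ** 2 + (cyp - cyg) ** 2
    diag2 = enc.width**2 + enc.height**2
    return math.exp(d2 / diag2) * iou_loss(pair.pred, pair.target)


def update_ema(
    state: EmaState, batch_iou_losses: Sequence[float], params: WiouParams = WiouParams()
) -> EmaState:
    """Fold one batch of IoU losses into the running mean.

    The first batch initialises the mean; afterwards
    mean <- decay * mean + (1 - decay) * batch_mean.
    """
    if len(batch_iou_losses) == 0:
        raise ValueError("batch must be non-empty")
    if any(l < 0.0 or l > 1.0 for l in batch_iou_losses):
        raise ValueError("IoU losses must lie in [0, 1]")
    batch_mean = sum(batch_iou_losses) / len(batch_iou_losses)
    if not state.initialised:
        return EmaState(batch_mean, True)
    new_mean = params.ema_decay * state.mean_iou_loss + (1.0 - params.ema_decay) * batch_mean
    return replace(state, mean_iou_loss=new_mean)


def anomaly_degree(l_iou: float, state: EmaState) -> float:
    """beta = L_IoU / running mean; larger beta marks a poorer anchor."""
    if not state.initialised:
        raise ValueError("EMA state not initialised")
    if state.mean_iou_loss <= 0.0:
        raise ValueError("EMA mean must be positive to form the anomaly ratio")
    return l_iou / state.mean_iou_loss


def focusing_coefficient(beta: float, params: WiouParams = WiouParams()) -> float:
    """Non-monotonic gradient-gain coefficient r = beta / (delta * alpha^(beta - delta))."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return beta / (params.delta * params.alpha ** (beta - params.delta))


def wiou_v3(pair: AnchorPair, state: EmaState, params: WiouParams = WiouParams()) -> float:
    """Focused loss: r(beta) * L_WIoU1 for one anchor pair."""
    beta = anomaly_degree(iou_loss(pair.pred, pair.target), state)
    return focusing_coefficient(beta, params) * wiou_v1(pair)


def focusing_table(
    params: WiouParams = WiouParams(),
    beta_max: float = 10.0,
    step: float = 0.25,
) -> list[tuple[float, float]]:
    """(beta, r) pairs over a grid, for inspection / CSV dumps."""
    rows = []
    n = int(round(beta_max / step))
    for i in range(n + 1):
        beta = i * step
        rows.append((beta, focusing_coefficient(beta, params)))
    return rows
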