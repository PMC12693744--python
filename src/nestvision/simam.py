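"""SimAM: parameter-free per-neuron attention weights.

Each neuron t of a feature-map channel is scored by the minimal value of a
linear-discriminant energy that separates it from the other neurons of the
same channel (binary labels y_t = 1 for the target, y_o = -1 for the rest,
with an L2 regulariser on the weight):

    e_t(w, b) = (1 - (w t + b))^2
              + (1/(M-1)) * sum_{i != t} (-1 - (w x_i + b))^2
              + lambda * w^2

The minimum has a closed form driven only by the channel mean and variance,

    e*_t = 4 (sigma^2 + lambda) / ((t - mu)^2 + 2 sigma^2 + 2 lambda),

so a neuron far from its channel mean (low energy) is salient.  The
attention weight is sigmoid(1 / e*_t), strictly inside (0, 1), and the
module multiplies the feature map by these weights element-wise.  Nothing
is learned: identical input gives bit-identical output.

Exact vs. fast statistics: the energy for neuron t is defined over the
*other* M-1 neurons.  Using the exclude-target mean/variance makes the
closed form the exact minimiser; the common fast implementation reuses the
over-all-M statistics for every neuron (O(M) per channel instead of
O(M^2)).  Both are available via ``exclude_target``; the fast form is the
default applied by :func:`apply_simam`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimamConfig", "neuron_energy", "minimal_energy", "simam_weights", "apply_simam"]


@dataclass(frozen=True)
class SimamConfig:
    """lambda_reg: L2 regulariser of the energy; must be positive."""

    lambda_reg: float = 1e-4
    exclude_target: bool = False

    def __post_init__(self) -> None:
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be > 0")


def _as_channel(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("channel must be a non-empty 2-D grid")
    return arr


def neuron_energy(
    channel,
    target_index: tuple[int, int],
    w: float,
    b: float,
    cfg: SimamConfig = SimamConfig(),
) -> float:
    """Evaluate the energy e_t(w, b) for one target neuron.

    Labels are y_t = 1 for the target and y_o = -1 for every other neuron.
    """
    arr = _as_channel(channel)
    m = arr.size
    if m < 2:
        raise ValueError("channel must contain at least 2 neurons")
    r, c = target_index
    t = arr[r, c]
    mask = np.ones(arr.shape, dtype=bool)
    mask[r, c] = False
    others = arr[mask]
    e = (1.0 - (w * t + b)) ** 2
    e += np.mean((-1.0 - (w * others + b)) ** 2)
    e += cfg.lambda_reg * w * w
    return float(e)


def minimal_energy(channel, cfg: SimamConfig = SimamConfig()) -> np.ndarray:
    """Closed-form minimal energy e*_t for every neuron of the channel."""
    arr = _as_channel(channel)
    m = arr.size
    if m < 2:
        raise ValueError("channel must contain at least 2 neurons")
    lam = cfg.lambda_reg
    if cfg.exclude_target:
        # leave-one-out mean and biased variance of the other M-1 neurons
        total = arr.sum()
        mu = (total - arr) / (m - 1)
        sq_total = (arr**2).sum()
        var = (sq_total - arr**2) / (m - 1) - mu**2
        var = np.maximum(var, 0.0)
    else:
        mu = arr.mean()
        var = arr.var()
    return 4.0 * (var + lam) / ((arr - mu) ** 2 + 2.0 * var + 2.0 * lam)


def simam_weights(channel, cfg: SimamConfig = SimamConfig()) -> np.ndarray:
    """Attention weights sigmoid(1/e*_t); same shape as the channel."""
    e_star = minimal_energy(channel, cfg)
    return 1.0 / (1.0 + np.exp(-1.0 / e_star))


def apply_simam(feature_map, cfg: SimamConfig = SimamConfig()) -> np.ndarray:
    """Weight a C x H x W feature map channel-wise by its SimAM weights."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3 or fm.shape[0] < 1:
        raise ValueError("feature map must be C x H x W with C >= 1")
    out = np.empty_like(fm)
    for c in range(fm.shape[0]):
        out[c] = fm[c] * simam_weights(fm[c], cfg)
    return out
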