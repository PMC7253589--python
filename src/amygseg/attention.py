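"""Top-down attention-guided refinement on residual connections.

High-level feature maps carry semantic, categorical information; early
layers carry fine spatial detail.  The refinement unit computes one
coefficient per low-level channel from the high-level guide,

    alpha_c = sigmoid(ReLU(BN(Conv1x1x1(AvgPool(F_high))))),

rescales the low-level features channel-wise and adds them back to the
high-level stream after a 1x1x1 channel alignment d:

    F_high' = F_high + d(alpha * F_low).

Because the ReLU precedes the sigmoid, every coefficient lies in
[0.5, 1]: the unit can only attenuate relative emphasis, never flip the
sign of a channel.  Two placements are supported: "local" (each
residual block's own output guides its input) and "global" (the
deepest feature map guides every block).  A squeeze-and-excitation
(SE) unit, which recalibrates the low-level features from themselves,
is provided as a baseline.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

ATTENTION_MODES = ("none", "local", "global", "se")


def _he_conv(rng, c_out, c_in, k=1, dtype=np.float32):
    fan_in = c_in * k ** 3
    std = np.sqrt(2.0 / fan_in)
    return nn.Tensor(
        rng.normal(0.0, std, size=(c_out, c_in, k, k, k)).astype(dtype),
        requires_grad=True,
    )


class AttentionUnit:
    """One top-down refinement unit attached to a residual connection.

    guide_channels: channels of the high-level map supplying the guide
    (C''_guide); low_channels: channels being recalibrated (C');
    high_channels: channels of the stream the result is added to (C'').
    """

    def __init__(self, guide_channels, low_channels, high_channels, rng,
                 bn_momentum=0.1, bn_eps=1e-5):
        self.guide_channels = guide_channels
        self.low_channels = low_channels
        self.high_channels = high_channels
        self.bn_momentum = bn_momentum
        self.bn_eps = bn_eps
        self.w_squeeze = _he_conv(rng, low_channels, guide_channels)
        self.bn_gamma = nn.Tensor(np.ones(low_channels, np.float32), requires_grad=True)
        self.bn_beta = nn.Tensor(np.zeros(low_channels, np.float32), requires_grad=True)
        self.bn_mean = np.zeros(low_channels, np.float32)
        self.bn_var = np.ones(low_channels, np.float32)
        self.w_align = _he_conv(rng, high_channels, low_channels)

    def parameters(self):
        return [self.w_squeeze, self.bn_gamma, self.bn_beta, self.w_align]

    def state_arrays(self):
        return {
            "w_squeeze": self.w_squeeze,
            "bn_gamma": self.bn_gamma,
            "bn_beta": self.bn_beta,
            "w_align": self.w_align,
            "bn_mean": self.bn_mean,
            "bn_var": self.bn_var,
        }


class SEUnit:
    """Squeeze-and-excitation baseline: self-recalibration of the skip input."""

    def __init__(self, channels, rng, reduction=2):
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.reduction = reduction
        self.w1 = _he_conv(rng, hidden, channels)
        self.b1 = nn.Tensor(np.zeros(hidden, np.float32), requires_grad=True)
        self.w2 = _he_conv(rng, channels, hidden)
        self.b2 = nn.Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def state_arrays(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def coefficients(self, f_low):
        z = nn.global_avg_pool(f_low if isinstance(f_low, nn.Tensor) else nn.Tensor(f_low))
        z = nn.relu(nn.conv3d(z, self.w1, bias=self.b1))
        return nn.sigmoid(nn.conv3d(z, self.w2, bias=self.b2))


def attention_coefficients(f_high, unit, training=False):
    """Per-channel coefficients alpha in [0.5, 1] from the high-level guide.

    Returns a Tensor of shape (N, C', 1, 1, 1).
    """
    t = f_high if isinstance(f_high, nn.Tensor) else nn.Tensor(np.asarray(f_high))
    if t.data.ndim != 5:
        raise ShapeError("guide features must be rank 5 (N, C, X, Y, Z)")
    if t.data.shape[1] != unit.guide_channels:
        raise ShapeError(
            f"guide has {t.data.shape[1]} channels, unit expects {unit.guide_channels}"
        )
    z = nn.global_avg_pool(t)
    z = nn.conv3d(z, unit.w_squeeze)
    z = nn.batch_norm(z, unit.bn_gamma, unit.bn_beta, unit.bn_mean, unit.bn_var,
                      training=training, momentum=unit.bn_momentum, eps=unit.bn_eps)
    z = nn.relu(z)
    return nn.sigmoid(z)


def refine(f_high, f_low, unit, training=False, alpha=None):
    """F_high + d(alpha * F_low); alpha defaults to coefficients from F_high."""
    th = f_high if isinstance(f_high, nn.Tensor) else nn.Tensor(np.asarray(f_high))
    tl = f_low if isinstance(f_low, nn.Tensor) else nn.Tensor(np.asarray(f_low))
    if th.data.shape[2:] != tl.data.shape[2:]:
        raise ShapeError("low- and high-level features must share spatial shape")
    if tl.data.shape[1] != unit.low_channels:
        raise ShapeError(
            f"low-level features have {tl.data.shape[1]} channels, "
            f"unit expects {unit.low_channels}"
        )
    if alpha is None:
        alpha = attention_coefficients(th, unit, training=training)
    reweighted = nn.mul(alpha, tl)
    aligned = nn.conv3d(reweighted, unit.w_align)
    return nn.add(th, aligned)


def wire_attention(network, mode):
    """Return a copy of `network` re-wired with the requested attention mode.

    Backbone weights are shared with the input network; attention-unit
    weights are freshly initialized from the network's stored seed.
    """
    from .arch import build_network  # deferred: arch imports this module

    if mode not in ATTENTION_MODES:
        raise ConfigurationError(
            f"unknown attention mode {mode!r}; expected one of {ATTENTION_MODES}"
        )
    import dataclasses

    cfg = dataclasses.replace(network.config, attention_mode=mode)
    rewired = build_network(cfg, seed=network.seed)
    for name, arr in network.backbone_arrays().items():
        dst = rewired.backbone_arrays()[name]
        if isinstance(dst, nn.Tensor):
            dst.data[...] = arr.data if isinstance(arr, nn.Tensor) else arr
        else:
            dst[...] = arr
    return rewired
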