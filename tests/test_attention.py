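"""Top-down attention-guided refinement: formula, bounds, wiring, overhead."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amygseg import nn
from amygseg.arch import NetworkConfig, build_network, count_parameters
from amygseg.attention import (
    AttentionUnit,
    SEUnit,
    attention_coefficients,
    refine,
    wire_attention,
)
from amygseg.errors import ConfigurationError, ShapeError


def identity_unit(guide, low, high, rng_seed=0):
    """Unit with zero squeeze weights and identity batch-norm statistics."""
    unit = AttentionUnit(guide, low, high, np.random.default_rng(rng_seed))
    unit.w_squeeze.data[...] = 0.0
    unit.bn_mean[...] = 0.0
    unit.bn_var[...] = 1.0
    return unit


def test_zero_presigmoid_gives_half():
    unit = identity_unit(3, 2, 3)
    f_high = np.random.default_rng(1).normal(size=(2, 3, 4, 4, 4))
    alpha = attention_coefficients(f_high, unit).data
    assert alpha.shape == (2, 2, 1, 1, 1)
    assert np.allclose(alpha, 0.5)


def test_single_channel_closed_form():
    """alpha = sigmoid(max(0, g)) for a constant single-channel guide."""
    unit = identity_unit(1, 1, 1)
    unit.w_squeeze.data[...] = 1.0
    for g, expected in ((np.log(3.0), 0.75), (-2.0, 0.5), (0.0, 0.5)):
        f_high = np.full((1, 1, 3, 3, 3), g)
        alpha = attention_coefficients(f_high, unit).data
        assert alpha.ravel()[0] == pytest.approx(expected, abs=1e-5)


@settings(deadline=None, max_examples=60)
@given(seed=st.integers(0, 10_000))
def test_alpha_always_in_half_one(seed):
    """ReLU before sigmoid forces alpha into [0.5, 1] for any weights/input."""
    rng = np.random.default_rng(seed)
    guide, low, high = rng.integers(1, 6, size=3)
    unit = AttentionUnit(int(guide), int(low), int(high), rng)
    unit.w_squeeze.data[...] = rng.normal(size=unit.w_squeeze.data.shape) * 5
    unit.bn_beta.data[...] = rng.normal(size=low) * 5
    unit.bn_mean[...] = rng.normal(size=low)
    unit.bn_var[...] = np.abs(rng.normal(size=low)) + 0.1
    f_high = rng.normal(size=(2, int(guide), 3, 3, 3)) * 10
    alpha = attention_coefficients(f_high, unit).data
    assert np.all(alpha >= 0.5) and np.all(alpha <= 1.0)


def test_monotone_in_presigmoid_response():
    """Raising a channel's squeeze response never lowers its coefficient."""
    unit = identity_unit(1, 1, 1)
    unit.w_squeeze.data[...] = 1.0
    guides = np.linspace(-3, 3, 25)
    alphas = [
        attention_coefficients(np.full((1, 1, 2, 2, 2), g), unit).data.item()
        for g in guides
    ]
    assert all(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:]))


def test_refine_with_zero_alignment_returns_f_high_bit_exact():
    rng = np.random.default_rng(2)
    unit = AttentionUnit(3, 2, 3, rng)
    unit.w_align.data[...] = 0.0
    f_high = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32)
    f_low = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
    out = refine(f_high, f_low, unit).data
    assert np.array_equal(out, f_high)


def test_refine_reduces_to_scaled_residual_with_identity_alignment():
    rng = np.random.default_rng(3)
    unit = AttentionUnit(2, 2, 2, rng)
    unit.w_align.data[...] = np.eye(2).reshape(2, 2, 1, 1, 1)
    f_high = rng.normal(size=(1, 2, 3, 3, 3))
    f_low = rng.normal(size=(1, 2, 3, 3, 3))
    a = 0.8
    out = refine(f_high, f_low, unit,
                 alpha=nn.Tensor(np.full((1, 2, 1, 1, 1), a))).data
    assert np.allclose(out, f_high + a * f_low, atol=1e-6)


def test_refine_matches_hand_computation():
    """2-channel 2^3 case written out and evaluated element by element."""
    unit = identity_unit(2, 2, 2)
    unit.w_squeeze.data[...] = np.array([[1.0, 0.0], [0.0, -1.0]]
                                        ).reshape(2, 2, 1, 1, 1)
    unit.w_align.data[...] = np.array([[2.0, 1.0], [0.0, 1.0]]
                                      ).reshape(2, 2, 1, 1, 1)
    f_high = np.zeros((1, 2, 2, 2, 2))
    f_high[0, 0] = 1.0   # channel means: (1, -2)
    f_high[0, 1] = -2.0
    f_low = np.arange(16, dtype=float).reshape(1, 2, 2, 2, 2)
    # hand computation, plain numpy only:
    pre = np.array([1.0 * 1.0 + 0.0 * -2.0, 0.0 * 1.0 + -1.0 * -2.0])
    pre = pre / np.sqrt(1.0 + 1e-5)   # identity BN still divides by sqrt(1+eps)
    alpha = 1 / (1 + np.exp(-np.maximum(pre, 0.0)))
    rew = alpha.reshape(2, 1, 1, 1) * f_low[0]
    aligned = np.stack([2.0 * rew[0] + 1.0 * rew[1], rew[1]])
    expected = f_high[0] + aligned
    out = refine(f_high, f_low, unit).data
    assert np.allclose(out[0], expected, atol=1e-6)


def test_refine_shape_errors():
    unit = identity_unit(2, 2, 2)
    with pytest.raises(ShapeError):
        refine(np.zeros((1, 2, 4, 4, 4)), np.zeros((1, 2, 3, 3, 3)), unit)
    with pytest.raises(ShapeError):
        refine(np.zeros((1, 2, 4, 4, 4)), np.zeros((1, 3, 4, 4, 4)), unit)
    with pytest.raises(ShapeError):
        attention_coefficients(np.zeros((1, 5, 2, 2, 2)), unit)


# ---------------------------------------------------------------------------
# wiring into the backbone

def test_mode_none_matches_plain_backbone(tiny_config):
    net = build_network(tiny_config, seed=4)
    rewired = wire_attention(net, "none")
    x = np.random.default_rng(5).normal(size=(1, 1, 6, 6, 6)).astype(np.float32)
    a = net.logits(x).data
    b = rewired.logits(x).data
    assert np.allclose(a, b)


def test_local_mode_places_one_unit_per_block():
    net = build_network(NetworkConfig(attention_mode="local"), seed=0)
    units = [blk.attention for blk in net.blocks]
    assert len(units) == 4
    assert all(isinstance(u, AttentionUnit) for u in units)


def test_unknown_mode_rejected(tiny_config):
    net = build_network(tiny_config, seed=0)
    with pytest.raises(ConfigurationError):
        wire_attention(net, "spatial")


def test_se_and_local_overheads_match_hand_count(tiny_config):
    base = count_parameters(build_network(tiny_config, seed=0))
    cfg_local = dataclasses.replace(tiny_config, attention_mode="local")
    cfg_se = dataclasses.replace(tiny_config, attention_mode="se")
    local = count_parameters(build_network(cfg_local, seed=0))
    se = count_parameters(build_network(cfg_se, seed=0))
    # tiny config: one block over layers 2-3, c_low = 4, c_high = 6.
    # local unit: squeeze 6*4 + BN 2*4 + align 4*6 = 56, replacing the 4*6 proj
    assert local - base == 56 - 24
    # SE (reduction 2): 4*2 + 2 + 2*4 + 4 = 22 extra on top of the plain skip
    assert se - base == 22
    assert local != se


def test_local_and_global_overheads_agree_at_printed_precision():
    """Table-2-style check: both variants add ~1.6% parameters."""
    base = count_parameters(build_network(NetworkConfig(attention_mode="none")))
    rel = {}
    for mode in ("local", "global"):
        n = count_parameters(build_network(NetworkConfig(attention_mode=mode)))
        rel[mode] = 100 * (n - base) / base
    assert abs(rel["local"] - rel["global"]) < 0.2
    assert 1.0 < rel["local"] < 2.0 and 1.0 < rel["global"] < 2.0


def test_global_mode_runs_and_differs_from_local():
    cfg = NetworkConfig(layer_widths=(3, 3, 4), dilations_dilated=(1, 2, 1),
                        dilations_standard=(1, 1, 1), n_classes=3,
                        residual_blocks=((2, 3),), attention_mode="global")
    net = build_network(cfg, seed=6)
    x = np.random.default_rng(7).normal(size=(1, 1, 6, 6, 6)).astype(np.float32)
    out_g = net.logits(x).data
    out_l = wire_attention(net, "local").logits(x).data
    assert out_g.shape == out_l.shape == (1, 3, 6, 6, 6)
    assert not np.allclose(out_g, out_l)


def test_se_unit_coefficients_depend_only_on_low_features():
    rng = np.random.default_rng(8)
    se = SEUnit(4, rng, reduction=2)
    f_low = rng.normal(size=(2, 4, 3, 3, 3))
    a1 = se.coefficients(f_low).data
    assert a1.shape == (2, 4, 1, 1, 1)
    assert np.all((a1 > 0) & (a1 < 1))  # plain sigmoid range, no ReLU floor
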