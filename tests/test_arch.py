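"""Backbone architecture: receptive fields, construction, counting, checkpoints."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amygseg import nn
from amygseg.arch import (
    NetworkConfig,
    build_network,
    count_parameters,
    dual_branch_layer,
    effective_kernel_size,
    forward,
    he_sample,
    he_std,
    load_checkpoint,
    receptive_field,
    save_checkpoint,
)
from amygseg.errors import ConfigurationError, DataError, ShapeError

DILATED_SCHEDULE = (1, 2, 4, 2, 8, 2, 4, 2, 1)


# ---------------------------------------------------------------------------
# receptive-field analytics

@pytest.mark.parametrize("k,d,expected", [(3, 2, 5), (3, 1, 3), (3, 8, 17)])
def test_effective_kernel_size(k, d, expected):
    assert effective_kernel_size(k, d) == expected


@pytest.mark.parametrize("k,d", [(0, 1), (3, 0), (-3, 2), (4, 1)])
def test_effective_kernel_size_rejects_bad_input(k, d):
    with pytest.raises(ValueError):
        effective_kernel_size(k, d)


@pytest.mark.parametrize(
    "dilations,expected",
    [
        ((1,) * 9, 19),               # standard branch
        (DILATED_SCHEDULE, 53),          # dilated branch
        ((), 1),                      # no layers: one voxel
        ((1,) * 7 + (2,) * 6 + (4,) * 6, 87),  # serial comparator stack
    ],
)
def test_receptive_field(dilations, expected):
    assert receptive_field(dilations, 3) == expected


@settings(deadline=None, max_examples=50)
@given(
    dilations=st.lists(st.integers(1, 8), min_size=1, max_size=12),
    which=st.integers(0, 100),
)
def test_receptive_field_strictly_increasing(dilations, which):
    i = which % len(dilations)
    base = receptive_field(dilations, 3)
    bumped = list(dilations)
    bumped[i] += 1
    assert receptive_field(bumped, 3) > base
    assert receptive_field(dilations + [1], 3) > base  # deeper chain sees more


# ---------------------------------------------------------------------------
# configuration

def test_default_config_branch_receptive_fields():
    cfg = NetworkConfig()
    rf_dilated = receptive_field(cfg.dilations_dilated, cfg.kernel_edge)
    rf_standard = receptive_field(cfg.dilations_standard, cfg.kernel_edge)
    assert (rf_standard, rf_dilated) == (19, 53)
    assert rf_dilated > rf_standard


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        NetworkConfig(layer_widths=(30,) * 9, dilations_dilated=(1,) * 8)
    with pytest.raises(ConfigurationError):
        NetworkConfig(residual_blocks=((2, 3), (3, 5)))  # overlapping
    with pytest.raises(ConfigurationError):
        NetworkConfig(residual_blocks=((2, 30),))  # beyond layer count
    with pytest.raises(ConfigurationError):
        NetworkConfig(n_classes=1)
    with pytest.raises(ConfigurationError):
        NetworkConfig(attention_mode="spatial")


def test_config_text_round_trip_is_lossless(tiny_config):
    for cfg in (NetworkConfig(), tiny_config,
                dataclasses.replace(NetworkConfig(), attention_mode="se",
                                    se_reduction=4)):
        assert NetworkConfig.from_text(cfg.to_text()) == cfg


# ---------------------------------------------------------------------------
# construction and forward contract

def test_build_network_default_widths():
    net = build_network(NetworkConfig(), seed=0)
    widths = [br.weight.data.shape[0] for br in net.dilated]
    assert widths == [30, 30, 40, 40, 40, 40, 50, 50, 50]
    assert all(
        s.weight.data.shape[0] == d.weight.data.shape[0]
        for s, d in zip(net.standard, net.dilated)
    )


def test_build_tiny_config_branch_receptive_fields():
    cfg = NetworkConfig(layer_widths=(2, 2, 2), dilations_dilated=(1, 2, 1),
                        dilations_standard=(1, 1, 1), residual_blocks=(),
                        attention_mode="none")
    build_network(cfg)
    assert receptive_field(cfg.dilations_dilated, 3) == 9
    assert receptive_field(cfg.dilations_standard, 3) == 7


def test_dual_branch_layer_zero_weights_give_zero_output(tiny_network):
    net = tiny_network
    for br in (net.dilated[0], net.standard[0]):
        br.weight.data[...] = 0
        br.gamma.data[...] = 0
        br.beta.data[...] = 0
    x = np.random.default_rng(0).normal(size=(1, 1, 6, 6, 6)).astype(np.float32)
    out = dual_branch_layer(x, 0, net)
    assert out.shape == (1, 4, 6, 6, 6)
    assert np.all(out == 0)


def test_dual_branch_layer_standard_zeroed_equals_dilated_only(tiny_network):
    net = tiny_network
    x = np.random.default_rng(1).normal(size=(2, 1, 6, 6, 6)).astype(np.float32)
    net.standard[0].gamma.data[...] = 0
    net.standard[0].beta.data[...] = 0
    fused = dual_branch_layer(x, 0, net)
    br = net.dilated[0]
    alone = nn.relu(
        nn.batch_norm(
            nn.conv3d(nn.Tensor(x), br.weight,
                      dilation=net.config.dilations_dilated[0]),
            br.gamma, br.beta, br.r_mean.copy(), br.r_var.copy(),
            training=False, update_running=False,
        )
    ).data
    assert np.allclose(fused, alone, atol=1e-6)


def test_dual_branch_layer_fusion_commutes(tiny_network):
    """Swapping the branch summands (weights and dilations) leaves output unchanged."""
    net = tiny_network
    x = np.random.default_rng(2).normal(size=(1, 1, 5, 5, 5)).astype(np.float32)
    before = dual_branch_layer(x, 0, net)
    net.dilated[0], net.standard[0] = net.standard[0], net.dilated[0]
    cfg = net.config
    dd, ds = list(cfg.dilations_dilated), list(cfg.dilations_standard)
    dd[0], ds[0] = ds[0], dd[0]
    net.config = dataclasses.replace(cfg, dilations_dilated=tuple(dd),
                                     dilations_standard=tuple(ds))
    after = dual_branch_layer(x, 0, net)
    assert np.allclose(before, after, atol=1e-6)


def test_dual_branch_layer_channel_mismatch(tiny_network):
    with pytest.raises(ShapeError):
        dual_branch_layer(np.zeros((1, 3, 4, 4, 4), np.float32), 0, tiny_network)


@pytest.mark.parametrize("edge", [1, 4, 9])
def test_forward_preserves_shape_and_normalizes(tiny_network, edge):
    x = np.random.default_rng(3).normal(size=(1, 1, edge, edge, edge))
    probs = forward(tiny_network, x.astype(np.float32))
    assert probs.shape == (1, 3, edge, edge, edge)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_forward_identical_patches_identical_outputs(tiny_network):
    x = np.random.default_rng(4).normal(size=(1, 1, 7, 7, 7)).astype(np.float32)
    batch = np.concatenate([x, x], axis=0)
    probs = forward(tiny_network, batch)
    assert np.array_equal(probs[0], probs[1])


def test_forward_rejects_non_finite_input(tiny_network):
    x = np.full((1, 1, 4, 4, 4), np.nan, dtype=np.float32)
    with pytest.raises(DataError):
        forward(tiny_network, x)


def test_residual_skips_carry_gradient_to_first_layer(tiny_network):
    """Gradient reaches the first layer through the live skip connections."""
    x = np.random.default_rng(5).normal(size=(1, 1, 6, 6, 6)).astype(np.float32)
    logits = tiny_network.logits(x, training=True)
    labels = np.zeros((1, 6, 6, 6), dtype=np.int64)
    loss = nn.softmax_cross_entropy(logits, labels)
    loss.backward()
    g = tiny_network.dilated[0].weight.grad
    assert g is not None and np.any(g != 0)


# ---------------------------------------------------------------------------
# parameter counting and initialization

def test_count_parameters_hand_example():
    # one dual layer (width 2, 1 input channel), per-branch BN, 2-class head:
    # 2*(27*1*2) + 2*(2*2) + (2*2 + 2) = 122
    cfg = NetworkConfig(layer_widths=(2,), dilations_dilated=(1,),
                        dilations_standard=(1,), n_classes=2,
                        residual_blocks=(), attention_mode="none")
    assert count_parameters(build_network(cfg)) == 122


def test_count_parameters_head_only():
    cfg = NetworkConfig(layer_widths=(), dilations_dilated=(),
                        dilations_standard=(), n_classes=2,
                        residual_blocks=(), attention_mode="none")
    assert count_parameters(build_network(cfg)) == 2 * 1 + 2


def test_attention_adds_parameters(tiny_config):
    base = count_parameters(build_network(tiny_config))
    local = count_parameters(
        build_network(dataclasses.replace(tiny_config, attention_mode="local"))
    )
    assert local > base


def test_he_init_standard_deviation():
    assert he_std(2) == pytest.approx(1.0)
    assert he_std(27) == pytest.approx(np.sqrt(2 / 27))
    with pytest.raises(ValueError):
        he_std(0)


def test_he_init_monte_carlo():
    rng = np.random.default_rng(99)
    samples = he_sample((100_000,), 27, rng)
    assert abs(samples.mean()) < 0.01
    assert abs(samples.std() / np.sqrt(2 / 27) - 1) < 0.02


# ---------------------------------------------------------------------------
# checkpointing

def test_checkpoint_round_trip_bit_exact(tiny_network, tmp_path):
    x = np.random.default_rng(6).normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
    before = forward(tiny_network, x)
    rng = np.random.default_rng(42)
    rng.normal(size=10)  # advance the stream so the state is non-trivial
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_network, path, rng=rng)
    restored, rng2 = load_checkpoint(path)
    assert restored.config == tiny_network.config
    after = forward(restored, x)
    assert np.array_equal(before, after)
    assert np.array_equal(rng.normal(size=5), rng2.normal(size=5))
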