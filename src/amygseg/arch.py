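"""Dual-branch dilated residual 3D fully convolutional backbone.

Every layer runs two parallel 3x3x3 convolution branches over the same
input: a *standard* branch at dilation 1, whose stacked receptive field
stays small (19^3 for the default nine-layer stack) so that predictions
are driven by voxels near the target structures, and a *dilated* branch
whose schedule {1,2,4,2,8,2,4,2,1} grows the receptive field to 53^3 to
supply surrounding context.  Each branch applies convolution, batch
normalization and ReLU, and the branch outputs are fused by element-wise
summation:

    F_l = F_dilated + F_standard.

Residual connections group the layers into blocks for serial feature
reuse, optionally enhanced by the top-down attention-guided refinement
units of :mod:`amygseg.attention`.  A 1x1x1 convolution maps the final
features to per-class scores.

All convolutions are stride-1 and zero-padded, so spatial shape is
preserved end to end; a network trained on 59^3 patches can segment
105^3 tiles (or any other size) unchanged.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import re

import numpy as np

from . import nn
from .attention import ATTENTION_MODES, AttentionUnit, SEUnit, attention_coefficients, refine
from .errors import ConfigurationError, DataError, ShapeError

BRANCH_MODES = ("dual", "dilated", "standard")

DEFAULT_LAYER_WIDTHS = (30, 30, 40, 40, 40, 40, 50, 50, 50)
DEFAULT_DILATIONS_DILATED = (1, 2, 4, 2, 8, 2, 4, 2, 1)
DEFAULT_RESIDUAL_BLOCKS = ((2, 3), (4, 5), (6, 7), (8, 9))


# ---------------------------------------------------------------------------
# receptive-field analytics

def effective_kernel_size(kernel_edge: int, dilation: int) -> int:
    """Edge length of a dilated kernel's footprint.

    Dilation spaces the kernel taps (dilation - 1) voxels apart, so a
    k^3 kernel at rate D covers k + (k - 1)(D - 1) voxels per axis;
    e.g. a 3^3 kernel at D = 2 acts as a 5^3 kernel.
    """
    if kernel_edge < 1 or dilation < 1:
        raise ValueError("kernel_edge and dilation must be positive")
    if kernel_edge % 2 != 1:
        raise ValueError("kernel_edge must be odd")
    return kernel_edge + (kernel_edge - 1) * (dilation - 1)


def receptive_field(dilations, kernel_edge: int = 3) -> int:
    """Receptive-field edge of a serial chain of k^3 convolutions.

    Each stride-1 layer adds (k - 1) * D voxels; 1x1x1 layers add
    nothing.  An empty chain sees a single voxel.
    """
    if kernel_edge < 1 or kernel_edge % 2 != 1:
        raise ValueError("kernel_edge must be odd and positive")
    dilations = list(dilations)
    if any(d < 1 for d in dilations):
        raise ValueError("dilations must be >= 1")
    return 1 + (kernel_edge - 1) * sum(dilations)


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class NetworkConfig:
    """Full architectural description of the network."""

    layer_widths: tuple = DEFAULT_LAYER_WIDTHS
    dilations_dilated: tuple = DEFAULT_DILATIONS_DILATED
    dilations_standard: tuple = None  # defaults to all ones
    kernel_edge: int = 3
    n_classes: int = 9
    attention_mode: str = "local"
    residual_blocks: tuple = DEFAULT_RESIDUAL_BLOCKS
    branch_mode: str = "dual"
    se_reduction: int = 2

    def __post_init__(self):
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        self.dilations_dilated = tuple(int(d) for d in self.dilations_dilated)
        if self.dilations_standard is None:
            self.dilations_standard = (1,) * len(self.layer_widths)
        self.dilations_standard = tuple(int(d) for d in self.dilations_standard)
        self.residual_blocks = tuple((int(a), int(b)) for a, b in self.residual_blocks)
        self.validate()

    def validate(self):
        n = len(self.layer_widths)
        if not (len(self.dilations_dilated) == len(self.dilations_standard) == n):
            raise ConfigurationError(
                "layer_widths, dilations_dilated and dilations_standard must have "
                f"equal length (got {n}, {len(self.dilations_dilated)}, "
                f"{len(self.dilations_standard)})"
            )
        if any(w < 1 for w in self.layer_widths):
            raise ConfigurationError("layer widths must be positive")
        if any(d < 1 for d in self.dilations_dilated + self.dilations_standard):
            raise ConfigurationError("dilations must be >= 1")
        if self.kernel_edge < 1 or self.kernel_edge % 2 != 1:
            raise ConfigurationError("kernel_edge must be odd and positive")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.attention_mode not in ATTENTION_MODES:
            raise ConfigurationError(f"unknown attention_mode {self.attention_mode!r}")
        if self.branch_mode not in BRANCH_MODES:
            raise ConfigurationError(f"unknown branch_mode {self.branch_mode!r}")
        prev_end = 0
        for a, b in self.residual_blocks:
            if a > b:
                raise ConfigurationError(f"residual block ({a}, {b}) is reversed")
            if a <= prev_end:
                raise ConfigurationError("residual blocks must be ordered and disjoint")
            if b > n:
                raise ConfigurationError(
                    f"residual block ({a}, {b}) exceeds layer count {n}"
                )
            prev_end = b
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")

    # -- plain-text serialization (key: value, lists bracketed) -------------

    def to_text(self) -> str:
        buf = _io.StringIO()
        buf.write(f"layer_widths: [{', '.join(map(str, self.layer_widths))}]\n")
        buf.write(f"dilations_dilated: [{', '.join(map(str, self.dilations_dilated))}]\n")
        buf.write(f"dilations_standard: [{', '.join(map(str, self.dilations_standard))}]\n")
        buf.write(f"kernel_edge: {self.kernel_edge}\n")
        buf.write(f"n_classes: {self.n_classes}\n")
        buf.write(f"attention_mode: {self.attention_mode}\n")
        blocks = ", ".join(f"{a}-{b}" for a, b in self.residual_blocks)
        buf.write(f"residual_blocks: [{blocks}]\n")
        buf.write(f"branch_mode: {self.branch_mode}\n")
        buf.write(f"se_reduction: {self.se_reduction}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "NetworkConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()

        def int_list(s):
            s = s.strip()
            if not (s.startswith("[") and s.endswith("]")):
                raise ConfigurationError(f"expected a bracketed list, got {s!r}")
            inner = s[1:-1].strip()
            return tuple(int(x) for x in inner.split(",")) if inner else ()

        def block_list(s):
            inner = s.strip()[1:-1].strip()
            if not inner:
                return ()
            out = []
            for item in inner.split(","):
                m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", item)
                if not m:
                    raise ConfigurationError(f"bad residual block {item!r}")
                out.append((int(m.group(1)), int(m.group(2))))
            return tuple(out)

        return cls(
            layer_widths=int_list(kv["layer_widths"]),
            dilations_dilated=int_list(kv["dilations_dilated"]),
            dilations_standard=int_list(kv["dilations_standard"]),
            kernel_edge=int(kv["kernel_edge"]),
            n_classes=int(kv["n_classes"]),
            attention_mode=kv["attention_mode"],
            residual_blocks=block_list(kv["residual_blocks"]),
            branch_mode=kv.get("branch_mode", "dual"),
            se_reduction=int(kv.get("se_reduction", 2)),
        )


# ---------------------------------------------------------------------------
# weight initialization

def he_std(fan_in: int) -> float:
    """Standard deviation sqrt(2 / fan_in) of the He initializer."""
    if fan_in < 1:
        raise ValueError("fan_in must be >= 1")
    return float(np.sqrt(2.0 / fan_in))


def he_sample(shape, fan_in: int, rng) -> np.ndarray:
    """Zero-mean Gaussian weights with std sqrt(2 / fan_in).

    Biases and batch-norm shifts start at zero and are not sampled here.
    """
    return rng.normal(0.0, he_std(fan_in), size=shape)


# ---------------------------------------------------------------------------
# network

class _BranchParams:
    def __init__(self, c_in, c_out, k, rng):
        self.weight = nn.Tensor(
            he_sample((c_out, c_in, k, k, k), c_in * k ** 3, rng).astype(np.float32),
            requires_grad=True,
        )
        self.gamma = nn.Tensor(np.ones(c_out, np.float32), requires_grad=True)
        self.beta = nn.Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self.r_mean = np.zeros(c_out, np.float32)
        self.r_var = np.ones(c_out, np.float32)

    def parameters(self):
        return [self.weight, self.gamma, self.beta]


class _Block:
    """A residual block: layer indices [start, end] (0-based, inclusive)."""

    def __init__(self, start, end):
        self.start = start
        self.end = end
        self.proj = None        # 1x1x1 projection Tensor or None (identity)
        self.attention = None   # AttentionUnit, SEUnit or None

    def parameters(self):
        params = [] if self.proj is None else [self.proj]
        if self.attention is not None:
            params += self.attention.parameters()
        return params


class Network:
    """The assembled model; built by :func:`build_network`."""

    bn_momentum = 0.1
    bn_eps = 1e-5

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        k = config.kernel_edge
        widths = config.layer_widths
        self.dilated = []
        self.standard = []
        c_in = 1
        for c_out in widths:
            self.dilated.append(
                _BranchParams(c_in, c_out, k, rng)
                if config.branch_mode in ("dual", "dilated") else None
            )
            self.standard.append(
                _BranchParams(c_in, c_out, k, rng)
                if config.branch_mode in ("dual", "standard") else None
            )
            c_in = c_out
        self.blocks = []
        for a, b in config.residual_blocks:
            blk = _Block(a - 1, b - 1)
            c_low = 1 if blk.start == 0 else widths[blk.start - 1]
            c_high = widths[blk.end]
            mode = config.attention_mode
            if mode in ("local", "global"):
                guide = c_high if mode == "local" else widths[-1]
                blk.attention = AttentionUnit(guide, c_low, c_high, rng,
                                              bn_momentum=self.bn_momentum,
                                              bn_eps=self.bn_eps)
            else:
                if mode == "se":
                    blk.attention = SEUnit(c_low, rng, reduction=config.se_reduction)
                if c_low != c_high:
                    blk.proj = nn.Tensor(
                        he_sample((c_high, c_low, 1, 1, 1), c_low, rng).astype(np.float32),
                        requires_grad=True,
                    )
            self.blocks.append(blk)
        c_last = widths[-1] if widths else 1
        n_cls = config.n_classes
        self.head_w = nn.Tensor(
            he_sample((n_cls, c_last, 1, 1, 1), c_last, rng).astype(np.float32),
            requires_grad=True,
        )
        self.head_b = nn.Tensor(np.zeros(n_cls, np.float32), requires_grad=True)
        # execution plan: ("layer", i) for stem layers, ("block", b) for blocks
        self.segments = []
        in_block = {}
        for b, blk in enumerate(self.blocks):
            for i in range(blk.start, blk.end + 1):
                in_block[i] = b
        i = 0
        while i < len(widths):
            b = in_block.get(i)
            if b is None:
                self.segments.append(("layer", i))
                i += 1
            else:
                self.segments.append(("block", b))
                i = self.blocks[b].end + 1

    # -- parameter bookkeeping ----------------------------------------------

    def parameters(self):
        params = []
        for br in self.dilated + self.standard:
            if br is not None:
                params += br.parameters()
        for blk in self.blocks:
            params += blk.parameters()
        params += [self.head_w, self.head_b]
        return params

    def named_arrays(self):
        """All weight and running-statistic arrays, keyed for checkpointing."""
        out = {}
        for tag, branch in (("dil", self.dilated), ("std", self.standard)):
            for i, br in enumerate(branch):
                if br is None:
                    continue
                out[f"{tag}{i}.weight"] = br.weight
                out[f"{tag}{i}.gamma"] = br.gamma
                out[f"{tag}{i}.beta"] = br.beta
                out[f"{tag}{i}.r_mean"] = br.r_mean
                out[f"{tag}{i}.r_var"] = br.r_var
        for b, blk in enumerate(self.blocks):
            if blk.proj is not None:
                out[f"block{b}.proj"] = blk.proj
            if blk.attention is not None:
                for name, arr in blk.attention.state_arrays().items():
                    out[f"block{b}.att.{name}"] = arr
        out["head.weight"] = self.head_w
        out["head.bias"] = self.head_b
        return out

    def backbone_arrays(self):
        """Arrays independent of the attention wiring (shared across modes)."""
        return {
            name: arr for name, arr in self.named_arrays().items()
            if ".att." not in name and not name.endswith(".proj")
        }

    # -- forward pass ---------------------------------------------------------

    def _branch(self, t, params, dilation, training, update_running):
        z = nn.conv3d(t, params.weight, dilation=dilation)
        z = nn.batch_norm(z, params.gamma, params.beta, params.r_mean, params.r_var,
                          training=training, momentum=self.bn_momentum,
                          eps=self.bn_eps, update_running=update_running)
        return nn.relu(z)

    def apply_layer(self, t, i, training=False, update_running=None):
        if update_running is None:
            update_running = training
        cfg = self.config
        out = None
        if self.dilated[i] is not None:
            out = self._branch(t, self.dilated[i], cfg.dilations_dilated[i],
                               training, update_running)
        if self.standard[i] is not None:
            s = self._branch(t, self.standard[i], cfg.dilations_standard[i],
                             training, update_running)
            out = s if out is None else nn.add(out, s)
        return out

    def _block_body(self, t, blk, training, update_running):
        for i in range(blk.start, blk.end + 1):
            t = self.apply_layer(t, i, training, update_running)
        return t

    def _skip(self, f_low, blk, training, update_running, guide):
        """The value added to the block body's output."""
        att = blk.attention
        if isinstance(att, AttentionUnit):
            g = guide  # None means local: guide is supplied by caller per block
            alpha = attention_coefficients(g, att, training=training)
            reweighted = nn.mul(alpha, f_low)
            return nn.conv3d(reweighted, att.w_align)
        if isinstance(att, SEUnit):
            alpha = att.coefficients(f_low)
            f_low = nn.mul(alpha, f_low)
        if blk.proj is not None:
            return nn.conv3d(f_low, blk.proj)
        return f_low

    def _features(self, t, training, update_running, guide_map):
        for kind, idx in self.segments:
            if kind == "layer":
                t = self.apply_layer(t, idx, training, update_running)
            else:
                blk = self.blocks[idx]
                f_low = t
                f_high = self._block_body(t, blk, training, update_running)
                if isinstance(blk.attention, AttentionUnit):
                    guide = guide_map[idx] if guide_map is not None else f_high
                    t = nn.add(f_high, self._skip(f_low, blk, training,
                                                  update_running, guide))
                else:
                    t = nn.add(f_high, self._skip(f_low, blk, training,
                                                  update_running, None))
        return t

    def _features_plain(self, t, training):
        """Attention-free pass (align convs serve as projections) for the
        global mode's top-down guide."""
        for kind, idx in self.segments:
            if kind == "layer":
                t = self.apply_layer(t, idx, training, update_running=False)
            else:
                blk = self.blocks[idx]
                f_low = t
                f_high = self._block_body(t, blk, training, update_running=False)
                if isinstance(blk.attention, AttentionUnit):
                    skip = nn.conv3d(f_low, blk.attention.w_align)
                elif blk.proj is not None:
                    skip = nn.conv3d(f_low, blk.proj)
                else:
                    skip = f_low
                t = nn.add(f_high, skip)
        return t

    def logits(self, x, training=False):
        """Class scores for a batch (N, 1, X, Y, Z); returns a Tensor."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None, None]
        if x.ndim != 5:
            raise ShapeError("input must be (N, 1, X, Y, Z) or a bare 3D array")
        if x.shape[1] != 1:
            raise ShapeError("input patches must be single-channel")
        if not np.all(np.isfinite(x)):
            raise DataError("input contains non-finite values")
        t = nn.Tensor(x.astype(np.float32, copy=False))
        guide_map = None
        if self.config.attention_mode == "global" and self.blocks:
            deepest = self._features_plain(t, training)
            guide_map = {b: deepest for b in range(len(self.blocks))}
        feats = self._features(t, training, training, guide_map)
        return nn.conv3d(feats, self.head_w, bias=self.head_b)


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Build the network with He-initialized weights (one seed controls all)."""
    return Network(config, seed=seed)


def dual_branch_layer(x, layer_index: int, network: Network, training: bool = False):
    """Run one dual-branch layer: per-branch conv + BN + ReLU, then sum.

    `x` is a rank-5 feature volume (or Tensor); returns a numpy array of
    the same spatial shape with layer_widths[layer_index] channels.
    """
    expected = 1 if layer_index == 0 else network.config.layer_widths[layer_index - 1]
    data = x.data if isinstance(x, nn.Tensor) else np.asarray(x)
    if data.shape[1] != expected:
        raise ShapeError(
            f"layer {layer_index} expects {expected} input channels, got {data.shape[1]}"
        )
    out = network.apply_layer(nn.Tensor(data), layer_index, training=training,
                              update_running=False)
    return out.data


def forward(network: Network, patch) -> np.ndarray:
    """Per-voxel class probabilities for a single-channel patch.

    Output shape: (N, n_classes, X, Y, Z); channels sum to one per voxel.
    """
    with nn.no_grad():
        logits = network.logits(patch, training=False)
    return nn.softmax(logits.data, axis=1)


def count_parameters(network: Network) -> int:
    """Total number of trainable weights (running BN statistics excluded)."""
    return int(sum(p.data.size for p in network.parameters()))


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(network: Network, path, rng=None):
    """Bundle all weights, the config, and optional RNG state into an .npz.

    save -> load reproduces forward outputs bit-exactly: arrays are
    stored verbatim and the config round-trips through its text form.
    """
    arrays = {}
    for name, arr in network.named_arrays().items():
        arrays[name] = arr.data if isinstance(arr, nn.Tensor) else arr
    meta = {"config": network.config.to_text(), "seed": network.seed}
    if rng is not None:
        state = rng.bit_generator.state
        meta["rng"] = json.dumps(state)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (network, rng_or_None)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
        config = NetworkConfig.from_text(meta["config"])
        network = Network(config, seed=meta.get("seed", 0))
        for name, arr in network.named_arrays().items():
            stored = z[name]
            if isinstance(arr, nn.Tensor):
                arr.data = stored.copy()
            else:
                arr[...] = stored
        rng = None
        if "rng" in meta:
            rng = np.random.default_rng(0)
            rng.bit_generator.state = json.loads(meta["rng"])
    return network, rng
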