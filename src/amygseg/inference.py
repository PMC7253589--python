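"""Whole-volume segmentation by tiled forward passes and stitching.

The network is fully convolutional, so a volume of any size can be
segmented by sliding fixed-size tiles over it.  Predictions within
`margin` voxels of a tile face see zero-padded (context-starved) input,
so each tile contributes only its central region; with stride =
patch_edge - 2*margin the central regions partition the volume and the
stitched result is independent of tile order.  The default margin,
(53 - 1) / 2 = 26, discards everything inside the dilated branch's
receptive-field radius.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError
from .io import LabelMap, VolumeImage

__all__ = ["TilingPlan", "plan_tiles", "segment_volume"]

DEFAULT_PATCH_EDGE = 105
DEFAULT_MARGIN = 26  # (53 - 1) / 2: dilated-branch receptive-field radius


@dataclasses.dataclass(frozen=True)
class TilingPlan:
    volume_shape: tuple
    patch_edge: int
    margin: int
    stride: int
    pad_after: tuple          # per-axis padding beyond the leading margin
    origins: tuple            # tile origins in padded coordinates


def plan_tiles(volume_shape, patch_edge: int = DEFAULT_PATCH_EDGE,
               margin: int = DEFAULT_MARGIN) -> TilingPlan:
    """Tile origins such that margin-cropped tile centers partition the volume."""
    volume_shape = tuple(int(s) for s in volume_shape)
    if len(volume_shape) != 3 or any(s < 1 for s in volume_shape):
        raise ConfigurationError("volume_shape must be three positive integers")
    if margin < 0 or patch_edge <= 2 * margin:
        raise ConfigurationError(
            f"need patch_edge > 2*margin (got {patch_edge}, margin {margin})"
        )
    stride = patch_edge - 2 * margin
    n_tiles = [max(1, -(-s // stride)) for s in volume_shape]
    pad_after = tuple(margin + n * stride - s for n, s in zip(n_tiles, volume_shape))
    axes = [range(n) for n in n_tiles]
    origins = tuple(
        (i * stride, j * stride, k * stride)
        for i in axes[0] for j in axes[1] for k in axes[2]
    )
    return TilingPlan(volume_shape, patch_edge, margin, stride, pad_after, origins)


def _pad_reflect(arr, pad_before, pad_after):
    """Symmetric padding that tolerates pads larger than the axis length."""
    pb = list(pad_before)
    pa = list(pad_after)
    while any(pb) or any(pa):
        step_b, step_a = [], []
        for ax in range(3):
            limit = arr.shape[ax]  # 'symmetric' allows pad == size
            step_b.append(min(pb[ax], limit))
            step_a.append(min(pa[ax], limit))
        arr = np.pad(arr, tuple(zip(step_b, step_a)), mode="symmetric")
        pb = [b - s for b, s in zip(pb, step_b)]
        pa = [a - s for a, s in zip(pa, step_a)]
    return arr


def segment_volume(network, volume, plan: TilingPlan = None,
                   return_proba: bool = False):
    """Per-voxel argmax of stitched class probabilities.

    Ties break toward the lowest class index.  The output LabelMap is
    aligned with the input grid and affine.
    """
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    affine = getattr(volume, "affine", np.eye(4))
    if plan is None:
        plan = plan_tiles(data.shape)
    if tuple(data.shape) != tuple(plan.volume_shape):
        raise ConfigurationError("tiling plan was made for a different shape")
    m, pe, stride = plan.margin, plan.patch_edge, plan.stride
    padded = _pad_reflect(data, (m, m, m), plan.pad_after)
    out = np.zeros(data.shape, dtype=np.int16)
    proba = (
        np.zeros((network.config.n_classes,) + data.shape, dtype=np.float32)
        if return_proba else None
    )
    for ox, oy, oz in plan.origins:
        tile = padded[ox:ox + pe, oy:oy + pe, oz:oz + pe]
        with nn.no_grad():
            logits = network.logits(tile[None, None], training=False).data
        if not np.all(np.isfinite(logits)):
            raise DataError("non-finite activations during inference")
        p = nn.softmax(logits, axis=1)[0]
        core = p[:, m:m + stride, m:m + stride, m:m + stride]
        # clip the central region to the unpadded volume
        ex = min(ox + stride, data.shape[0]) - ox
        ey = min(oy + stride, data.shape[1]) - oy
        ez = min(oz + stride, data.shape[2]) - oz
        out[ox:ox + ex, oy:oy + ey, oz:oz + ez] = np.argmax(
            core[:, :ex, :ey, :ez], axis=0
        )
        if return_proba:
            proba[:, ox:ox + ex, oy:oy + ey, oz:oz + ez] = core[:, :ex, :ey, :ez]
    labels = LabelMap(out, affine)
    if return_proba:
        return labels, proba
    return labels
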