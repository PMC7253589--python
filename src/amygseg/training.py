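"""Patch sampling, loss, optimization schedule and cross-validation.

Training minimizes unweighted voxel-wise categorical cross-entropy with
Adam.  The learning rate follows a polynomial ("poly") decay,

    lr = lr_initial * (1 - iter / total_iter) ** power,

with power 0.9, reaching exactly zero at the final iteration.  Patches
(default 59^3) are sampled from the whole brain, with a configurable
fraction centered on foreground voxels to counter the ~0.05% class
imbalance.  Cross-validation uses a rotation design in which every
subject is tested exactly once.
"""

from __future__ import annotations

import dataclasses
import io as _io
import logging

import numpy as np
from skimage.filters import threshold_otsu

from . import nn
from .arch import Network
from .errors import ConfigurationError, DataError
from .inference import plan_tiles, segment_volume
from .metrics import dice

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "normalize_volume",
    "poly_lr",
    "sample_patches",
    "make_cv_folds",
    "train",
    "select_best",
    "TrainingHistory",
]

log = logging.getLogger("amygseg")


@dataclasses.dataclass
class TrainConfig:
    train_patch_edge: int = 59
    infer_patch_edge: int = 105
    batch_size: int = 14  # the source also reports 11 patches per iteration
    initial_lr: float = 0.001
    lr_power: float = 0.9
    total_iterations: int = 1000
    iterations_per_epoch: int = 100
    seed: int = 0
    foreground_sampling_fraction: float = 0.5
    normalize_volumes: bool = True  # z-score each volume before sampling

    def __post_init__(self):
        if self.train_patch_edge < 1 or self.infer_patch_edge < 1:
            raise ConfigurationError("patch edges must be positive")
        if self.initial_lr <= 0 or self.lr_power <= 0:
            raise ConfigurationError("initial_lr and lr_power must be positive")
        if not 0.0 <= self.foreground_sampling_fraction <= 1.0:
            raise ConfigurationError("foreground_sampling_fraction must be in [0, 1]")
        if self.batch_size < 1 or self.total_iterations < 1:
            raise ConfigurationError("batch_size and total_iterations must be >= 1")

    def to_text(self) -> str:
        buf = _io.StringIO()
        for f in dataclasses.fields(self):
            buf.write(f"{f.name}: {getattr(self, f.name)}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "TrainConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            if isinstance(f.default, bool):
                coerced[f.name] = kv[f.name].lower() in ("1", "true", "yes")
            elif isinstance(f.default, float):
                coerced[f.name] = float(kv[f.name])
            else:
                coerced[f.name] = int(kv[f.name])
        return cls(**coerced)


def poly_lr(iteration: int, total: int, initial_lr: float = 0.001,
            power: float = 0.9) -> float:
    """Polynomially decayed learning rate; exactly 0 at iteration == total."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if iteration < 0 or iteration > total:
        raise ValueError(f"iteration {iteration} outside [0, {total}]")
    return float(initial_lr * (1.0 - iteration / total) ** power)


# ---------------------------------------------------------------------------
# patch sampling

def _brain_mask(volume):
    """Foreground-of-the-head mask via Otsu when none is supplied."""
    data = np.asarray(getattr(volume, "data", volume))
    return data > threshold_otsu(data)


def normalize_volume(volume):
    """Z-score a volume by its global mean and standard deviation.

    Applied to every training volume when TrainConfig.normalize_volumes
    is set (the default); volumes segmented with such a model must be
    normalized the same way.
    """
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    std = data.std()
    out = (data - data.mean()) / (std if std > 0 else 1.0)
    if hasattr(volume, "affine"):
        from .io import VolumeImage

        return VolumeImage(out, volume.affine)
    return out


def _pad_to_patch(arr, edge, mode, **kw):
    pads = []
    for s in arr.shape:
        deficit = max(0, edge - s)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode=mode, **kw)
    return arr, np.array([p[0] for p in pads])


def sample_patches(volume, labels, n, config: TrainConfig, rng,
                   brain_mask=None, return_centers=False):
    """n co-located (patch, label-patch) pairs, fully inside the volume.

    A fraction `config.foreground_sampling_fraction` of patches is
    centered on a uniformly drawn foreground voxel (clamped so the patch
    fits), the rest on a uniformly drawn brain voxel.  Intensities are
    padded symmetrically and labels with background when the volume is
    smaller than the patch.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    vol = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    lab = np.asarray(getattr(labels, "data", labels))
    edge = config.train_patch_edge
    if brain_mask is None:
        brain_mask = _brain_mask(vol)
    vol, shift = _pad_to_patch(vol, edge, "symmetric")
    lab, _ = _pad_to_patch(lab, edge, "constant", constant_values=0)
    mask, _ = _pad_to_patch(np.asarray(brain_mask, bool), edge, "constant",
                            constant_values=False)
    fg = np.argwhere(lab > 0)
    brain = np.argwhere(mask)
    frac = config.foreground_sampling_fraction
    if frac > 0 and len(fg) == 0:
        raise DataError("foreground sampling requested but no labeled voxels exist")
    if len(brain) == 0:
        brain = np.argwhere(np.ones_like(lab, dtype=bool))
    half = edge // 2
    lo = half
    hi = np.asarray(vol.shape) - (edge - half)  # max allowed center, inclusive
    out, centers = [], []
    for _ in range(n):
        use_fg = rng.random() < frac
        pool = fg if use_fg else brain
        center = pool[rng.integers(len(pool))]
        center = np.minimum(np.maximum(center, lo), hi)
        sl = tuple(slice(c - half, c - half + edge) for c in center)
        out.append((vol[sl].copy(), lab[sl].copy()))
        centers.append(tuple(int(c - s) for c, s in zip(center, shift)))
    if return_centers:
        return out, centers
    return out


# ---------------------------------------------------------------------------
# cross-validation

@dataclasses.dataclass(frozen=True)
class FoldPlan:
    folds: tuple  # of dicts with keys train / validation / test

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_cv_folds(subjects, k: int, val_size: int, test_size: int) -> FoldPlan:
    """k-fold rotation design: test blocks partition the cohort.

    With 14 subjects, k=7, val=2, test=2 each fold trains on 10,
    validates on 2 and tests on 2, and every subject is tested once.
    """
    subjects = list(subjects)
    n = len(subjects)
    if k * test_size != n:
        raise ConfigurationError(
            f"k * test_size must equal the cohort size ({k} * {test_size} != {n})"
        )
    if val_size + test_size >= n:
        raise ConfigurationError("validation + test cannot exhaust the cohort")
    folds = []
    for f in range(k):
        test_idx = [f * test_size + j for j in range(test_size)]
        val_idx = [(f * test_size + test_size + j) % n for j in range(val_size)]
        holdout = set(test_idx) | set(val_idx)
        train_idx = [i for i in range(n) if i not in holdout]
        folds.append({
            "train": [subjects[i] for i in train_idx],
            "validation": [subjects[i] for i in val_idx],
            "test": [subjects[i] for i in test_idx],
        })
    return FoldPlan(tuple(folds))


# ---------------------------------------------------------------------------
# training loop

@dataclasses.dataclass
class TrainingHistory:
    losses: list = dataclasses.field(default_factory=list)
    epochs: list = dataclasses.field(default_factory=list)
    # epochs: dicts with epoch (1-based), iteration, val_dice, state


def _snapshot(network: Network):
    return {
        name: (arr.data.copy() if isinstance(arr, nn.Tensor) else arr.copy())
        for name, arr in network.named_arrays().items()
    }


def restore_snapshot(network: Network, state):
    for name, arr in network.named_arrays().items():
        if isinstance(arr, nn.Tensor):
            arr.data[...] = state[name]
        else:
            arr[...] = state[name]


def _validation_dice(network, val_data, n_classes, normalize=True):
    scores = []
    for vol, lab in val_data:
        if normalize:
            vol = normalize_volume(vol)
        data = np.asarray(getattr(vol, "data", vol))
        plan = plan_tiles(data.shape, patch_edge=min(data.shape), margin=0)
        pred = segment_volume(network, vol, plan).data
        truth = np.asarray(getattr(lab, "data", lab))
        per_class = [
            dice(pred == c, truth == c)
            for c in range(1, n_classes) if (truth == c).any()
        ]
        if per_class:
            scores.append(float(np.mean(per_class)))
    return float(np.mean(scores)) if scores else float("nan")


def train(network: Network, data, config: TrainConfig, val_data=None,
          brain_masks=None) -> TrainingHistory:
    """Optimize `network` on (volume, labels) pairs; reproducible by seed.

    Each iteration draws `batch_size` patches, each from a uniformly
    chosen subject, computes mean voxel-wise cross-entropy over the
    batch and applies one Adam step at the poly-decayed learning rate.
    Validation mean foreground Dice (and a weight snapshot) is recorded
    every `iterations_per_epoch` iterations when `val_data` is given.
    """
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    params = network.parameters()
    opt = nn.Adam(params)
    masks = brain_masks or [None] * len(data)
    # per-subject voxel pools, computed once
    pools = []
    for (vol, lab), m in zip(data, masks):
        v = np.asarray(getattr(vol, "data", vol), dtype=np.float32)
        l = np.asarray(getattr(lab, "data", lab))
        mask = _brain_mask(v) if m is None else np.asarray(m, bool)
        if config.normalize_volumes:
            v = normalize_volume(v)
        pools.append((v, l, mask))
    total = config.total_iterations
    edge = config.train_patch_edge
    log.info("training: %d iterations, batch %d, patch %d^3, seed %d",
             total, config.batch_size, edge, config.seed)
    for it in range(total):
        xs, ys = [], []
        for _ in range(config.batch_size):
            v, l, mask = pools[rng.integers(len(pools))]
            (patch, lpatch), = sample_patches(
                v, l, 1, config, rng, brain_mask=mask
            )
            xs.append(patch)
            ys.append(lpatch)
        x = np.stack(xs)[:, None]
        y = np.stack(ys).astype(np.int64)
        logits = network.logits(x, training=True)
        loss = nn.softmax_cross_entropy(logits, y)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss {loss_val} at iteration {it}; aborting"
            )
        opt.zero_grad()
        loss.backward()
        opt.step(poly_lr(it, total, config.initial_lr, config.lr_power))
        history.losses.append(loss_val)
        end_of_epoch = (it + 1) % config.iterations_per_epoch == 0 or it + 1 == total
        if end_of_epoch and val_data is not None:
            epoch = len(history.epochs) + 1
            vd = _validation_dice(network, val_data, network.config.n_classes,
                                  normalize=config.normalize_volumes)
            history.epochs.append({
                "epoch": epoch, "iteration": it + 1, "val_dice": vd,
                "state": _snapshot(network),
            })
            log.info("epoch %d (iter %d): loss %.4f, val dice %.4f",
                     epoch, it + 1, loss_val, vd)
    return history


def select_best(history: TrainingHistory):
    """Epoch record with the highest validation Dice; earliest wins ties."""
    if not history.epochs:
        raise ValueError("history contains no epochs")
    best = history.epochs[0]
    for rec in history.epochs[1:]:
        if rec["val_dice"] > best["val_dice"]:
            best = rec
    return best
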