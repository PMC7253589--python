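"""Synthetic 3D cohorts with the statistical structure the method assumes.

A phantom is a brain-shaped ellipsoid on a dark background carrying two
mirrored, very small ellipsoidal target structures, each divided into
four compartments by three sequential planar cuts with thin
low-intensity septa along the cut planes.  Intensities are per-tissue
means under a smooth multiplicative bias field plus additive Gaussian
noise.  The defaults reproduce the extreme class imbalance of the real
task: both target structures together occupy ~0.05% of the brain mask.

The geometry is a deliberate surrogate: it reproduces the properties
the segmentation method is designed around (tiny, adjacent,
low-contrast compartments inside a large homogeneous organ), not
anatomy.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .io import LabelMap, VolumeImage

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
    "domain_shift_variant",
]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, intensity and variability model of one synthetic cohort."""

    shape: tuple = (191, 236, 171)
    spacing: tuple = (1.0, 1.0, 1.0)
    # brain ellipsoid (voxels, centered in the grid)
    brain_semiaxes: tuple = (80.0, 99.0, 72.0)
    # left target structure center, offset from the brain center (voxels);
    # the right structure is its mirror image across the grid's mid-x plane
    structure_offset: tuple = (-24.0, 18.0, -14.0)
    # relative axis lengths of the target ellipsoid; absolute size is derived
    # from foreground_fraction unless structure_semiaxes is set explicitly
    structure_axis_ratios: tuple = (1.6, 1.1, 1.0)
    structure_semiaxes: tuple = None
    # both structures jointly, as a fraction of brain-mask voxels
    foreground_fraction: float = 0.0005
    # compartment volume fractions (4 compartments from 3 sequential cuts)
    compartment_fractions: tuple = (0.35, 0.30, 0.20, 0.15)
    cut_normals: tuple = ((1.0, 0.3, 0.0), (0.2, 1.0, 0.3), (0.0, 0.3, 1.0))
    septum_halfwidth: float = 0.6  # voxels; distance to a cut plane
    # per-tissue intensity means (arbitrary units)
    background_mean: float = 10.0
    brain_mean: float = 100.0
    compartment_means: tuple = (82.0, 94.0, 106.0, 118.0)
    septum_mean: float = 60.0
    noise_sigma: float = 6.0
    bias_amplitude: float = 0.05  # residual inhomogeneity after correction
    # inter-subject jitter (cohorts only)
    center_jitter: float = 2.0       # voxels, uniform per axis
    axes_jitter: float = 0.10        # relative, uniform per axis
    intensity_jitter: float = 0.03   # relative, uniform per tissue
    bilateral_labels: bool = False   # True: labels 1-4 on both sides

    @classmethod
    def small(cls) -> "PhantomSpec":
        """Fast-CPU preset: 48^3 grid with scaled-up (~1%) imbalance.

        Labels are bilateral (1-4 on both sides) so the preset exercises
        compartment discrimination rather than laterality.  Compartment
        means are spread well clear of the brain mean and the septa are
        dropped: at this scale the structures are only ~10 voxels across,
        so a one-voxel septum sheet would not be thin relative to them,
        and per-voxel contrast has to carry the signal that partial
        context supplies at full scale.
        """
        return cls(
            shape=(48, 48, 48),
            brain_semiaxes=(22.0, 21.0, 20.0),
            structure_offset=(-8.0, 3.0, -2.0),
            foreground_fraction=0.01,
            compartment_means=(40.0, 80.0, 140.0, 180.0),
            noise_sigma=5.0,
            septum_halfwidth=0.0,
            center_jitter=1.5,
            bilateral_labels=True,
        )

    @property
    def n_labels(self) -> int:
        return 5 if self.bilateral_labels else 9

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff

    def derived_structure_semiaxes(self) -> np.ndarray:
        """Solve for per-side semi-axes hitting the foreground target.

        Continuous volumes: brain 4/3*pi*prod(brain_semiaxes); per side
        V = foreground_fraction * brain / 2 = 4/3*pi*s^3*prod(ratios).
        """
        if self.structure_semiaxes is not None:
            return np.asarray(self.structure_semiaxes, dtype=float)
        ratios = np.asarray(self.structure_axis_ratios, dtype=float)
        brain_vol = np.prod(np.asarray(self.brain_semiaxes, dtype=float))
        s3 = self.foreground_fraction * brain_vol / (2.0 * np.prod(ratios))
        return ratios * np.cbrt(s3)


def _ellipsoid_mask(shape, center, semiaxes):
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    u = ((x - center[0]) / semiaxes[0]) ** 2
    v = ((y - center[1]) / semiaxes[1]) ** 2
    w = ((z - center[2]) / semiaxes[2]) ** 2
    return (u + v + w) <= 1.0


def _compartment_labels(points, center, normals, fractions):
    """Assign compartments 1..4 by three sequential planar cuts.

    Cut offsets are taken at quantiles of the projections so compartment
    volume fractions track `fractions` for any jittered geometry; septum
    distances to the used cut planes are returned alongside.
    """
    rel = points - center
    labels = np.zeros(len(points), dtype=np.int16)
    septum_dist = np.full(len(points), np.inf)
    remaining = np.ones(len(points), dtype=bool)
    fr = np.asarray(fractions, dtype=float)
    fr = fr / fr.sum()
    for c in range(3):
        n = np.asarray(normals[c], dtype=float)
        n = n / np.linalg.norm(n)
        proj = rel @ n
        frac_here = fr[c] / fr[c:].sum()
        cut = np.quantile(proj[remaining], frac_here)
        take = remaining & (proj <= cut)
        labels[take] = c + 1
        affected = remaining
        septum_dist[affected] = np.minimum(
            septum_dist[affected], np.abs(proj[affected] - cut)
        )
        remaining = remaining & ~take
    labels[remaining] = 4
    return labels, septum_dist


def _smooth_bias(shape, amplitude, rng):
    """Multiplicative bias: 1 + amplitude * low-order cosine mixture in [-1,1]."""
    if amplitude == 0:
        return 1.0
    field = np.zeros(shape, dtype=np.float32)
    axes = [np.linspace(0.0, 1.0, s, dtype=np.float32) for s in shape]
    for _ in range(3):
        coef = rng.normal(size=3)
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        gx = np.cos(np.pi * freq[0] * axes[0] + phase[0]) * coef[0]
        gy = np.cos(np.pi * freq[1] * axes[1] + phase[1]) * coef[1]
        gz = np.cos(np.pi * freq[2] * axes[2] + phase[2]) * coef[2]
        field += gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    peak = np.abs(field).max()
    if peak > 0:
        field /= peak
    return 1.0 + amplitude * field


def _jittered_geometry(spec, rng, jitter):
    """Per-subject geometry: (left center, right center, semiaxes, means)."""
    shape = np.asarray(spec.shape, dtype=float)
    brain_center = (shape - 1) / 2.0
    offset = np.asarray(spec.structure_offset, dtype=float)
    semiaxes = spec.derived_structure_semiaxes()
    means = {
        "background": spec.background_mean,
        "brain": spec.brain_mean,
        "compartments": np.asarray(spec.compartment_means, dtype=float),
        "septum": spec.septum_mean,
    }
    if jitter:
        c_jit = rng.uniform(-spec.center_jitter, spec.center_jitter, size=(2, 3))
        a_jit = 1.0 + rng.uniform(-spec.axes_jitter, spec.axes_jitter, size=(2, 3))
        i_jit = 1.0 + rng.uniform(-spec.intensity_jitter, spec.intensity_jitter, size=7)
    else:
        c_jit = np.zeros((2, 3))
        a_jit = np.ones((2, 3))
        i_jit = np.ones(7)
    left_center = brain_center + offset + c_jit[0]
    mirror_offset = offset.copy()
    mirror_offset[0] = -mirror_offset[0]
    right_center = brain_center + mirror_offset + c_jit[1]
    means["background"] *= i_jit[0]
    means["brain"] *= i_jit[1]
    means["compartments"] = means["compartments"] * i_jit[2:6]
    means["septum"] *= i_jit[6]
    return left_center, right_center, semiaxes * a_jit, means, brain_center


def _paint_structure(intensity, labels, spec, center, semiaxes, means,
                     mirror, label_offset):
    """Voxelize one target structure into the intensity and label grids."""
    shape = spec.shape
    lo = np.maximum(np.floor(center - semiaxes - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + semiaxes + 2).astype(int),
                    np.asarray(shape))
    if np.any(hi - lo <= 0):
        raise ConfigurationError("target structure lies outside the grid")
    grids = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = grids.reshape(3, -1).T.astype(float)
    rel = (pts - center) / semiaxes
    inside = (rel ** 2).sum(axis=1) <= 1.0
    if not np.any(inside):
        raise ConfigurationError("target structure contains no voxels")
    normals = np.asarray(spec.cut_normals, dtype=float)
    if mirror:
        normals = normals.copy()
        normals[:, 0] = -normals[:, 0]
    comp, septum_dist = _compartment_labels(
        pts[inside], center, normals, spec.compartment_fractions
    )
    coords = pts[inside].astype(int)
    ix, iy, iz = coords[:, 0], coords[:, 1], coords[:, 2]
    vals = means["compartments"][comp - 1]
    septum = septum_dist <= spec.septum_halfwidth
    vals = np.where(septum, means["septum"], vals)
    intensity[ix, iy, iz] = vals
    labels[ix, iy, iz] = comp + label_offset


def generate_phantom(spec: PhantomSpec, seed: int, jitter: bool = False,
                     return_mask: bool = False):
    """One phantom: (VolumeImage, LabelMap) [, brain mask].

    Reproducible: the same spec and seed give bit-identical outputs.
    Labels: 0 background, 1-4 left compartments, 5-8 right (or 1-4 on
    both sides when spec.bilateral_labels is set).
    """
    rng = np.random.default_rng(seed)
    left_c, right_c, semiaxes, means, brain_center = _jittered_geometry(
        spec, rng, jitter
    )
    brain = _ellipsoid_mask(spec.shape, brain_center, spec.brain_semiaxes)
    intensity = np.full(spec.shape, means["background"], dtype=np.float32)
    intensity[brain] = means["brain"]
    labels = np.zeros(spec.shape, dtype=np.int16)
    right_offset = 0 if spec.bilateral_labels else 4
    _paint_structure(intensity, labels, spec, left_c, semiaxes[0], means,
                     mirror=False, label_offset=0)
    _paint_structure(intensity, labels, spec, right_c, semiaxes[1], means,
                     mirror=True, label_offset=right_offset)
    bias = _smooth_bias(spec.shape, spec.bias_amplitude, rng)
    intensity *= bias
    if spec.noise_sigma > 0:
        intensity += spec.noise_sigma * rng.standard_normal(
            spec.shape, dtype=np.float32
        )
    affine = spec.affine()
    out = (VolumeImage(intensity, affine), LabelMap(labels, affine))
    if return_mask:
        return out + (brain,)
    return out


def generate_cohort(n: int, spec: PhantomSpec, seed: int):
    """n phantoms with independent jitter of centers, axes and intensities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate_phantom(spec, int(s), jitter=True) for s in subject_seeds]


def domain_shift_variant(spec: PhantomSpec, shift: dict) -> PhantomSpec:
    """A spec with identical geometry/labels but shifted intensities.

    `shift` keys (all optional): `scale`, `offset` applied to every
    tissue mean; `invert` (bool) flips contrast about the mean range;
    `noise_sigma`, `bias_amplitude` override the acquisition model.
    Geometry and label statistics are untouched.
    """
    allowed = {"scale", "offset", "invert", "noise_sigma", "bias_amplitude"}
    unknown = set(shift) - allowed
    if unknown:
        raise ConfigurationError(f"unknown shift keys: {sorted(unknown)}")
    means = np.array(
        [spec.background_mean, spec.brain_mean, *spec.compartment_means,
         spec.septum_mean], dtype=float,
    )
    if shift.get("invert"):
        means = means.max() + means.min() - means
    means = means * shift.get("scale", 1.0) + shift.get("offset", 0.0)
    return dataclasses.replace(
        spec,
        background_mean=float(means[0]),
        brain_mean=float(means[1]),
        compartment_means=tuple(means[2:6]),
        septum_mean=float(means[6]),
        noise_sigma=float(shift.get("noise_sigma", spec.noise_sigma)),
        bias_amplitude=float(shift.get("bias_amplitude", spec.bias_amplitude)),
    )
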