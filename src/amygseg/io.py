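"""NIfTI readers/writers, in-memory grid types and class tables."""

from __future__ import annotations

import dataclasses

import nibabel as nib
import numpy as np

from .errors import AlignmentError, DataError

__all__ = [
    "VolumeImage",
    "LabelMap",
    "ClassTable",
    "CLASS_TABLES",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "check_aligned",
]


@dataclasses.dataclass
class VolumeImage:
    """A 3D scalar intensity grid with an index-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4, dtype=np.float64)
    )

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("volume data must be 3D")
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")

    @property
    def spacing(self):
        """Voxel edge lengths in mm, per axis."""
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass
class LabelMap:
    """A 3D integer grid aligned with a VolumeImage."""

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4, dtype=np.float64)
    )

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise DataError("label data must be integer-valued")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("label data must be 3D")

    @property
    def spacing(self):
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass(frozen=True)
class ClassTable:
    """Ordered mapping label integer -> class name; background is 0."""

    name: str
    class_names: tuple

    def __post_init__(self):
        if not self.class_names or self.class_names[0] != "background":
            raise DataError("class 0 must be 'background'")

    @property
    def n_classes(self):
        return len(self.class_names)

    @property
    def labels(self):
        return tuple(range(len(self.class_names)))

    @property
    def foreground_labels(self):
        return tuple(range(1, len(self.class_names)))

    def validate_labels(self, data):
        values = np.unique(np.asarray(data))
        bad = [int(v) for v in values if v < 0 or v >= self.n_classes]
        if bad:
            raise DataError(
                f"label value(s) {bad} not in class table {self.name!r} "
                f"(valid: 0..{self.n_classes - 1})"
            )


_COMPARTMENTS = ("lateral", "basal", "centromedial", "cortico-superficial")

CLASS_TABLES = {
    "subnuclei9": ClassTable(
        "subnuclei9",
        ("background",)
        + tuple(f"left {c}" for c in _COMPARTMENTS)
        + tuple(f"right {c}" for c in _COMPARTMENTS),
    ),
    "whole3": ClassTable("whole3", ("background", "left amygdala", "right amygdala")),
    "compartments5": ClassTable("compartments5", ("background",) + _COMPARTMENTS),
}


def read_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def write_volume(volume: VolumeImage, path):
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                             volume.affine), str(path))


def read_labels(path, table: ClassTable = None) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.all(data == np.round(data)):
        raise DataError(f"{path}: label image contains non-integer values")
    data = data.astype(np.int16)
    if table is not None:
        table.validate_labels(data)
    return LabelMap(data, img.affine)


def write_labels(labels: LabelMap, path):
    nib.save(nib.Nifti1Image(np.asarray(labels.data, dtype=np.int16),
                             labels.affine), str(path))


def check_aligned(volume: VolumeImage, labels: LabelMap, atol=1e-4):
    if volume.shape != labels.shape:
        raise AlignmentError(
            f"image shape {volume.shape} != label shape {labels.shape}"
        )
    if not np.allclose(volume.affine, labels.affine, atol=atol):
        raise AlignmentError("image and label affines differ")
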