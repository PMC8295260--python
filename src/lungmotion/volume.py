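"""Image volumes and lung/lobe label maps on a fixed patient coordinate frame.

All volumes in one subject share a single axis convention:

* ``+x`` — patient-left (transverse axis),
* ``+y`` — dorsal / posterior (dorsal–ventral axis),
* ``+z`` — superior (apico-basal axis).

Arrays are indexed ``[ix, iy, iz]`` and the world position (mm) of a voxel
centre is ``origin + index * spacing``.  NIfTI I/O goes through nibabel with a
diagonal affine built from ``spacing`` and ``origin``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import EmptyMaskError

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Lobe label codes used by :class:`LungSegmentation`.
LOBE_CODES = {"LUL": 1, "LLL": 2, "RUL": 3, "RML": 4, "RLL": 5}
LEFT_LOBES = ("LUL", "LLL")
RIGHT_LOBES = ("RUL", "RML", "RLL")


def world_axes(shape, spacing, origin):
    """Per-axis 1-D arrays of voxel-centre world coordinates (mm)."""
    return tuple(
        origin[a] + spacing[a] * np.arange(shape[a], dtype=float) for a in range(3)
    )


def world_to_index(points, spacing, origin):
    """Map world points (..., 3) in mm to fractional voxel indices."""
    pts = np.asarray(points, dtype=float)
    return (pts - np.asarray(origin)) / np.asarray(spacing)


@dataclass(eq=False)
class ImageVolume:
    """A 3-D scalar CT-like volume in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        HU values; must lie within the representable CT range
        [{HU_MIN}, {HU_MAX}].
    spacing : tuple of float
        Voxel size per axis in mm; strictly positive.
    origin : tuple of float
        World position (mm) of the voxel at index (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume expects a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < HU_MIN - 1e-6 or hi > HU_MAX + 1e-6:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: found [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self):
        return world_axes(self.shape, self.spacing, self.origin)

    def save(self, path):
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)


@dataclass(eq=False)
class LungSegmentation:
    """Integer lobe label map aligned with an :class:`ImageVolume`.

    Codes: 0 = non-lung, 1 = LUL, 2 = LLL, 3 = RUL, 4 = RML, 5 = RLL.
    In phantoms the left lung (LUL/LLL) lies on the +x (patient-left) side of
    the midline.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LungSegmentation expects a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.labels.min() < 0 or self.labels.max() > 5:
            raise ValueError("lobe labels must be in 0..5")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self):
        return world_axes(self.shape, self.spacing, self.origin)

    def lung_mask(self, side: str | None = None) -> np.ndarray:
        """Boolean mask of lung voxels, optionally restricted to one side."""
        if side is None:
            return self.labels > 0
        if side == "left":
            names = LEFT_LOBES
        elif side == "right":
            names = RIGHT_LOBES
        else:
            raise ValueError("side must be 'left', 'right' or None")
        return np.isin(self.labels, [LOBE_CODES[n] for n in names])

    def lobe_mask(self, name: str) -> np.ndarray:
        return self.labels == LOBE_CODES[name]

    def region_mask(self, names) -> np.ndarray:
        """Pooled mask over several lobe names (e.g. ('RUL', 'RML'))."""
        return np.isin(self.labels, [LOBE_CODES[n] for n in names])

    def require_lung(self, side: str | None = None) -> np.ndarray:
        mask = self.lung_mask(side)
        if not mask.any():
            raise EmptyMaskError(f"no lung voxels (side={side!r})")
        return mask

    def save(self, path):
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path) -> "LungSegmentation":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return cls(np.asarray(img.dataobj).astype(np.int16), spacing, origin)
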