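"""CT volume and stone mask containers plus NIfTI / raw-array I/O.

Conventions
-----------
* Attenuation is stored in Hounsfield units (HU) as float64.
* Array axis order is ``(slice, row, column)``: axis 0 walks through axial
  slices. NIfTI files store data as ``(i, j, k)`` with the slice axis last,
  so volumes are transposed on load/save and ``spacing`` is reordered to
  match. Voxel indices are 0-based throughout.
* ``spacing`` is the per-axis voxel size in millimetres, in the same
  ``(slice, row, column)`` order as the array.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InputError, ValidationError

__all__ = [
    "CTVolume",
    "StoneMask",
    "load_volume",
    "load_mask",
    "resample_isotropic",
]

#: 26-connectivity structuring element (all neighbours of a 3x3x3 cube).
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CTVolume:
    """A 3D attenuation field in HU with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got {self.values.ndim} dimension(s)"
            )
        if min(self.values.shape) < 1:
            raise ValidationError("all volume dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite attenuation values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValidationError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return np.allclose(self.spacing, self.spacing[0], rtol=1e-3)

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTVolume":
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float64)
            zooms = img.header.get_zooms()[:3]
        except Exception as exc:  # nibabel raises a zoo of error types
            raise InputError(f"cannot read NIfTI volume {path!s}: {exc}") from exc
        if data.ndim != 3:
            raise InputError(f"{path!s}: expected a 3D NIfTI image, got {data.ndim}D")
        # (i, j, k) -> (slice, row, column)
        return cls(values=data.transpose(2, 1, 0), spacing=(zooms[2], zooms[1], zooms[0]))

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        sz, sy, sx = self.spacing
        affine = np.diag([sx, sy, sz, 1.0])
        img = nib.Nifti1Image(self.values.transpose(2, 1, 0), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))

    @classmethod
    def from_raw(cls, sidecar: str | Path) -> "CTVolume":
        """Load a raw binary array described by a JSON sidecar.

        The sidecar carries ``{"file", "shape", "spacing", "dtype"}``; the
        data file path is resolved relative to the sidecar.
        """
        sidecar = Path(sidecar)
        try:
            meta = json.loads(sidecar.read_text())
            raw = sidecar.parent / meta["file"]
            data = np.fromfile(raw, dtype=np.dtype(meta.get("dtype", "float32")))
            data = data.reshape(meta["shape"])
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read raw volume via {sidecar!s}: {exc}") from exc
        return cls(values=data, spacing=tuple(meta.get("spacing", (1.0, 1.0, 1.0))))


@dataclass
class StoneMask:
    """Binary voxel membership of one stone, congruent with a :class:`CTVolume`.

    ``truncated`` is set when the segmented component touched the clip window
    (possible truncation of the stone); ``seed`` records the voxel that
    initiated segmentation, when any.
    """

    mask: np.ndarray
    seed: tuple[int, int, int] | None = None
    truncated: bool = False
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != volume shape {volume.shape}"
            )

    def is_single_component(self) -> bool:
        """True when all member voxels form one 26-connected component."""
        if self.n_voxels == 0:
            return False
        _, n = ndimage.label(self.mask, structure=CONNECTIVITY_26)
        return n == 1

    @classmethod
    def from_nifti(cls, path: str | Path) -> "StoneMask":
        vol = CTVolume.from_nifti(path)
        return cls(mask=vol.values > 0.5, spacing=vol.spacing)

    def to_nifti(self, path: str | Path) -> None:
        CTVolume(self.mask.astype(np.float64), self.spacing).to_nifti(path)


def load_volume(path: str | Path) -> CTVolume:
    """Dispatch on extension: ``.nii``/``.nii.gz`` or a raw-array JSON sidecar."""
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return CTVolume.from_nifti(path)
    if name.endswith(".json"):
        return CTVolume.from_raw(path)
    raise InputError(f"unrecognized volume format: {name}")


def load_mask(path: str | Path) -> StoneMask:
    if str(path).endswith((".nii", ".nii.gz")):
        return StoneMask.from_nifti(path)
    raise InputError(f"unrecognized mask format: {path!s}")


def resample_isotropic(volume: CTVolume, target_mm: float = 1.0, order: int = 1) -> CTVolume:
    """Resample to isotropic voxels of ``target_mm`` by spline interpolation.

    The neighbourhood filters operate in voxel units; on anisotropic data
    resampling to 1 mm isotropic first keeps the 26-neighbourhood geometry
    comparable with the 1/1 mm axial reformat the feature pair was defined on.
    """
    if target_mm <= 0:
        raise ValidationError("target_mm must be positive")
    zoom = [s / target_mm for s in volume.spacing]
    if np.allclose(zoom, 1.0):
        return volume
    values = ndimage.zoom(volume.values, zoom, order=order, mode="nearest")
    return CTVolume(values=values, spacing=(target_mm,) * 3)


def warn_if_anisotropic(volume: CTVolume, context: str) -> None:
    if not volume.is_isotropic:
        warnings.warn(
            f"{context}: voxel spacing {volume.spacing} is anisotropic; the "
            "26-neighbourhood is evaluated in voxel units. Consider "
            "resample_isotropic() first.",
            stacklevel=3,
        )
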