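"""Extraction of the (maxHU, ppLapl) feature pair and stone size.

maxHU is the attenuation of the single highest-attenuating voxel inside the
stone mask; ppLapl is the scaled-Laplacian filter output at that same
voxel, i.e. the contrast between the peak and the weighted mean of its 26
neighbours. Both are point estimates, so they do not depend on how the
stone boundary is segmented (the Laplacian neighbourhood is taken from the
full volume, not clipped to the mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .filters import LaplacianKernel, scaled_laplacian
from .volume import CTVolume, StoneMask

__all__ = ["StoneFeatures", "extract_features", "measure_size"]


@dataclass
class StoneFeatures:
    """The two-feature description of one stone."""

    max_hu: float
    pp_lapl: float
    peak_index: tuple[int, int, int]
    size_mm: float | None = None
    on_border: bool = False  # peak lies on the volume border (replicated padding)

    def as_pair(self) -> tuple[float, float]:
        return (self.max_hu, self.pp_lapl)


def extract_features(
    volume: CTVolume,
    mask: StoneMask,
    kernel: LaplacianKernel | None = None,
    with_size: bool = True,
) -> StoneFeatures:
    """Locate the attenuation peak within ``mask`` and read both features.

    Ties in the maximum are broken toward the lexicographically smallest
    voxel index in (slice, row, column) order, so the result is
    deterministic.
    """
    mask.check_congruent(volume)
    if mask.n_voxels == 0:
        raise ValidationError("cannot extract features from an empty mask")
    kernel = kernel or LaplacianKernel()

    masked = np.where(mask.mask, volume.values, -np.inf)
    flat_peak = int(np.argmax(masked))  # first occurrence = lexicographic min
    peak = tuple(int(i) for i in np.unravel_index(flat_peak, volume.shape))
    max_hu = float(volume.values[peak])

    lap = scaled_laplacian(volume, kernel)
    pp_lapl = float(lap[peak])

    on_border = any(i == 0 or i == dim - 1 for i, dim in zip(peak, volume.shape))
    size = measure_size(mask, volume.spacing) if with_size else None
    return StoneFeatures(
        max_hu=max_hu, pp_lapl=pp_lapl, peak_index=peak, size_mm=size, on_border=on_border
    )


def measure_size(mask: StoneMask | np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Largest axial diameter of the mask, in mm.

    Emulates a caliper measurement in the axial plane: within each slice,
    every member voxel contributes its footprint extremes (voxel centre
    +/- half a voxel along each in-plane axis); the diameter of a slice is
    the maximum pairwise distance between those points, and the stone size
    is the maximum over slices. A single voxel with 1 mm spacing measures
    1.0 mm.
    """
    arr = mask.mask if isinstance(mask, StoneMask) else np.asarray(mask, dtype=bool)
    if arr.ndim != 3:
        raise ValidationError("measure_size expects a 3D mask")
    if not arr.any():
        raise ValidationError("cannot measure the size of an empty mask")
    _, sr, sc = (float(s) for s in spacing)

    best = 0.0
    for k in range(arr.shape[0]):
        rows, cols = np.nonzero(arr[k])
        if rows.size == 0:
            continue
        y = rows * sr
        x = cols * sc
        pts = np.concatenate(
            [
                np.stack([y - sr / 2, x], axis=1),
                np.stack([y + sr / 2, x], axis=1),
                np.stack([y, x - sc / 2], axis=1),
                np.stack([y, x + sc / 2], axis=1),
            ]
        )
        best = max(best, float(pdist(pts).max()))
    return best
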