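"""Threshold-based stone segmentation from a seed point.

Stands in for interactive stone marking: grows the 26-connected component
of voxels at or above a threshold around a user-supplied seed, restricted
to a clip cube so neighbouring bone or a second stone cannot leak in.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import CONNECTIVITY_26, CTVolume, StoneMask

__all__ = ["segment_stone", "DEFAULT_THRESHOLD_HU", "DEFAULT_MAX_EXTENT_MM"]

#: Conventional minimum stone attenuation; well below any stone peak.
DEFAULT_THRESHOLD_HU = 130.0
#: Clip cube side; twice the upper bound of the 3-20 mm size range.
DEFAULT_MAX_EXTENT_MM = 40.0


def segment_stone(
    volume: CTVolume,
    seed: tuple[int, int, int],
    threshold: float = DEFAULT_THRESHOLD_HU,
    max_extent_mm: float = DEFAULT_MAX_EXTENT_MM,
) -> StoneMask:
    """26-connected component of voxels >= ``threshold`` containing ``seed``.

    The search is clipped to a cube of side ``max_extent_mm`` centred on the
    seed. If the component touches the clip boundary the returned mask is
    flagged ``truncated`` (the stone may extend beyond the window).
    Deterministic; the result is independent of which member voxel seeds it
    (up to the shift of the clip window).
    """
    seed = tuple(int(i) for i in seed)
    if len(seed) != 3 or any(i < 0 or i >= s for i, s in zip(seed, volume.shape)):
        raise ValidationError(f"seed {seed} outside volume of shape {volume.shape}")
    if max_extent_mm <= 0:
        raise ValidationError("max_extent_mm must be positive")
    if volume.values[seed] < threshold:
        raise ValidationError(
            f"seed value {volume.values[seed]:.0f} HU is below the {threshold:.0f} HU "
            "threshold; place the seed inside the stone and re-seed"
        )

    half = [int(np.floor((max_extent_mm / 2.0) / s)) for s in volume.spacing]
    lo = [max(0, c - h) for c, h in zip(seed, half)]
    hi = [min(dim, c + h + 1) for c, h, dim in zip(seed, half, volume.shape)]
    window = tuple(slice(a, b) for a, b in zip(lo, hi))

    above = volume.values[window] >= threshold
    labels, _ = ndimage.label(above, structure=CONNECTIVITY_26)
    seed_local = tuple(c - a for c, a in zip(seed, lo))
    component = labels == labels[seed_local]

    touches = any(
        component.take(0, axis=ax).any() or component.take(-1, axis=ax).any()
        for ax in range(3)
    )

    mask = np.zeros(volume.shape, dtype=bool)
    mask[window] = component
    return StoneMask(mask=mask, seed=seed, truncated=touches, spacing=volume.spacing)
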