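"""Region-of-interest extraction by binary erosion with a disk.

The skin-air margin of a mammogram is vendor-enhanced and must not feed the
texture features, so the breast mask is eroded with a disk-shaped
structuring element (radius 100 px at full clinical resolution). The disk is
the exact Euclidean one — offset (dr, dc) belongs to the element iff
dr^2 + dc^2 <= radius^2 — and pixels beyond the image border count as
background, so erosion also retreats from the image edges (including the
chest-wall edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import BreastMask

DEFAULT_RADIUS = 100
#: Row count of a full-resolution craniocaudal mammogram that the default
#: 100 px radius is tied to; smaller images scale the radius proportionally.
REFERENCE_ROWS = 2800


class EmptyROIError(ValueError):
    """Erosion removed every pixel."""


@dataclass
class ROIMask:
    mask: np.ndarray
    erosion_radius: int
    parent_mask_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def disk_element(radius: int) -> np.ndarray:
    """Euclidean disk structuring element of the given pixel radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    d = np.arange(-r, r + 1)
    return (d[:, None] ** 2 + d[None, :] ** 2) <= r * r


def erode(mask: BreastMask | np.ndarray, radius: int) -> ROIMask:
    """Erode a breast mask with a disk of the given radius.

    An output pixel survives iff every disk offset from it lands on a true
    mask pixel; out-of-bounds offsets count as false.
    """
    if isinstance(mask, BreastMask):
        grid, parent_id = mask.mask, mask.source_image_id
    else:
        grid, parent_id = np.asarray(mask, dtype=bool), ""
    if not grid.any():
        raise EmptyROIError("cannot erode an empty mask")
    radius = int(radius)
    if radius == 0:
        eroded = grid.copy()
    else:
        eroded = ndimage.binary_erosion(
            grid, structure=disk_element(radius), border_value=0
        )
    if not eroded.any():
        raise EmptyROIError(
            f"ROI empty at radius {radius}; use a smaller erosion radius"
        )
    return ROIMask(mask=eroded, erosion_radius=radius, parent_mask_id=parent_id)


def scaled_radius(rows: int, full_radius: int = DEFAULT_RADIUS) -> int:
    """Erosion radius proportional to image height.

    The clinical default of 100 px presumes a ~2800-row mammogram; synthetic
    images are far smaller, so the radius scales as
    ``round(full_radius * rows / 2800)`` to keep a proportional margin.
    """
    return int(round(full_radius * rows / REFERENCE_ROWS))
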