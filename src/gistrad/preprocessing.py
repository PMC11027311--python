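"""Image preparation: thresholding, laterality standardization, cropping.

The screening images enter the pipeline as raw grayscale grids. Preparation
mirrors the study design: a binary breast mask is obtained by thresholding at
gray level 100 (the breast is post-processed to be bright on a dark
background), right-breast images are mirrored so the chest wall sits on the
left edge of every image, and image and mask are cropped to the tight
bounding box of the breast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import CohortImage

DEFAULT_THRESHOLD = 100


class EmptyMaskError(ValueError):
    """No pixel reaches the breast threshold."""


@dataclass
class BreastMask:
    mask: np.ndarray
    source_image_id: str = ""
    threshold_used: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def threshold_mask(
    pixels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    image_id: str = "",
) -> BreastMask:
    """Binary breast mask: pixel is breast iff its value is >= threshold.

    The >= convention keeps the threshold value itself inside the breast. For
    16-bit inputs the threshold applies on the native intensity scale.
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty image")
    mask = pixels >= threshold
    if not mask.any():
        raise EmptyMaskError(
            f"no breast region: no pixel >= {threshold} in image {image_id or '<unnamed>'}"
        )
    return BreastMask(mask=mask, source_image_id=image_id, threshold_used=threshold)


def standardize_laterality(image: CohortImage) -> CohortImage:
    """Mirror right-breast images about the vertical axis and relabel them L,
    so the chest wall is on the left edge of every image."""
    if image.laterality == "L":
        return image
    if image.laterality == "R":
        return replace(image, pixels=np.fliplr(image.pixels), laterality="L")
    raise ValueError(f"unknown laterality {image.laterality!r}")


def bounding_box(mask: np.ndarray) -> tuple[slice, slice]:
    """Tight bounding box (row slice, col slice) of the true pixels."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("no breast region: mask is empty")
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def crop_to_breast(
    pixels: np.ndarray,
    mask: BreastMask,
    box: tuple[slice, slice] | None = None,
) -> tuple[np.ndarray, BreastMask]:
    """Cut image and mask to the tight bounding box of the breast.

    Pass ``box`` to crop to a precomputed (e.g. dataset-wide) box instead of
    the per-image one; default is per-image.
    """
    pixels = np.asarray(pixels)
    if pixels.shape != mask.mask.shape:
        raise ValueError("image and mask shapes differ")
    if box is None:
        box = bounding_box(mask.mask)
    rs, cs = box
    return pixels[rs, cs], BreastMask(
        mask=mask.mask[rs, cs],
        source_image_id=mask.source_image_id,
        threshold_used=mask.threshold_used,
    )


def common_bounding_box(masks: list[np.ndarray]) -> tuple[slice, slice]:
    """Union bounding box across a dataset (the alternative crop mode)."""
    boxes = [bounding_box(m) for m in masks]
    r0 = min(b[0].start for b in boxes)
    r1 = max(b[0].stop for b in boxes)
    c0 = min(b[1].start for b in boxes)
    c1 = max(b[1].stop for b in boxes)
    return slice(r0, r1), slice(c0, c1)
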