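"""Reading grayscale images from common formats.

TIFF and PNG cover the synthetic pipeline and most exported screening
images; the DICOM adapter extracts the pixel grid and the image-laterality
tag for de-identified craniocaudal mammograms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF or PNG as a 2-D array on its native scale."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif suffix == ".png":
        pixels = np.asarray(Image.open(path).convert("I"))
    else:
        raise ValueError(f"unsupported image format {suffix!r} ({path})")
    pixels = np.squeeze(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {pixels.shape}")
    return pixels


def read_dicom(path: str | Path) -> tuple[np.ndarray, str | None]:
    """Read a DICOM file: (pixel grid, laterality tag or None).

    Laterality comes from ImageLaterality (fallback Laterality). Requires
    pydicom.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    laterality = getattr(ds, "ImageLaterality", None) or getattr(
        ds, "Laterality", None
    )
    return np.asarray(ds.pixel_array), laterality
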