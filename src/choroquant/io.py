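"""Image and table I/O in plain interchange formats.

B-scans are written as 16-bit grayscale TIFF, label masks as 8-bit PNG
(0 = outside, 1 = stroma, 2 = lumen), boundaries and cohort tables as CSV.
Intensity scaling to uint16 is recorded so reads invert it exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .segmentation import BScan

#: fixed intensity scale for float->uint16 TIFF round-trips
TIFF_SCALE = 64.0


def write_bscan_tiff(image: BScan, path: str | Path) -> None:
    """Write a B-scan as 16-bit TIFF (intensities scaled by TIFF_SCALE)."""
    import tifffile

    arr = np.clip(np.asarray(image.pixels, float) * TIFF_SCALE, 0, 65535)
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_bscan_tiff(
    path: str | Path,
    axial_um_per_px: float,
    lateral_um_per_px: float,
    fovea_col: int,
    meridian: str = "vertical",
    eye_id: str = "",
    laterality: str = "OD",
) -> BScan:
    """Read a 16-bit TIFF back into a B-scan with the supplied metadata."""
    import tifffile

    arr = tifffile.imread(str(path)).astype(float) / TIFF_SCALE
    return BScan(
        pixels=arr,
        axial_um_per_px=axial_um_per_px,
        lateral_um_per_px=lateral_um_per_px,
        fovea_col=fovea_col,
        meridian=meridian,
        eye_id=eye_id,
        laterality=laterality,
    )


def write_label_png(labels: np.ndarray, path: str | Path) -> None:
    """Write a 0/1/2 label mask as 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), np.asarray(labels, dtype=np.uint8))


def read_label_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)))
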