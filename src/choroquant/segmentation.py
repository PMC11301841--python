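"""Choroid boundary representation, I/O, and a baseline gradient segmenter.

The analyzed band is bounded by the inner choroid interface (below the
RPE/Bruch's complex) and the choroid-sclera interface. Boundaries are stored
per column as 0-based pixel depths, inclusive at both ends, so the band in a
column spans rows ``upper..lower`` and its thickness is ``lower - upper + 1``
pixels.

The primary pipeline consumes supplied boundaries (checked or manually
corrected segmentations); :func:`baseline_segment` is a simple deterministic
gradient-step finder so that end-to-end runs need no trained model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "BScan",
    "ChoroidBoundaries",
    "read_boundaries",
    "write_boundaries",
    "boundaries_from_label_image",
    "baseline_segment",
]

#: Label-image convention shared across the package.
LABEL_OUTSIDE, LABEL_STROMA, LABEL_LUMEN = 0, 1, 2


@dataclass
class BScan:
    """A 2D OCT reflectance cross-section.

    ``pixels`` is indexed [row, column]; rows are depth (increasing
    downward), columns are lateral position. ``fovea_col`` marks the foveal
    center. ``meridian`` is ``"vertical"`` or ``"horizontal"``;
    ``laterality`` (``"OD"``/``"OS"``) determines nasal/temporal naming on
    the horizontal meridian.
    """

    pixels: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    fovea_col: int
    meridian: str = "vertical"
    eye_id: str = ""
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("pixel spacings must be positive")
        if not (0 <= self.fovea_col < self.pixels.shape[1]):
            raise ValueError(
                f"fovea_col {self.fovea_col} outside image width {self.pixels.shape[1]}"
            )
        if self.meridian not in ("vertical", "horizontal"):
            raise ValueError(f"meridian must be vertical|horizontal, got {self.meridian!r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD|OS, got {self.laterality!r}")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ChoroidBoundaries:
    """Per-column inner (upper) and outer (lower) choroid interface depths.

    ``valid`` marks columns where both interfaces are defined and
    ``lower >= upper``. Invalid columns are excluded from all downstream
    sums; they are never interpolated.
    """

    upper_px: np.ndarray
    lower_px: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.upper_px = np.asarray(self.upper_px, dtype=float)
        self.lower_px = np.asarray(self.lower_px, dtype=float)
        if self.upper_px.shape != self.lower_px.shape or self.upper_px.ndim != 1:
            raise ValueError("upper_px and lower_px must be 1D arrays of equal length")
        if self.valid is None:
            self.valid = np.isfinite(self.upper_px) & np.isfinite(self.lower_px)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.upper_px.shape:
            raise ValueError("valid mask must match boundary length")
        # enforce the band invariant: flag, never silently repair
        with np.errstate(invalid="ignore"):
            bad = self.valid & ~(self.lower_px >= self.upper_px)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} column(s) with lower < upper marked invalid",
                stacklevel=2,
            )
            self.valid = self.valid & ~bad

    @property
    def n_cols(self) -> int:
        return self.upper_px.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0

    def thickness_px(self) -> np.ndarray:
        """Inclusive band thickness per column (NaN on invalid columns)."""
        t = self.lower_px - self.upper_px + 1.0
        t[~self.valid] = np.nan
        return t

    def band_mask(self, n_rows: int) -> np.ndarray:
        """Boolean (n_rows, n_cols) mask of the band over valid columns."""
        rows = np.arange(n_rows)[:, None]
        up = np.where(self.valid, self.upper_px, n_rows)
        lo = np.where(self.valid, self.lower_px, -1)
        return (rows >= up[None, :]) & (rows <= lo[None, :])


def write_boundaries(boundaries: ChoroidBoundaries, path: str | Path) -> None:
    """Write boundaries as CSV with columns column,upper_px,lower_px,valid."""
    df = pd.DataFrame(
        {
            "column": np.arange(boundaries.n_cols),
            "upper_px": boundaries.upper_px,
            "lower_px": boundaries.lower_px,
            "valid": boundaries.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def boundaries_from_label_image(labels: np.ndarray) -> ChoroidBoundaries:
    """Extract boundaries from a label image (0 outside, 1 stroma, 2 lumen).

    Per column, the upper boundary is the first in-band row and the lower the
    last; columns with no band pixels are invalid.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label image must be 2D")
    in_band = labels > LABEL_OUTSIDE
    any_band = in_band.any(axis=0)
    n_rows = labels.shape[0]
    rows = np.arange(n_rows)[:, None]
    upper = np.where(any_band, np.where(in_band, rows, n_rows).min(axis=0), np.nan)
    lower = np.where(any_band, np.where(in_band, rows, -1).max(axis=0), np.nan)
    if not any_band.any():
        raise ValueError("label image contains no band pixels in any column")
    return ChoroidBoundaries(upper_px=upper, lower_px=lower, valid=any_band)


def read_boundaries(source: str | Path | np.ndarray) -> ChoroidBoundaries:
    """Read boundaries from a CSV table, a label image file, or a label array.

    CSV files use the column,upper_px,lower_px,valid layout written by
    :func:`write_boundaries`; image files (PNG/TIFF) use the 0/1/2 label
    convention.

    Raises
    ------
    ValueError
        If no column carries a usable boundary pair.
    """
    if isinstance(source, np.ndarray):
        return boundaries_from_label_image(source)
    path = Path(source)
    if path.suffix.lower() in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        return boundaries_from_label_image(np.asarray(iio.imread(path)))
    df = pd.read_csv(path)
    required = {"column", "upper_px", "lower_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"boundary table must contain columns {sorted(required)}")
    df = df.sort_values("column")
    valid = (
        df["valid"].astype(bool).to_numpy()
        if "valid" in df.columns
        else np.isfinite(df["upper_px"]) & np.isfinite(df["lower_px"])
    )
    b = ChoroidBoundaries(
        upper_px=df["upper_px"].to_numpy(float),
        lower_px=df["lower_px"].to_numpy(float),
        valid=np.asarray(valid, dtype=bool),
    )
    if not b.valid.any():
        raise ValueError(f"no valid boundary columns in {path}")
    return b


def baseline_segment(
    image: BScan,
    smoothing: int = 9,
    min_step: float | None = None,
    search_from_row: int = 0,
) -> ChoroidBoundaries:
    """Locate the choroid band by axial intensity steps, column by column.

    Per column the upper boundary is placed at the strongest positive axial
    intensity step at or below ``search_from_row`` and the lower boundary at
    the strongest negative step below the upper; the two boundary curves are
    then median-smoothed laterally with window ``smoothing``. Columns whose
    best step is weaker than ``min_step`` (default: 5% of the image dynamic
    range) are marked invalid. Deterministic.

    This is a stand-in for a trained segmenter and is only adequate on
    high-contrast images; supplied boundaries are the primary input path.
    """
    img = np.asarray(image.pixels, dtype=float)
    n_rows, n_cols = img.shape
    if min_step is None:
        dyn = float(img.max() - img.min())
        min_step = 0.05 * dyn
    # light axial smoothing before differencing to suppress speckle spikes
    prof = uniform_filter1d(img, size=3, axis=0, mode="nearest")
    grad = np.diff(prof, axis=0)  # grad[r] = prof[r+1] - prof[r]

    upper = np.full(n_cols, np.nan)
    lower = np.full(n_cols, np.nan)
    valid = np.zeros(n_cols, dtype=bool)
    lo_row = max(0, search_from_row)
    for c in range(n_cols):
        g = grad[lo_row:, c]
        if g.size == 0:
            continue
        iu = int(np.argmax(g))
        if g[iu] <= min_step:
            continue
        # band starts at the first row after the rising edge
        u = lo_row + iu + 1
        g_below = grad[u:, c]
        if g_below.size == 0:
            continue
        il = int(np.argmin(g_below))
        if -g_below[il] <= min_step:
            continue
        l = u + il  # last bright row before the falling edge
        if l < u:
            continue
        upper[c], lower[c], valid[c] = u, l, True

    if not valid.any():
        raise ValueError("baseline segmentation found no boundary step in any column")
    if smoothing > 1 and valid.sum() >= smoothing:
        # median-smooth across valid columns only, then re-impose validity
        upper[valid] = median_filter(upper[valid], size=smoothing, mode="nearest")
        lower[valid] = median_filter(lower[valid], size=smoothing, mode="nearest")
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > 0:
        logger.info("baseline_segment: %.1f%% of columns invalid", 100 * frac_invalid)
    return ChoroidBoundaries(upper_px=upper, lower_px=lower, valid=valid)
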