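"""Fovea-centred regional partition and choroidal metrics.

The 6-mm macular section is divided into five regions along each meridian:
a central 1-mm fovea region (C), two 1-mm parafoveal regions and two 1.5-mm
perifoveal regions. On the vertical meridian the flanks are superior (S1,
S2) and inferior (I1, I2); on the horizontal meridian temporal (T1, T2) and
nasal (N1, N2), with the nasal side mirrored between right (OD) and left
(OS) eyes. Region intervals are expressed in true (magnification-corrected)
millimetres from the foveal centre and tile [-3, +3) half-open, so every
column belongs to exactly one region.

Per region and per meridian the module computes:

* ChT — mean choroidal thickness (µm) over valid columns;
* LA / SA — lumen / stroma pixel counts converted to mm² with the
  Bennett-corrected pixel area;
* TCA = LA + SA and CVI = LA / TCA;
* width-normalized LA/SA in which perifoveal values are divided by 1.5 so
  all regions are comparable per millimetre of width.

Meridian LA/SA are totals over the 6-mm section (their sum matches mean
ChT in mm times the analysed width); meridian ChT is the mean thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binarization import BinarizedChoroid
from .magnification import ScaleCorrection
from .segmentation import LABEL_LUMEN, BScan, ChoroidBoundaries

__all__ = [
    "RegionSpec",
    "RegionMetrics",
    "RegionalMetrics",
    "partition_regions",
    "assign_columns",
    "compute_metrics",
    "summarize_eye",
]

#: (offset interval in mm, width class) for the five regions, negative side first.
_INTERVALS = [(-3.0, -1.5), (-1.5, -0.5), (-0.5, 0.5), (0.5, 1.5), (1.5, 3.0)]
_PERIFOVEAL_WIDTH = 1.5

#: region names from negative to positive offsets
_NAMES = {
    ("vertical", "OD"): ["S2", "S1", "C", "I1", "I2"],
    ("vertical", "OS"): ["S2", "S1", "C", "I1", "I2"],
    # horizontal scans are stored temporal-to-nasal for OD and mirrored for OS
    ("horizontal", "OD"): ["T2", "T1", "C", "N1", "N2"],
    ("horizontal", "OS"): ["N2", "N1", "C", "T1", "T2"],
}


@dataclass(frozen=True)
class RegionSpec:
    """One region: half-open offset interval [a, b) in corrected mm."""

    name: str
    a_mm: float
    b_mm: float

    @property
    def width_mm(self) -> float:
        return self.b_mm - self.a_mm

    @property
    def is_perifoveal(self) -> bool:
        return math.isclose(self.width_mm, _PERIFOVEAL_WIDTH)


def partition_regions(meridian: str, laterality: str = "OD") -> list[RegionSpec]:
    """Return the five region intervals for a meridian, ordered by offset.

    Vertical: negative offsets are superior. Horizontal: for OD the scan is
    stored temporal-to-nasal (negative offsets temporal); OS mirrors the
    nasal/temporal labels, superior/inferior are laterality-independent.
    """
    key = (meridian, laterality)
    if key not in _NAMES:
        raise ValueError(f"unknown meridian/laterality {key!r}")
    names = _NAMES[key]
    return [RegionSpec(n, a, b) for n, (a, b) in zip(names, _INTERVALS)]


def assign_columns(
    regions: list[RegionSpec],
    n_cols: int,
    fovea_col: int,
    lateral_um_per_px: float,
    correction: ScaleCorrection,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Map image columns to regions by corrected offset of the column centre.

    Returns ``(columns_by_region, clamped_fraction_by_region)`` where the
    clamped fraction is the share of each region's physical width that falls
    outside the image (0 when the section fully covers ±3 mm).
    """
    step_mm = lateral_um_per_px * correction.factor / 1000.0
    offsets = (np.arange(n_cols) - fovea_col) * step_mm
    cols: dict[str, np.ndarray] = {}
    clamped: dict[str, float] = {}
    lo_img = offsets[0] - step_mm / 2
    hi_img = offsets[-1] + step_mm / 2
    for r in regions:
        cols[r.name] = np.nonzero((offsets >= r.a_mm) & (offsets < r.b_mm))[0]
        covered = max(0.0, min(r.b_mm, hi_img) - max(r.a_mm, lo_img))
        clamped[r.name] = max(0.0, 1.0 - covered / r.width_mm)
    return cols, clamped


@dataclass
class RegionMetrics:
    """Physical-unit metrics for one region (NaN when no valid column)."""

    ChT_um: float
    LA_mm2: float
    SA_mm2: float
    TCA_mm2: float
    CVI: float
    LA_norm_mm2: float
    SA_norm_mm2: float
    n_cols: int
    valid_fraction: float
    clamped_fraction: float


@dataclass
class RegionalMetrics:
    """All regions of one meridian plus the meridian aggregates."""

    meridian: str
    laterality: str
    regions: dict[str, RegionMetrics]
    ChT_um: float
    LA_mm2: float
    SA_mm2: float
    TCA_mm2: float
    CVI: float
    valid_fraction: float
    correction_factor: float


def _region_metrics(
    cols: np.ndarray,
    thickness_px: np.ndarray,
    lumen_counts: np.ndarray,
    band_counts: np.ndarray,
    valid: np.ndarray,
    axial_um: float,
    pixel_area_mm2: float,
    norm_divisor: float,
    clamped: float,
) -> RegionMetrics:
    sel = cols[valid[cols]] if cols.size else cols
    n_valid = sel.size
    if n_valid == 0:
        nan = float("nan")
        return RegionMetrics(nan, nan, nan, nan, nan, nan, nan, int(cols.size), 0.0, clamped)
    cht = float(np.mean(thickness_px[sel]) * axial_um)
    la = float(lumen_counts[sel].sum() * pixel_area_mm2)
    tca = float(band_counts[sel].sum() * pixel_area_mm2)
    sa = tca - la
    cvi = la / tca if tca > 0 else float("nan")
    return RegionMetrics(
        ChT_um=cht,
        LA_mm2=la,
        SA_mm2=sa,
        TCA_mm2=tca,
        CVI=cvi,
        LA_norm_mm2=la / norm_divisor,
        SA_norm_mm2=sa / norm_divisor,
        n_cols=int(cols.size),
        valid_fraction=n_valid / cols.size,
        clamped_fraction=clamped,
    )


def compute_metrics(
    binarized: BinarizedChoroid,
    boundaries: ChoroidBoundaries,
    image: BScan,
    correction: ScaleCorrection,
    regions: list[RegionSpec] | None = None,
) -> RegionalMetrics:
    """Compute per-region and meridian choroidal metrics for one B-scan."""
    if regions is None:
        regions = partition_regions(image.meridian, image.laterality)
    if binarized.labels.shape != image.pixels.shape:
        raise ValueError("binarized labels and image shapes differ")
    if boundaries.n_cols != image.n_cols:
        raise ValueError("boundaries and image widths differ")

    cols_by_region, clamped = assign_columns(
        regions, image.n_cols, image.fovea_col, image.lateral_um_per_px, correction
    )
    lumen_counts = (binarized.labels == LABEL_LUMEN).sum(axis=0)
    band_counts = boundaries.band_mask(image.n_rows).sum(axis=0)
    thickness_px = boundaries.lower_px - boundaries.upper_px + 1.0
    pixel_area_mm2 = (
        image.axial_um_per_px * image.lateral_um_per_px * correction.factor * 1e-6
    )

    per_region: dict[str, RegionMetrics] = {}
    for r in regions:
        per_region[r.name] = _region_metrics(
            cols_by_region[r.name],
            thickness_px,
            lumen_counts,
            band_counts,
            boundaries.valid,
            image.axial_um_per_px,
            pixel_area_mm2,
            r.width_mm if r.is_perifoveal else 1.0,
            clamped[r.name],
        )

    # meridian aggregates over the union of region columns (the 6-mm section)
    section = np.concatenate([cols_by_region[r.name] for r in regions])
    sel = section[boundaries.valid[section]] if section.size else section
    if sel.size:
        cht = float(np.mean(thickness_px[sel]) * image.axial_um_per_px)
        la = float(lumen_counts[sel].sum() * pixel_area_mm2)
        tca = float(band_counts[sel].sum() * pixel_area_mm2)
        sa, cvi = tca - la, (la / tca if tca > 0 else float("nan"))
        vfrac = sel.size / section.size
    else:
        cht = la = sa = tca = cvi = float("nan")
        vfrac = 0.0
    return RegionalMetrics(
        meridian=image.meridian,
        laterality=image.laterality,
        regions=per_region,
        ChT_um=cht,
        LA_mm2=la,
        SA_mm2=sa,
        TCA_mm2=tca,
        CVI=cvi,
        valid_fraction=vfrac,
        correction_factor=correction.factor,
    )


def summarize_eye(metrics_by_meridian: dict[str, RegionalMetrics]) -> dict[str, float]:
    """Flatten per-meridian metrics into named cohort-table columns.

    Meridian aggregates become ``ChT_V``, ``LA_V`` … (``_H`` horizontal).
    Region columns use the region name (``ChT_N2``, ``LA_S1`` …) with the
    shared fovea region disambiguated as ``C_V`` / ``C_H``; regional LA/SA
    are the width-normalized values, with raw totals under ``LA_raw_*``.
    Missing meridians yield no columns (flagged missing downstream).
    """
    if not metrics_by_meridian:
        raise ValueError("at least one meridian required")
    out: dict[str, float] = {}
    for meridian, m in metrics_by_meridian.items():
        sfx = "V" if meridian == "vertical" else "H"
        out[f"ChT_{sfx}"] = m.ChT_um
        out[f"LA_{sfx}"] = m.LA_mm2
        out[f"SA_{sfx}"] = m.SA_mm2
        out[f"TCA_{sfx}"] = m.TCA_mm2
        out[f"CVI_{sfx}"] = m.CVI
        out[f"valid_fraction_{sfx}"] = m.valid_fraction
        for name, rm in m.regions.items():
            tag = f"C_{sfx}" if name == "C" else name
            out[f"ChT_{tag}"] = rm.ChT_um
            out[f"LA_{tag}"] = rm.LA_norm_mm2
            out[f"SA_{tag}"] = rm.SA_norm_mm2
            out[f"CVI_{tag}"] = rm.CVI
            out[f"LA_raw_{tag}"] = rm.LA_mm2
            out[f"SA_raw_{tag}"] = rm.SA_mm2
    return out
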