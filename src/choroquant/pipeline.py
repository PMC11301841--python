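"""End-to-end quantification of one B-scan: binarize, correct, regionalize."""

from __future__ import annotations

from .binarization import BinarizationConfig, niblack_binarize
from .magnification import ScaleCorrection
from .regions import RegionalMetrics, compute_metrics
from .segmentation import BScan, ChoroidBoundaries


def quantify_bscan(
    image: BScan,
    boundaries: ChoroidBoundaries,
    al_mm: float,
    binarization: BinarizationConfig | None = None,
) -> RegionalMetrics:
    """Quantify one meridian scan of one eye.

    Runs Niblack lumen/stroma binarization inside the supplied choroid band,
    applies the Bennett lateral magnification correction for the eye's axial
    length, and returns regional plus meridian metrics in physical units.
    """
    binarized = niblack_binarize(image, boundaries, binarization)
    correction = ScaleCorrection(al_mm)
    return compute_metrics(binarized, boundaries, image, correction)
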