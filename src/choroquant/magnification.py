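"""Axial-length-dependent lateral magnification correction (Bennett's formula).

OCT scan length as reported by the device assumes a schematic eye. For an eye
of axial length AL (mm), the true lateral extent ``t`` of a nominal scan
length ``s`` is

    t = p * q * s,    q = 0.01306 * (AL - 1.82),

where ``p`` is the system camera magnification and ``q`` the ocular
magnification. With the device's implied ``p = 1 / (0.01306 * 22.58)`` the
correction collapses to

    t = (AL - 1.82) / 22.58 * s,

which is the identity (t = s) at AL = 24.4 mm. Only lateral distances are
corrected; axial sampling is optical-path based and left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ScaleCorrection", "lateral_factor", "apply_correction", "AL_BOUNDS_MM"]

#: Physiological axial-length bounds (mm); outside these the correction
#: factor is meaningless (negative or wildly large).
AL_BOUNDS_MM = (15.0, 40.0)

_Q_COEFF = 0.01306
_Q_OFFSET = 1.82
_DENOM = 22.58


def lateral_factor(al_mm: float) -> float:
    """Return the lateral scale factor t/s = (AL - 1.82) / 22.58.

    Parameters
    ----------
    al_mm : float
        Axial length in millimetres; must lie within ``AL_BOUNDS_MM``.

    Raises
    ------
    ValueError
        If ``al_mm`` is outside physiological bounds.
    """
    lo, hi = AL_BOUNDS_MM
    if not (lo <= al_mm <= hi):
        raise ValueError(
            f"axial length {al_mm!r} mm outside physiological bounds [{lo}, {hi}] mm"
        )
    return (al_mm - _Q_OFFSET) / _DENOM


@dataclass(frozen=True)
class ScaleCorrection:
    """Magnification correction for one eye.

    Attributes
    ----------
    al_mm : axial length in mm.
    factor : lateral scale factor t/s (dimensionless).
    q : ocular magnification factor, 0.01306 * (AL - 1.82).
    p : system magnification factor, 1 / (0.01306 * 22.58); p * q == factor.
    """

    al_mm: float
    factor: float = field(init=False)
    q: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor", lateral_factor(self.al_mm))
        object.__setattr__(self, "q", _Q_COEFF * (self.al_mm - _Q_OFFSET))
        object.__setattr__(self, "p", 1.0 / (_Q_COEFF * _DENOM))


def apply_correction(
    pixel_metrics: dict,
    axial_um_per_px: float,
    lateral_um_per_px: float,
    al_mm: float,
) -> dict:
    """Convert pixel-unit measurements to true physical units.

    ``pixel_metrics`` maps names to values whose unit is inferred from the
    key suffix: ``*_axial_px`` (axial distance), ``*_lateral_px`` (lateral
    distance), ``*_area_px`` (pixel-count area). Axial distances become µm
    (uncorrected), lateral distances become µm scaled by the Bennett factor,
    areas become mm² scaled by the factor (one lateral dimension per pixel).

    Returns a new dict with suffixes replaced by ``_um`` / ``_mm2``.
    """
    if axial_um_per_px <= 0 or lateral_um_per_px <= 0:
        raise ValueError("pixel spacings must be positive")
    factor = lateral_factor(al_mm)
    out: dict = {}
    for key, value in pixel_metrics.items():
        if key.endswith("_axial_px"):
            out[key[: -len("_axial_px")] + "_um"] = value * axial_um_per_px
        elif key.endswith("_lateral_px"):
            out[key[: -len("_lateral_px")] + "_um"] = (
                value * lateral_um_per_px * factor
            )
        elif key.endswith("_area_px"):
            out[key[: -len("_area_px")] + "_mm2"] = (
                value * axial_um_per_px * lateral_um_per_px * factor * 1e-6
            )
        else:
            out[key] = value
    return out
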