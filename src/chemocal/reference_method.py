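"""Computational pieces of the HPLC reference assay.

Two small utilities: back-calculation of analyte content from a peak area
through an external calibration line and the sample dilution scheme, and the
USP isocratic column-transfer check on the column length / particle size
(L/dp) ratio, which may move within −25% to +50% of the prescribed ratio.

The default calibration line (area = 14,603 · c − 2,363, valid 10–30 µg/mL)
is the validated line for chlorpheniramine maleate used throughout the
synthetic study.  Concentrations outside the validated range are flagged,
not rejected: the stated single dilution scheme puts high-strength units
above the calibrated range, and rejecting them outright would make the
workflow unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError, QuantitationError

__all__ = [
    "CalibrationLine",
    "ColumnGeometry",
    "QuantResult",
    "DEFAULT_CPM_LINE",
    "backcalc_content",
    "ldp_ratio",
    "ldp_allowed_range",
]


@dataclass(frozen=True)
class CalibrationLine:
    """area = slope · concentration(µg/mL) + intercept."""

    slope: float
    intercept: float
    valid_range: tuple[float, float] = (10.0, 30.0)  # µg/mL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ParameterError("calibration slope must be positive")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ParameterError("valid_range must satisfy lo < hi")


DEFAULT_CPM_LINE = CalibrationLine(slope=14_603.0, intercept=-2_363.0)


@dataclass(frozen=True)
class ColumnGeometry:
    length_mm: float
    particle_um: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.particle_um <= 0:
            raise ParameterError("column length and particle size must be > 0")


@dataclass(frozen=True)
class QuantResult:
    concentration_ug_per_ml: float
    content_mg: float
    within_calibrated_range: bool


def backcalc_content(peak_area: float, line: CalibrationLine = DEFAULT_CPM_LINE,
                     dilution_factor: float = 10.0,
                     volume_ml: float = 25.0) -> QuantResult:
    """Invert the calibration line and undo the dilution scheme.

    concentration = (area − intercept) / slope   [µg/mL]
    content       = concentration × dilution_factor × volume_mL / 1000   [mg]

    The default dilution (1 mL → 10 mL from a 25 mL stock) matches the
    one-tablet sample preparation.  A negative implied concentration is a
    quantitation error; out-of-range concentrations are flagged.
    """
    conc = (peak_area - line.intercept) / line.slope
    if conc < 0:
        raise QuantitationError(
            f"peak area {peak_area} implies negative concentration {conc:.4g}"
        )
    lo, hi = line.valid_range
    return QuantResult(
        concentration_ug_per_ml=conc,
        content_mg=conc * dilution_factor * volume_ml / 1000.0,
        within_calibrated_range=bool(lo <= conc <= hi),
    )


def ldp_ratio(col: ColumnGeometry) -> float:
    """Column length over particle diameter, both in µm (dimensionless)."""
    return col.length_mm * 1000.0 / col.particle_um


def ldp_allowed_range(reference: ColumnGeometry) -> tuple[float, float]:
    """USP-permitted L/dp window around a prescribed column: (−25%, +50%)."""
    ratio = ldp_ratio(reference)
    return (0.75 * ratio, 1.50 * ratio)
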