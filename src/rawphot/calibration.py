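"""Linear calibration from absorbance to concentration units.

Point-of-care oxidative-stress assays report concentrations in Carratelli
Units (CARR.U.); the device is calibrated with a small set of standards —
typically three, spanning the working range (around 30, 130 and 300
CARR.U.) — and every other concentration is read off the fitted line
``concentration = slope * A + intercept``.  The regression is of
concentration on absorbance (not inverse regression), so predicting from a
standard's absorbance on a collinear curve recovers its concentration
exactly.

A reading instrument whose LED peaks at a different wavelength than the
reference photometer (here 522 vs 505 nm) sees a proportionally different
absorbance; that inter-instrument offset is modelled as a single
multiplicative factor determined empirically against the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .errors import ContractError


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map A -> concentration fitted from standards."""

    slope: float            # concentration units per absorbance unit
    intercept: float
    r_squared: float
    standards: tuple        # ((A, concentration), ...)
    unit: str = "CARR.U."

    @property
    def a_span(self) -> tuple[float, float]:
        a = [s[0] for s in self.standards]
        return min(a), max(a)


@dataclass(frozen=True)
class ConcentrationEstimate:
    value: float
    unit: str
    extrapolated: bool


@dataclass(frozen=True)
class WavelengthCorrection:
    """Multiplicative inter-instrument absorbance correction."""

    factor: float
    source_peak_nm: float = 522.0
    reference_peak_nm: float = 505.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ContractError("wavelength correction factor must be > 0")


def fit_calibration(standards, unit: str = "CARR.U.") -> CalibrationCurve:
    """OLS line concentration = slope*A + intercept through the standards."""
    pts = [(float(a), float(c)) for a, c in standards]
    if len(pts) < 2:
        raise ContractError("calibration requires at least 2 standards")
    A = np.array([p[0] for p in pts])
    C = np.array([p[1] for p in pts])
    if np.ptp(A) == 0:
        raise ContractError("standards must have distinct absorbance values")
    fit = stats.linregress(A, C)
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise ContractError("degenerate calibration: slope is zero or non-finite")
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        standards=tuple(pts),
        unit=unit,
    )


def predict_concentration(curve: CalibrationCurve, A: float) -> ConcentrationEstimate:
    """slope*A + intercept; values beyond the standards span are flagged."""
    lo, hi = curve.a_span
    return ConcentrationEstimate(
        value=float(curve.slope * A + curve.intercept),
        unit=curve.unit,
        extrapolated=not (lo <= A <= hi),
    )


def apply_wavelength_correction(A: float, correction: WavelengthCorrection) -> float:
    return A * correction.factor


def save_calibration(
    path: str | Path,
    curve: CalibrationCurve,
    correction: WavelengthCorrection | None = None,
) -> None:
    doc = {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "unit": curve.unit,
        "standards": [list(s) for s in curve.standards],
    }
    if correction is not None:
        doc["wavelength_correction"] = {
            "factor": correction.factor,
            "source_peak_nm": correction.source_peak_nm,
            "reference_peak_nm": correction.reference_peak_nm,
        }
    Path(path).write_text(yaml.safe_dump(doc))


def load_calibration(
    path: str | Path,
) -> tuple[CalibrationCurve, WavelengthCorrection | None]:
    doc = yaml.safe_load(Path(path).read_text())
    curve = CalibrationCurve(
        slope=float(doc["slope"]),
        intercept=float(doc["intercept"]),
        r_squared=float(doc["r_squared"]),
        standards=tuple((float(a), float(c)) for a, c in doc["standards"]),
        unit=str(doc.get("unit", "CARR.U.")),
    )
    corr = None
    if "wavelength_correction" in doc:
        wc = doc["wavelength_correction"]
        corr = WavelengthCorrection(
            factor=float(wc["factor"]),
            source_peak_nm=float(wc.get("source_peak_nm", 522.0)),
            reference_peak_nm=float(wc.get("reference_peak_nm", 505.0)),
        )
    return curve, corr
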