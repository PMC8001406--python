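"""Spectrophotometric assay arithmetic.

Covers the calibration chain behind leaf-extract antioxidant traits:
DPPH percent inhibition, linear standard curves (gallic acid for
antioxidant activity and phenolics, catechin for flavonoids) and the
mass-balance conversion of an absorbance reading to mg equivalents per
gram of fresh leaf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "percent_inhibition", "fit_standard_curve", "to_equivalents"]


def percent_inhibition(a_blank: float, a_extract: float) -> float:
    """Radical scavenging activity, %: 100 x (A_blank - A_extract)/A_blank.

    Values outside [0, 100] (pro-oxidant readings, over-quenched blanks)
    are reported as-is with a warning.
    """
    if a_blank <= 0:
        raise ValueError("blank absorbance must be > 0")
    pct = 100.0 * (a_blank - a_extract) / a_blank
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"percent inhibition {pct:.2f} outside [0, 100]", stacklevel=2)
    return pct


@dataclass
class StandardCurve:
    """OLS calibration line absorbance = slope x concentration + intercept."""

    analyte: str
    concentrations: np.ndarray  # ug/mL
    absorbances: np.ndarray
    slope: float
    intercept: float
    r2: float

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())


def fit_standard_curve(
    concentrations, absorbances, analyte: str = "gallic acid"
) -> StandardCurve:
    """Fit the calibration line; needs >= 3 points spanning >= 2 distinct
    concentrations (replicated concentrations are fine)."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3:
        raise ValueError("need >= 3 calibration points")
    if np.unique(c).size < 2:
        raise ValueError("calibration concentrations are constant")
    fit = stats.linregress(c, a)
    return StandardCurve(
        analyte=analyte, concentrations=c, absorbances=a,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
    )


def to_equivalents(
    absorbance: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    extract_volume_ml: float = 3.0,
    leaf_mass_g: float = 0.5,
) -> float:
    """mg equivalents per gram of fresh leaf from one absorbance reading.

    concentration (ug/mL) = (A - intercept)/slope, then
    mg/g = conc x dilution x volume / (1000 x mass).  Readings mapping
    outside the curve's calibrated range are flagged with a warning.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    if leaf_mass_g <= 0:
        raise ValueError("leaf mass must be > 0")
    conc = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"concentration {conc:.3g} ug/mL outside calibrated range "
            f"[{lo:g}, {hi:g}]", stacklevel=2)
    return conc * dilution_factor * extract_volume_ml / (1000.0 * leaf_mass_g)
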