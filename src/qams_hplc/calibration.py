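"""Standard series construction, calibration fitting, LOD/LOQ, and
external-standard quantification.

The calibration model is the unweighted ordinary least-squares line
``area = slope · concentration + intercept`` with ``r`` the Pearson
correlation of area on concentration.  Detection and quantification limits
follow the signal-to-noise convention: LOD at S/N = 3, LOQ at S/N = 10,
computed from the baseline noise s.d. and the peak height obtained per unit
concentration, so LOQ/LOD = 10/3 identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StandardSeries",
    "CalibrationCurve",
    "build_series",
    "fit_calibration",
    "estimate_lod_loq",
    "es_content",
]


def build_series(stock: float, aliquots: list[float], final: float) -> np.ndarray:
    """Concentrations of a serial dilution: ``stock × aliquot / final`` per
    aliquot, order preserved."""
    if stock < 0:
        raise ValueError("stock concentration must be >= 0")
    if final <= 0:
        raise ValueError("final volume must be > 0")
    aliquots = np.asarray(aliquots, dtype=float)
    if np.any(aliquots <= 0):
        raise ValueError("aliquot volumes must be > 0")
    if np.any(aliquots > final):
        raise ValueError("aliquot volume exceeds final volume (impossible dilution)")
    return stock * aliquots / final


@dataclass
class StandardSeries:
    """One analyte's dilution series with measured peak areas."""

    analyte_name: str
    stock_concentration: float  # µg·mL⁻¹
    aliquot_volumes: list[float]  # mL
    final_volume: float  # mL
    areas: np.ndarray  # response·seconds, parallel to aliquot_volumes
    concentrations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.concentrations = build_series(self.stock_concentration, self.aliquot_volumes, self.final_volume)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != self.concentrations.shape:
            raise ValueError("areas must be parallel to aliquot_volumes")


@dataclass
class CalibrationCurve:
    """Fitted line Y = slope·X + intercept with its working range."""

    analyte_name: str
    slope: float  # area per (µg·mL⁻¹)
    intercept: float  # area
    r: float  # Pearson correlation
    linear_range: tuple[float, float]  # µg·mL⁻¹
    lod: float | None = None  # µg·mL⁻¹
    loq: float | None = None  # µg·mL⁻¹


def fit_calibration(series: StandardSeries) -> CalibrationCurve:
    """OLS fit of area on concentration over the series' levels."""
    x = series.concentrations
    y = series.areas
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentration levels to fit")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte_name=series.analyte_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range=(float(x.min()), float(x.max())),
    )


def estimate_lod_loq(curve: CalibrationCurve, noise_sd: float, height_per_conc: float) -> tuple[float, float]:
    """LOD (S/N = 3) and LOQ (S/N = 10) in concentration units.

    ``height_per_conc`` is the peak height obtained per unit concentration
    (response per µg·mL⁻¹), typically measured on the lowest standard.  The
    limits are attached to ``curve`` and also returned.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if height_per_conc <= 0:
        raise ValueError("height_per_conc must be > 0")
    lod = 3.0 * noise_sd / height_per_conc
    loq = 10.0 * noise_sd / height_per_conc
    curve.lod = lod
    curve.loq = loq
    return lod, loq


def es_content(curve: CalibrationCurve, area: float) -> float:
    """External-standard concentration: X = (area − intercept) / slope.

    Predictions outside the fitted linear range are flagged with a warning
    but returned — sample contents legitimately fall near range edges.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    x = (area - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    if not (lo <= x <= hi):
        warnings.warn(
            f"{curve.analyte_name}: predicted concentration {x:.4g} outside "
            f"linear range [{lo:.4g}, {hi:.4g}]",
            stacklevel=2,
        )
    return x
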