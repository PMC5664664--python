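"""Peak-band quantification, linear calibration curves and detection limits.

Net line intensity is the sum of (processed) counts over the line's
channel band, averaged across replicate acquisitions.  Calibration is
classical: intensity is regressed on reference concentration
(counts = slope·c + intercept, ordinary least squares) and inverted for
prediction.  Detection limits follow the blank-replicate convention:
the qualitative limit (QDL) is 3× and the quantitative limit (QNDL) 10×
the sample standard deviation of repeated blank determinations, both in
mg/kg (the blank intensities are pushed through the calibration curve
first, so the spread is measured in concentration units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import ElementLine, EnergyCalibration, Spectrum, band_channels

#: Regulatory screening levels (mg/kg) for the five elements, secondary
#: soil standard (GB15618-1995).
NATIONAL_LEVELS: dict[str, float] = {
    "Cr": 90.0, "Cu": 35.0, "Zn": 100.0, "As": 20.0, "Pb": 35.0,
}

EXPECTED_BLANK_REPLICATES = 11


class FitError(ValueError):
    """Calibration regression could not be fitted or inverted."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-element linear intensity↔concentration model."""

    element: str
    slope: float            # counts per (mg/kg)
    intercept: float        # counts
    r2: float
    n_points: int
    concentration_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")
        if self.n_points < 3:
            raise ValueError("calibration curve needs >= 3 points")


@dataclass(frozen=True)
class DetectionLimits:
    """3σ/10σ blank-derived limits; qndl/qdl = 10/3 by construction."""

    element: str
    qdl: float
    qndl: float
    n_replicates: int
    blank_sd: float


def net_intensity(s: Spectrum, line: ElementLine, cal: EnergyCalibration) -> float:
    """Sum of counts over the inclusive channel band of ``line``."""
    lo, hi = band_channels(line, cal, n_channels=s.n_channels)
    return float(np.sum(s.counts[lo:hi + 1]))


def replicate_intensity(replicates: Sequence[Spectrum], line: ElementLine,
                        cal: EnergyCalibration) -> float:
    """Arithmetic mean of net intensity over replicate acquisitions."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate spectrum")
    return float(np.mean([net_intensity(r, line, cal) for r in replicates]))


def fit_curve(points: Iterable[tuple[float, float]], element: str) -> CalibrationCurve:
    """OLS fit intensity = slope·concentration + intercept with R².

    ``points`` are (concentration mg/kg, mean net intensity counts) pairs;
    at least three points over at least two distinct concentrations.
    """
    pts = [(float(c), float(i)) for c, i in points]
    if len(pts) < 3:
        raise FitError(f"{element}: need >= 3 calibration points, got {len(pts)}")
    conc = np.array([p[0] for p in pts])
    inten = np.array([p[1] for p in pts])
    if np.unique(conc).size < 2:
        raise FitError(f"{element}: all concentrations equal; fit is degenerate")
    res = stats.linregress(conc, inten)
    return CalibrationCurve(
        element=element,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        n_points=len(pts),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def predict(curve: CalibrationCurve, intensity: float) -> float:
    """Invert the curve: (intensity − intercept)/slope.

    May be negative for blank-level intensities; deliberately not clamped
    so that blank spread statistics stay unbiased.
    """
    if curve.slope == 0:
        raise FitError(f"{curve.element}: zero slope, cannot invert")
    return (float(intensity) - curve.intercept) / curve.slope


def detection_limits(blank_concentrations: Sequence[float], element: str
                     ) -> DetectionLimits:
    """QDL = 3·sd, QNDL = 10·sd of predicted blank concentrations (ddof=1)."""
    vals = np.asarray(list(blank_concentrations), dtype=float)
    if vals.size < 2:
        raise ValueError(f"{element}: need >= 2 blank replicates, got {vals.size}")
    if vals.size != EXPECTED_BLANK_REPLICATES:
        warnings.warn(
            f"{element}: {vals.size} blank replicates "
            f"(the standard protocol uses {EXPECTED_BLANK_REPLICATES})",
            stacklevel=2)
    sd = float(np.std(vals, ddof=1))
    return limits_from_blank_sd(sd, element, n_replicates=int(vals.size))


def limits_from_blank_sd(blank_sd: float, element: str,
                         n_replicates: int = EXPECTED_BLANK_REPLICATES
                         ) -> DetectionLimits:
    """Limits from an already-computed blank standard deviation (mg/kg)."""
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    return DetectionLimits(element=element, qdl=3.0 * blank_sd,
                           qndl=10.0 * blank_sd, n_replicates=n_replicates,
                           blank_sd=blank_sd)


def qndl_from_qdl(qdl: float) -> float:
    """QNDL implied by a reported QDL: (10/3)·QDL (same blank sd)."""
    return qdl * 10.0 / 3.0


def compare_to_threshold(limits: DetectionLimits, national_level: float) -> bool:
    """True iff the quantitative limit meets the regulatory screening level."""
    if not (national_level > 0):
        raise ValueError("national_level must be > 0")
    return limits.qndl <= national_level


def curves_table(curves: Sequence[CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.element, c.slope, c.intercept, c.r2, c.n_points,
          c.concentration_range[0], c.concentration_range[1]) for c in curves],
        columns=["element", "slope", "intercept", "r2", "n_points",
                 "conc_lo_mg_kg", "conc_hi_mg_kg"],
    )


def limits_table(limits: Sequence[DetectionLimits]) -> pd.DataFrame:
    # reporting layer rounds to 2 decimals; full precision stays internal
    return pd.DataFrame(
        [(l.element, round(l.qdl, 2), round(l.qndl, 2), l.n_replicates)
         for l in limits],
        columns=["element", "qdl_mg_kg", "qndl_mg_kg", "n_replicates"],
    )
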