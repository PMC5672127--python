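"""Linear calibration: OLS fitting, intercept-ignorability, external-standard
inversion, and LOD/LOQ from a dilution series.

The core is the sklearn-style :class:`LinearCalibration` estimator
(`fit(X, y)` on concentrations vs areas, `predict` forward, `inverse`
for external-standard quantitation); the module-level functions are thin
wrappers over it that speak the package's domain types.

LOD and LOQ follow the signal-to-noise convention: the concentrations at
which peak *height* reaches 3x and 10x the baseline noise sd.  Height, not
area, because S/N is a height quantity; consequently LOQ/LOD = 10/3 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from qams.chromio import CalibrationCurve, Peak

__all__ = [
    "CalibrationPoint",
    "LodLoq",
    "LinearCalibration",
    "fit_linear",
    "intercept_ignorable",
    "invert_es",
    "lod_loq_from_series",
]

#: |slope/intercept| above which the intercept is negligible and the
#: one-point form X = Y/a is valid.
INTERCEPT_RATIO_THRESHOLD = 100.0


@dataclass
class CalibrationPoint:
    """One calibration observation: concentration X (ug/mL) vs area Y."""

    concentration: float
    area: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not np.isfinite(self.area):
            raise ValueError("area must be finite")


@dataclass
class LodLoq:
    """Detection and quantification limits (ug/mL), at S/N 3 and 10."""

    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not 0 < self.lod < self.loq:
            raise ValueError(f"require 0 < lod < loq, got {self.lod}, {self.loq}")


class LinearCalibration(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares linear response y = a*x + b.

    Parameters
    ----------
    analyte : str
        Analyte name attached to the fitted curve.
    wavelength : float
        Detection wavelength in nm.

    Attributes
    ----------
    slope_a_ : float
        Fitted response slope (area per ug/mL).
    intercept_b_ : float
        Fitted intercept (area units).
    r_squared_ : float
        Coefficient of determination 1 - SS_res/SS_tot.
    range_low_, range_high_ : float
        Concentration span of the training data.
    n_points_ : int
        Number of calibration points.

    Examples
    --------
    >>> import numpy as np
    >>> cal = LinearCalibration(analyte="cholesterol", wavelength=205)
    >>> x = np.array([[1.0], [2.0], [3.0]])
    >>> _ = cal.fit(x, 206.39 * x.ravel() - 1.93)
    >>> round(cal.slope_a_, 2)
    206.39
    """

    def __init__(self, analyte: str = "", wavelength: float = 205.0):
        self.analyte = analyte
        self.wavelength = wavelength

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single concentration column")
        y = np.asarray(y, dtype=float)
        x = X[:, 0]
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        if len(x) < 3:
            raise ValueError(f"need >= 3 calibration points, got {len(x)}")
        if len(np.unique(x)) < 2:
            raise ValueError("degenerate design: all concentrations equal")
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.slope_a_, self.intercept_b_ = float(coef[0]), float(coef[1])
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.range_low_ = float(x.min())
        self.range_high_ = float(x.max())
        self.n_points_ = len(x)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.slope_a_ * X[:, 0] + self.intercept_b_

    def inverse(self, area):
        """External-standard inversion X = (Y - b) / a."""
        return (np.asarray(area, dtype=float) - self.intercept_b_) / self.slope_a_

    def to_curve(self) -> CalibrationCurve:
        """Export the fitted line as a :class:`CalibrationCurve`."""
        return CalibrationCurve(
            analyte=self.analyte,
            wavelength=self.wavelength,
            slope_a=self.slope_a_,
            intercept_b=self.intercept_b_,
            r_squared=max(min(self.r_squared_, 1.0), 0.0),
            range_low=self.range_low_,
            range_high=self.range_high_,
            n_points=self.n_points_,
        )


def fit_linear(
    points: Sequence[CalibrationPoint],
    analyte: str = "",
    wavelength: float = 205.0,
) -> CalibrationCurve:
    """OLS fit of area on concentration; returns the calibration line.

    Requires >= 3 points with >= 2 distinct concentrations; the curve's
    linear range is set to the span of the input concentrations.
    """
    x = np.array([[p.concentration] for p in points])
    y = np.array([p.area for p in points])
    return LinearCalibration(analyte=analyte, wavelength=wavelength).fit(x, y).to_curve()


def intercept_ignorable(curve: CalibrationCurve) -> tuple[bool, float]:
    """Whether the intercept can be dropped: |a/b| > 100.

    Returns (flag, |a/b|); the ratio is infinite for a zero intercept.
    A true flag licenses the one-point form X = Y/a, the premise of
    slope-ratio relative correction factors.
    """
    if curve.intercept_b == 0:
        return True, float("inf")
    ratio = abs(curve.slope_a / curve.intercept_b)
    return ratio > INTERCEPT_RATIO_THRESHOLD, ratio


def invert_es(curve: CalibrationCurve, area: float) -> float:
    """External-standard concentration X = (Y - b) / a.

    Warns (but still returns the value) when the result falls outside the
    curve's fitted linear range — diluted samples routinely do.
    """
    conc = (area - curve.intercept_b) / curve.slope_a
    if not curve.range_low <= conc <= curve.range_high:
        warnings.warn(
            f"{curve.analyte or 'analyte'}: concentration {conc:.6g} ug/mL "
            f"outside calibrated range [{curve.range_low:.6g}, "
            f"{curve.range_high:.6g}]",
            stacklevel=2,
        )
    return conc


def lod_loq_from_series(
    dilution_series: Sequence[tuple[float, Peak]], noise_sd: float
) -> LodLoq:
    """LOD/LOQ from a dilution series and a noise estimate.

    Fits peak height vs concentration through the origin (slope h, mAU per
    ug/mL), then LOD = 3*sd/h and LOQ = 10*sd/h.

    Parameters
    ----------
    dilution_series : sequence of (concentration ug/mL, Peak)
        At least 3 points; heights are baseline-corrected.
    noise_sd : float
        Baseline noise standard deviation in mAU (from
        :func:`qams.peakproc.estimate_noise`), > 0.
    """
    if hasattr(noise_sd, "sd"):  # accept a NoiseEstimate directly
        noise_sd = noise_sd.sd
    if noise_sd <= 0:
        raise ValueError("noise sd must be > 0")
    if len(dilution_series) < 3:
        raise ValueError("need >= 3 dilution points")
    c = np.array([conc for conc, _ in dilution_series], dtype=float)
    h = np.array([peak.height for _, peak in dilution_series], dtype=float)
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("all concentrations zero")
    slope = float(c @ h) / denom  # through-origin least squares
    if slope <= 0:
        raise ValueError(f"non-positive height slope {slope}")
    return LodLoq(lod=3.0 * noise_sd / slope, loq=10.0 * noise_sd / slope)
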