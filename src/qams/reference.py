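"""Published six-sterol reference data for Oviductus Ranae quality control.

The HPLC-DAD assay quantifies six steroids — 7-hydroxycholesterol,
7-ketocholesterol, 4-cholesten-3-one, 7-dehydrocholesterol, cholesterol and
stigmasterol — with cholesterol as the single internal reference.
This module ships the published per-analyte linear calibrations
(slope, intercept, R^2, linear range at each analyte's detection
wavelength) and the mixed-standard panel (detection channel, stock
concentration) as in-code constants, so worked examples and the
command-line tools can run without external files.

Expected relative retention times in :func:`six_sterol_panel` are synthetic:
the published assay does not report absolute retention times, so the panel
uses the simulator's default elution layout (see :mod:`qams.synth`).
"""

from __future__ import annotations

from qams.chromio import AnalytePanel, CalibrationCurve, PanelEntry

__all__ = [
    "CHOLESTEROL",
    "six_sterol_calibrations",
    "six_sterol_panel",
]

CHOLESTEROL = "cholesterol"

# analyte -> (wavelength nm, slope a, intercept b, R^2, range ug/mL)
_CALIBRATIONS = {
    "cholesterol": (205.0, 206.39, -1.93, 1.0000, (1.00e3, 1.20e3)),
    "stigmasterol": (205.0, 1704.6, 16.13, 0.9997, (6.43, 77.21)),
    "7-hydroxycholesterol": (205.0, 316.9, 3.13, 0.9998, (39.47, 473.70)),
    "7-ketocholesterol": (240.0, 1094.3, -0.33, 1.0000, (8.13, 97.57)),
    "4-cholesten-3-one": (240.0, 1120.8, 1.10, 1.0000, (5.05, 60.67)),
    "7-dehydrocholesterol": (280.0, 620.05, -0.42, 0.9999, (2.44, 29.32)),
}

# analyte -> mixed-standard stock concentration, ug/mL
_STOCKS = {
    "7-hydroxycholesterol": 157.9,
    "7-ketocholesterol": 32.525,
    "4-cholesten-3-one": 20.225,
    "7-dehydrocholesterol": 9.775,
    "cholesterol": 4.00e3,
    "stigmasterol": 25.738,
}

# synthetic elution layout (minutes); cholesterol-relative ratios feed
# expected_rtt below and the simulator's default peak placement
DEFAULT_RETENTION_TIMES = {
    "7-hydroxycholesterol": 4.5,
    "7-ketocholesterol": 6.0,
    "4-cholesten-3-one": 7.5,
    "7-dehydrocholesterol": 9.0,
    "cholesterol": 10.5,
    "stigmasterol": 12.5,
}


def six_sterol_calibrations() -> list[CalibrationCurve]:
    """The published six calibration lines, one per analyte."""
    return [
        CalibrationCurve(
            analyte=name,
            wavelength=wl,
            slope_a=a,
            intercept_b=b,
            r_squared=r2,
            range_low=lo,
            range_high=hi,
            n_points=8,
        )
        for name, (wl, a, b, r2, (lo, hi)) in _CALIBRATIONS.items()
    ]


def six_sterol_panel() -> AnalytePanel:
    """The six-sterol panel with cholesterol as internal reference.

    Stock concentrations and detection wavelengths are the published ones;
    expected relative retention times come from the synthetic elution layout.
    """
    t_ref = DEFAULT_RETENTION_TIMES[CHOLESTEROL]
    entries = [
        PanelEntry(
            name=name,
            detection_wavelength=_CALIBRATIONS[name][0],
            expected_rtt=1.0 if name == CHOLESTEROL
            else DEFAULT_RETENTION_TIMES[name] / t_ref,
            stock_concentration=_STOCKS[name],
        )
        for name in _CALIBRATIONS
    ]
    return AnalytePanel(analytes=entries, reference_analyte=CHOLESTEROL)
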