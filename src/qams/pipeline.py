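"""End-to-end wiring: chromatograms -> peaks -> assignments -> areas ->
calibration curves / quantitation.  Used by the command-line interface and
by anyone scripting the whole workflow.

Each analyte is always measured on its own detection channel; the internal
reference's peak is located on every channel (it responds everywhere) so
relative retention times are available per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from qams.calibration import CalibrationPoint, fit_linear
from qams.chromio import AnalytePanel, CalibrationCurve, Chromatogram, SamplePrep
from qams.peakproc import estimate_baseline, detect_peaks
from qams.qams_core import (
    RCFTable,
    QuantResult,
    assign_peaks,
    quantify_es,
    quantify_qams,
    to_mass_fraction,
)

__all__ = [
    "PipelineConfig",
    "measure_areas",
    "calibrate_from_series",
    "quantify_sample",
]


@dataclass
class PipelineConfig:
    """Thresholds for the detection/assignment stages (units as documented
    in the respective modules)."""

    baseline_window: float = 1.0  # minutes
    min_height: float = 10.0  # mAU
    min_width: float = 0.01  # minutes
    rtt_tolerance: float = 0.05  # fraction
    reference_window: tuple[float, float] | None = None  # minutes


def measure_areas(
    chromatograms: Mapping[float, Chromatogram],
    panel: AnalytePanel,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Detect, assign and integrate: per-analyte peak area on its own channel.

    Analytes whose peak is not found on their channel are omitted from the
    result (with a warning).
    """
    config = config or PipelineConfig()
    areas: dict[str, float] = {}
    for channel, chrom in chromatograms.items():
        wanted = [
            a.name for a in panel.analytes if a.detection_wavelength == channel
        ]
        if not wanted:
            continue
        baseline = estimate_baseline(chrom, config.baseline_window)
        peaks = detect_peaks(chrom, baseline, config.min_height, config.min_width)
        assignments = assign_peaks(
            peaks,
            panel,
            rtt_tolerance=config.rtt_tolerance,
            reference_window=config.reference_window,
        )
        found = {a.analyte: a for a in assignments}
        for name in wanted:
            if name in found:
                areas[name] = found[name].peak.area
            else:
                warnings.warn(
                    f"{name}: no peak assigned on its {channel} nm channel",
                    stacklevel=2,
                )
    return areas


def calibrate_from_series(
    runs: Sequence,
    panel: AnalytePanel,
    config: PipelineConfig | None = None,
) -> list[CalibrationCurve]:
    """Fit per-analyte calibration lines from measured series areas.

    `runs` is a sequence of objects with `concentrations` (analyte -> ug/mL)
    and `chromatograms` (channel -> Chromatogram), e.g.
    :class:`qams.synth.CalibrationRun` or equivalents loaded from disk.
    """
    points: dict[str, list[CalibrationPoint]] = {n: [] for n in panel.names}
    for run in runs:
        areas = measure_areas(run.chromatograms, panel, config)
        for name, area in areas.items():
            points[name].append(
                CalibrationPoint(
                    concentration=run.concentrations[name], area=area
                )
            )
    curves = []
    for entry in panel.analytes:
        pts = points[entry.name]
        if len(pts) < 3:
            raise ValueError(
                f"{entry.name}: only {len(pts)} usable calibration points"
            )
        curves.append(
            fit_linear(
                pts, analyte=entry.name, wavelength=entry.detection_wavelength
            )
        )
    return curves


def quantify_sample(
    chromatograms: Mapping[float, Chromatogram],
    panel: AnalytePanel,
    curves: Sequence[CalibrationCurve],
    rcf: RCFTable,
    prep: SamplePrep | None = None,
    mode: str = "both",
    config: PipelineConfig | None = None,
) -> list[QuantResult]:
    """Quantify one sample by the external-standard and/or single-marker route.

    Returns one :class:`QuantResult` per assigned analyte, with mass
    fractions when `prep` is given and the ES-vs-QAMS relative error when
    both routes ran.
    """
    if mode not in ("es", "qams", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    by_name = {c.analyte: c for c in curves}
    areas = measure_areas(chromatograms, panel, config)
    results: list[QuantResult] = []
    for name in panel.names:
        if name not in areas:
            continue
        area = areas[name]
        conc_es = conc_qams = None
        if mode in ("es", "both"):
            conc_es = quantify_es(area, by_name[name])
        if mode in ("qams", "both"):
            conc_qams = quantify_qams(area, rcf, name)
        rel_err = (
            100.0 * (conc_qams - conc_es) / conc_es
            if conc_es not in (None, 0) and conc_qams is not None
            else None
        )
        results.append(
            QuantResult(
                analyte=name,
                conc_es=conc_es,
                conc_qams=conc_qams,
                mass_fraction_es=(
                    to_mass_fraction(conc_es, prep)
                    if prep and conc_es is not None
                    else None
                ),
                mass_fraction_qams=(
                    to_mass_fraction(conc_qams, prep)
                    if prep and conc_qams is not None
                    else None
                ),
                relative_error=rel_err,
            )
        )
    return results
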