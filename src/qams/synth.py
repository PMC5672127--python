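"""Synthetic multi-wavelength chromatogram generator with known ground truth.

Emulates an isocratic HPLC-DAD acquisition of the six-sterol panel:
Gaussian peaks whose areas follow the published linear response slopes on
each analyte's detection channel (off-channel response defaults to 10% of
the own-channel slope so that every peak is visible on every channel, as a
real DAD trace would show), a linear baseline drift, i.i.d. Gaussian
detector noise, and multiplicative retention-time jitter composed of a
shared per-run factor (emulating flow-rate variation, which cancels in
relative retention times) plus a small independent per-peak term.

What it does not emulate: tailing/fronting peak shapes, gradient elution,
detector saturation, or matrix interferences.  Everything is reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from qams.chromio import AnalytePanel, CalibrationCurve, Chromatogram, SamplePrep
from qams.reference import DEFAULT_RETENTION_TIMES

__all__ = [
    "AnalyteTruth",
    "SimulationTruth",
    "CalibrationRun",
    "BatchRecord",
    "make_truth",
    "simulate_chromatogram",
    "simulate_run",
    "simulate_calibration_series",
    "simulate_batch_study",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: default extract: 2.0 g of powder into 2 mL of methanol
DEFAULT_PREP = SamplePrep(sample_mass=2.0, extract_volume=2.0)

#: realistic per-batch extract concentration ranges (ug/mL) mirroring the
#: content spread of genuine material (reference sterol dominant)
DEFAULT_CONCENTRATION_RANGES: dict[str, tuple[float, float]] = {
    "cholesterol": (2.1e3, 3.9e3),
    "7-hydroxycholesterol": (53.0, 81.0),
    "7-ketocholesterol": (11.5, 22.0),
    "4-cholesten-3-one": (5.8, 9.2),
    "stigmasterol": (11.2, 15.6),
    "7-dehydrocholesterol": (3.7, 6.1),
}

#: injection-volume series relative to the 20 uL reference volume
#: (5, 10, 15, 20, 30, 40, 50, 60 uL)
DEFAULT_VOLUME_FRACTIONS = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class AnalyteTruth:
    """Ground truth for one simulated analyte."""

    true_concentration: float  # ug/mL
    true_apex_time: float  # minutes, before jitter
    true_sigma: float  # minutes
    response_slope: dict[float, float]  # channel nm -> area per (ug/mL)

    def __post_init__(self) -> None:
        if self.true_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.true_sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SimulationTruth:
    """Full ground truth of a simulated acquisition."""

    analytes: dict[str, AnalyteTruth]
    seed: int
    noise_sd: float = 0.2  # mAU
    drift: float = 0.5  # mAU per minute
    rt_jitter_sd: float = 0.003  # shared multiplicative factor, fraction
    peak_jitter_sd: float = 0.0005  # independent per-peak factor, fraction

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.rt_jitter_sd < 0 or self.peak_jitter_sd < 0:
            raise ValueError("noise and jitter magnitudes must be >= 0")

    def with_concentrations(
        self, concentrations: Mapping[str, float]
    ) -> "SimulationTruth":
        """Copy with replaced concentrations (other parameters shared)."""
        return SimulationTruth(
            analytes={
                name: AnalyteTruth(
                    true_concentration=float(concentrations[name]),
                    true_apex_time=a.true_apex_time,
                    true_sigma=a.true_sigma,
                    response_slope=dict(a.response_slope),
                )
                for name, a in self.analytes.items()
            },
            seed=self.seed,
            noise_sd=self.noise_sd,
            drift=self.drift,
            rt_jitter_sd=self.rt_jitter_sd,
            peak_jitter_sd=self.peak_jitter_sd,
        )


@dataclass
class CalibrationRun:
    """One injection level of a calibration series, with its ground truth."""

    volume_fraction: float
    concentrations: dict[str, float]  # effective on-column, ug/mL
    chromatograms: dict[float, Chromatogram]  # channel -> trace


@dataclass
class BatchRecord:
    """One simulated sample batch: traces per channel, prep, ground truth."""

    chromatograms: dict[float, Chromatogram]
    prep: SamplePrep
    truth: SimulationTruth


def make_truth(
    panel: AnalytePanel,
    curves: Sequence[CalibrationCurve],
    concentrations: Mapping[str, float] | None = None,
    retention_times: Mapping[str, float] | None = None,
    sigma: float | Mapping[str, float] = 0.05,
    off_channel_response: float = 0.10,
    seed: int = 0,
    noise_sd: float = 0.2,
    drift: float = 0.5,
    rt_jitter_sd: float = 0.003,
    peak_jitter_sd: float = 0.0005,
) -> SimulationTruth:
    """Assemble a :class:`SimulationTruth` for a panel.

    Response slopes on each analyte's own detection channel come from its
    calibration curve; on the other channels the slope defaults to
    `off_channel_response` (10%) of the own-channel slope.  Concentrations
    default to the panel's stock concentrations; retention times default to
    the package's synthetic elution layout.
    """
    by_name = {c.analyte: c for c in curves}
    rts = dict(retention_times or DEFAULT_RETENTION_TIMES)
    channels = panel.wavelengths
    analytes: dict[str, AnalyteTruth] = {}
    for entry in panel.analytes:
        curve = by_name[entry.name]
        sig = sigma[entry.name] if isinstance(sigma, Mapping) else float(sigma)
        conc = (
            float(concentrations[entry.name])
            if concentrations is not None
            else entry.stock_concentration
        )
        slopes = {
            ch: curve.slope_a
            if ch == entry.detection_wavelength
            else off_channel_response * curve.slope_a
            for ch in channels
        }
        analytes[entry.name] = AnalyteTruth(
            true_concentration=conc,
            true_apex_time=rts[entry.name],
            true_sigma=sig,
            response_slope=slopes,
        )
    return SimulationTruth(
        analytes=analytes,
        seed=seed,
        noise_sd=noise_sd,
        drift=drift,
        rt_jitter_sd=rt_jitter_sd,
        peak_jitter_sd=peak_jitter_sd,
    )


def _jittered_apexes(truth: SimulationTruth, seed: int) -> dict[str, float]:
    """Per-run jittered apex times, shared across channels of the run."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    shared = 1.0 + truth.rt_jitter_sd * rng.standard_normal()
    names = sorted(truth.analytes)
    per_peak = 1.0 + truth.peak_jitter_sd * rng.standard_normal(len(names))
    return {
        name: truth.analytes[name].true_apex_time * shared * per_peak[i]
        for i, name in enumerate(names)
    }


def simulate_chromatogram(
    truth: SimulationTruth,
    panel: AnalytePanel,
    wavelength: float,
    duration: float = 15.0,
    dt: float = 0.005,
    seed: int | None = None,
) -> Chromatogram:
    """Simulate one detector channel of one injection.

    The trace is the sum of Gaussian peaks (area = channel slope x
    concentration), a linear drift and white noise.  Retention-time jitter
    depends only on `seed`, so calling with the same seed at different
    wavelengths yields channels of the *same* physical run; the noise
    realisation differs per channel.

    Raises
    ------
    ValueError
        If `dt` exceeds one fifth of the narrowest peak sigma, or `duration`
        does not cover every apex plus five sigma.
    """
    seed = truth.seed if seed is None else seed
    sigmas = [a.true_sigma for a in truth.analytes.values()]
    if sigmas and dt > min(sigmas) / 5.0:
        raise ValueError(
            f"dt = {dt} min too coarse for narrowest sigma {min(sigmas)} min"
        )
    apexes = _jittered_apexes(truth, seed)
    late = max(
        (apexes[n] + 5 * a.true_sigma for n, a in truth.analytes.items()),
        default=0.0,
    )
    if duration < late:
        raise ValueError(f"duration {duration} min does not cover peaks (need {late:.3g})")

    times = np.arange(0.0, duration + dt / 2, dt)
    signal = truth.drift * times
    for name, a in truth.analytes.items():
        area = a.response_slope.get(float(wavelength), 0.0) * a.true_concentration
        if area <= 0:
            continue
        amplitude = area / (a.true_sigma * SQRT_2PI)
        signal = signal + amplitude * np.exp(
            -0.5 * ((times - apexes[name]) / a.true_sigma) ** 2
        )
    rng = np.random.default_rng([seed & 0x7FFFFFFF, int(wavelength)])
    if truth.noise_sd > 0:
        signal = signal + truth.noise_sd * rng.standard_normal(len(times))
    return Chromatogram(
        times,
        signal,
        float(wavelength),
        meta={"synthetic": "true", "seed": str(seed)},
    )


def simulate_run(
    truth: SimulationTruth,
    panel: AnalytePanel,
    duration: float = 15.0,
    dt: float = 0.005,
    seed: int | None = None,
) -> dict[float, Chromatogram]:
    """All detector channels of one injection (shared retention jitter)."""
    return {
        ch: simulate_chromatogram(truth, panel, ch, duration, dt, seed)
        for ch in panel.wavelengths
    }


def simulate_calibration_series(
    truth: SimulationTruth,
    panel: AnalytePanel,
    volume_fractions: Sequence[float] = DEFAULT_VOLUME_FRACTIONS,
    seed: int | None = None,
    duration: float = 15.0,
    dt: float = 0.005,
) -> list[CalibrationRun]:
    """Injection-volume calibration series of the mixed standard.

    Each level scales every analyte's effective on-column concentration by
    its volume fraction (relative to the 20 uL reference volume); `truth`
    concentrations define the fraction-1 level.
    """
    if len(volume_fractions) == 0:
        raise ValueError("empty volume-fraction series")
    if any(f <= 0 for f in volume_fractions):
        raise ValueError("volume fractions must be > 0")
    seed = truth.seed if seed is None else seed
    runs: list[CalibrationRun] = []
    for i, frac in enumerate(volume_fractions):
        conc = {
            name: a.true_concentration * frac for name, a in truth.analytes.items()
        }
        level_truth = truth.with_concentrations(conc)
        runs.append(
            CalibrationRun(
                volume_fraction=float(frac),
                concentrations=conc,
                chromatograms=simulate_run(
                    level_truth, panel, duration, dt, seed=seed + 1000 + i
                ),
            )
        )
    return runs


def simulate_batch_study(
    n_batches: int,
    panel: AnalytePanel,
    curves: Sequence[CalibrationCurve],
    concentration_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    prep: SamplePrep = DEFAULT_PREP,
    duration: float = 15.0,
    dt: float = 0.005,
    **truth_kwargs,
) -> list[BatchRecord]:
    """Simulate a multi-batch sample study with known per-batch contents.

    Each batch draws its analyte concentrations uniformly within
    `concentration_ranges` (defaults emulate the content spread of real
    material) and is acquired on every panel channel.
    """
    if n_batches < 1:
        raise ValueError("need n_batches >= 1")
    ranges = dict(concentration_ranges or DEFAULT_CONCENTRATION_RANGES)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"{name}: inverted concentration range ({lo}, {hi})")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xBA7C])
    records: list[BatchRecord] = []
    for b in range(n_batches):
        conc = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()
        }
        truth = make_truth(
            panel, curves, concentrations=conc, seed=seed + 2000 + b, **truth_kwargs
        )
        records.append(
            BatchRecord(
                chromatograms=simulate_run(truth, panel, duration, dt),
                prep=prep,
                truth=truth,
            )
        )
    return records
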