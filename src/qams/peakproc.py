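"""Baseline estimation, peak detection/integration, noise estimation and
system-suitability metrics (theoretical plates, resolution).

Conventions
-----------
Signal-to-noise is defined as baseline-corrected peak height divided by the
standard deviation of the detrended baseline noise; the 3x / 10x multipliers
for LOD/LOQ live in :mod:`qams.calibration`.  Fused peaks are split at the
valley minimum between apexes (perpendicular-drop convention, the common
chromatography-workstation default).  Width at half height is obtained by
linear interpolation of the half-height crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy import ndimage as _ndi

from qams.chromio import Chromatogram, Peak

__all__ = [
    "BaselineModel",
    "NoiseEstimate",
    "estimate_baseline",
    "detect_peaks",
    "integrate_peak",
    "estimate_noise",
    "signal_to_noise",
    "plate_count",
    "resolution",
]


@dataclass
class BaselineModel:
    """Estimated baseline on the same time grid as its source chromatogram."""

    times: np.ndarray
    baseline_values: np.ndarray
    method_tag: str = "rolling-min"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.baseline_values = np.asarray(self.baseline_values, dtype=float)
        if len(self.times) != len(self.baseline_values):
            raise ValueError("baseline grid/value length mismatch")
        if not np.all(np.isfinite(self.baseline_values)):
            raise ValueError("baseline values must be finite")

    @classmethod
    def zero(cls, chrom: Chromatogram) -> "BaselineModel":
        """An all-zero baseline (for already-corrected or synthetic traces)."""
        return cls(chrom.times, np.zeros_like(chrom.times), "zero")


@dataclass
class NoiseEstimate:
    """Noise standard deviation measured over a peak-free region."""

    sd: float
    region_start: float
    region_end: float
    n_points: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_points < 20:
            raise ValueError(f"noise region too short: {self.n_points} points")


def estimate_baseline(chrom: Chromatogram, window: float) -> BaselineModel:
    """Rolling-minimum baseline followed by a same-window rolling mean.

    `window` is in minutes and must span at least 5 sampling intervals and
    at most the trace. A window much wider than the widest peak (>= ~8 sigma)
    keeps the baseline under the peaks; narrower windows start eating into
    them.
    """
    dt = chrom.sampling_interval
    span = chrom.times[-1] - chrom.times[0]
    if window < 5 * dt:
        raise ValueError(
            f"baseline window {window} min must be >= 5 sampling intervals "
            f"({5 * dt:.4g} min)"
        )
    if window > span:
        raise ValueError(f"baseline window {window} min exceeds trace span {span:.4g}")
    n = max(int(round(window / dt)) | 1, 5)  # odd, >= 5 samples
    rolled = _ndi.minimum_filter1d(chrom.intensities, size=n, mode="nearest")
    smooth = _ndi.uniform_filter1d(rolled, size=n, mode="nearest")
    return BaselineModel(chrom.times, smooth, "rolling-min+mean")


def _half_width(
    times: np.ndarray, corrected: np.ndarray, apex: int, left: int, right: int
) -> float:
    """Width at half of baseline-corrected height, linearly interpolated."""
    half = corrected[apex] / 2.0
    t_left = times[left]
    for i in range(apex, left, -1):
        if corrected[i - 1] <= half <= corrected[i]:
            frac = (half - corrected[i - 1]) / (corrected[i] - corrected[i - 1])
            t_left = times[i - 1] + frac * (times[i] - times[i - 1])
            break
    t_right = times[right]
    for i in range(apex, right):
        if corrected[i + 1] <= half <= corrected[i]:
            frac = (corrected[i] - half) / (corrected[i] - corrected[i + 1])
            t_right = times[i] + frac * (times[i + 1] - times[i])
            break
    return max(t_right - t_left, times[1] - times[0])


def detect_peaks(
    chrom: Chromatogram,
    baseline: BaselineModel,
    min_height: float,
    min_width: float,
) -> list[Peak]:
    """Detect peaks in the baseline-corrected signal.

    Local maxima above `min_height` (mAU) with width >= `min_width`
    (minutes) are kept. Peak bounds extend from the apex to the nearest
    valley (local minimum shared with a neighbouring peak) or to the
    baseline crossing, whichever comes first; areas therefore partition
    fused envelopes. Returned peaks are ordered by apex time.
    """
    if min_height <= 0 or min_width <= 0:
        raise ValueError("min_height and min_width must be > 0")
    corrected = chrom.intensities - baseline.baseline_values
    dt = chrom.sampling_interval
    idx, _props = _sig.find_peaks(
        corrected, height=min_height, width=max(min_width / dt, 1.0)
    )
    if len(idx) == 0:
        return []

    n = len(corrected)
    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        # left bound: valley shared with the previous peak, unless the signal
        # returns to baseline first
        if k > 0:
            valley = int(np.argmin(corrected[idx[k - 1]:apex + 1])) + idx[k - 1]
        else:
            valley = 0
        left = apex
        while left > valley and corrected[left - 1] > 0:
            left -= 1
        left = max(left, valley)
        # right bound, symmetric
        if k + 1 < len(idx):
            valley = int(np.argmin(corrected[apex:idx[k + 1] + 1])) + apex
        else:
            valley = n - 1
        right = apex
        while right < valley and corrected[right + 1] > 0:
            right += 1
        right = min(right, valley)

        if apex <= left or apex >= right:
            continue
        height = float(corrected[apex])
        area = integrate_peak(
            chrom, baseline, float(chrom.times[left]), float(chrom.times[right])
        )
        peaks.append(
            Peak(
                apex_time=float(chrom.times[apex]),
                start_time=float(chrom.times[left]),
                end_time=float(chrom.times[right]),
                height=height,
                area=area,
                width_half=_half_width(chrom.times, corrected, apex, left, right),
            )
        )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def integrate_peak(
    chrom: Chromatogram, baseline: BaselineModel, start: float, end: float
) -> float:
    """Trapezoidal integral of max(signal - baseline, 0) over [start, end].

    Endpoints may fall between grid points; the signal is linearly
    interpolated there, so integrating [a,b] and [b,c] sums to [a,c].
    """
    if start >= end:
        raise ValueError(f"require start < end, got {start} >= {end}")
    if start < chrom.times[0] or end > chrom.times[-1]:
        raise ValueError(
            f"[{start}, {end}] outside grid "
            f"[{chrom.times[0]}, {chrom.times[-1]}]"
        )
    corrected = np.maximum(chrom.intensities - baseline.baseline_values, 0.0)
    inside = (chrom.times > start) & (chrom.times < end)
    t = np.concatenate(([start], chrom.times[inside], [end]))
    y = np.concatenate(
        (
            [np.interp(start, chrom.times, corrected)],
            corrected[inside],
            [np.interp(end, chrom.times, corrected)],
        )
    )
    return float(np.trapezoid(y, t))


def estimate_noise(
    chrom: Chromatogram,
    region_start: float,
    region_end: float,
    peaks: list[Peak] | None = None,
) -> NoiseEstimate:
    """Noise sd over a peak-free region, after removing a linear trend.

    If `peaks` is given, a region overlapping any peak's [start, end] is
    rejected as contaminated.
    """
    if region_start >= region_end:
        raise ValueError("require region_start < region_end")
    if region_start < chrom.times[0] or region_end > chrom.times[-1]:
        raise ValueError("noise region outside chromatogram")
    if peaks:
        for p in peaks:
            if region_start < p.end_time and p.start_time < region_end:
                raise ValueError(
                    f"noise region [{region_start}, {region_end}] overlaps "
                    f"peak at {p.apex_time:.3g} min"
                )
    mask = (chrom.times >= region_start) & (chrom.times <= region_end)
    t = chrom.times[mask]
    y = chrom.intensities[mask]
    if len(t) < 20:
        raise ValueError(f"noise region has {len(t)} points (need >= 20)")
    trend = np.polynomial.Polynomial.fit(t, y, 1)(t)
    sd = float(np.std(y - trend, ddof=1))
    return NoiseEstimate(
        sd=sd, region_start=region_start, region_end=region_end, n_points=len(t)
    )


def signal_to_noise(peak: Peak, noise: NoiseEstimate) -> float:
    """S/N = baseline-corrected height / noise sd."""
    if noise.sd <= 0:
        raise ZeroDivisionError("noise sd must be > 0 for an S/N ratio")
    return peak.height / noise.sd


def plate_count(peak: Peak) -> float:
    """Theoretical plates from the half-height width: N = 5.54 (t_R / w_half)^2."""
    return 5.54 * (peak.apex_time / peak.width_half) ** 2


def resolution(peak1: Peak, peak2: Peak) -> float:
    """Resolution Rs = 2 (t2 - t1) / (w1 + w2) with baseline widths."""
    if not peak1.apex_time < peak2.apex_time:
        raise ValueError("peak1 must elute before peak2")
    return 2.0 * (peak2.apex_time - peak1.apex_time) / (
        peak1.base_width + peak2.base_width
    )
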