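"""Single-marker multi-component quantitation (QAMS).

The idea: when every analyte's calibration line passes near enough to the
origin (|a/b| > 100), its calibration collapses to X = Y/a, and any
analyte K can be quantified from the internal reference S alone through the
relative correction factor

    f_{K/S} = a_K / a_S,        X_K = Y_K / (f_{K/S} * a_S).

Only the reference standard is ever injected; the factors, once established,
transfer across runs.  Peaks are located by relative retention time
R = t_K / t_S — a ratio that cancels uniform flow-rate or dead-volume
shifts — with optional confirmation by UV-spectrum similarity from the
diode-array detector.

The external-standard (ES) route, X = (Y - b)/a per analyte, is kept
alongside as the conventional comparator; agreement of the two is the
method's accuracy check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from qams.calibration import intercept_ignorable, invert_es
from qams.chromio import AnalytePanel, CalibrationCurve, Peak, SamplePrep

__all__ = [
    "read_rcf_table",
    "write_rcf_table",
    "RCFTable",
    "PeakAssignment",
    "QuantResult",
    "QamsQuantifier",
    "relative_correction_factor",
    "build_rcf_table",
    "relative_retention_time",
    "assign_peaks",
    "spectral_similarity",
    "quantify_qams",
    "quantify_es",
    "to_mass_fraction",
    "compare_methods",
]

#: default fractional tolerance for relative-retention-time matching
DEFAULT_RTT_TOLERANCE = 0.05


@dataclass
class RCFTable:
    """Relative correction factors anchored to one internal reference.

    factors[k] = a_k / a_ref; the reference's own factor is exactly 1.
    `reference_slope` is the reference's calibration slope a_S, so any
    analyte's concentration is area / (factors[k] * reference_slope).
    """

    reference_analyte: str
    reference_slope: float
    factors: dict[str, float]
    wavelength_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_analyte not in self.factors:
            raise ValueError("reference analyte missing from factor table")
        if self.factors[self.reference_analyte] != 1.0:
            raise ValueError("reference factor must be exactly 1")
        if not self.reference_slope > 0:
            raise ValueError("reference slope must be > 0")
        for name, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"factor for {name} must be > 0, got {f}")

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Factors rounded for display (4 decimals by convention)."""
        return {k: round(v, ndigits) for k, v in self.factors.items()}


@dataclass
class PeakAssignment:
    """A peak identified as one panel analyte via relative retention time."""

    analyte: str
    peak: Peak
    rtt_observed: float
    rtt_expected: float
    rtt_deviation: float
    spectral_score: float | None = None

    def __post_init__(self) -> None:
        if not self.rtt_observed > 0:
            raise ValueError("rtt_observed must be > 0")


@dataclass
class QuantResult:
    """Per-analyte quantitation by the external-standard and/or single-marker
    route, with their relative disagreement when both are present."""

    analyte: str
    conc_es: float | None = None
    conc_qams: float | None = None
    mass_fraction_es: float | None = None
    mass_fraction_qams: float | None = None
    relative_error: float | None = None


def relative_correction_factor(
    curve_k: CalibrationCurve, curve_s: CalibrationCurve
) -> float:
    """f_{K/S} = a_K / a_S, the slope ratio of analyte over reference.

    Warns if either line's intercept is not ignorable (|a/b| <= 100), since
    the slope-ratio shortcut assumes the one-point form X = Y/a.
    """
    if curve_k.slope_a <= 0 or curve_s.slope_a <= 0:
        raise ValueError("calibration slopes must be > 0")
    for curve in (curve_k, curve_s):
        ok, ratio = intercept_ignorable(curve)
        if not ok:
            warnings.warn(
                f"{curve.analyte or 'curve'}: |a/b| = {ratio:.3g} <= 100; "
                "intercept not ignorable, slope-ratio factor is approximate",
                stacklevel=2,
            )
    return curve_k.slope_a / curve_s.slope_a


def build_rcf_table(
    curves: Sequence[CalibrationCurve], reference: str
) -> RCFTable:
    """Relative correction factors for a whole panel of calibration lines.

    The reference's factor is set to exactly 1 (not computed), so repeated
    rebuilds and slope rescalings cannot drift it.
    """
    by_name: dict[str, CalibrationCurve] = {}
    for c in curves:
        if c.analyte in by_name:
            raise ValueError(f"duplicate curve for {c.analyte}")
        by_name[c.analyte] = c
    if reference not in by_name:
        raise ValueError(f"reference {reference!r} has no calibration curve")
    ref = by_name[reference]
    factors = {
        name: 1.0 if name == reference else relative_correction_factor(c, ref)
        for name, c in by_name.items()
    }
    return RCFTable(
        reference_analyte=reference,
        reference_slope=ref.slope_a,
        factors=factors,
        wavelength_map={name: c.wavelength for name, c in by_name.items()},
    )


def relative_retention_time(t_k: float, t_s: float) -> float:
    """R = t_K / t_S; invariant under uniform time rescaling."""
    if t_k <= 0 or t_s <= 0:
        raise ValueError("retention times must be > 0")
    return t_k / t_s


def assign_peaks(
    peaks: Sequence[Peak],
    panel: AnalytePanel,
    rtt_tolerance: float = DEFAULT_RTT_TOLERANCE,
    reference_window: tuple[float, float] | None = None,
) -> list[PeakAssignment]:
    """Identify panel analytes among detected peaks by relative retention time.

    The reference peak is taken as the largest-area peak inside
    `reference_window` (absolute minutes; the whole trace when None) — the
    reference is by design the dominant constituent, so area is the robust
    criterion.  Every other peak's retention-time ratio against it is then
    matched to the panel's expected ratios: each analyte takes the peak with
    the smallest fractional deviation within `rtt_tolerance`, greedily from
    the smallest deviation, ties broken toward the larger area, and no peak
    is assigned twice.  Analytes with no matching peak are simply omitted.

    Raises
    ------
    ValueError
        If no reference candidate exists, or an exact deviation-and-area tie
        makes an assignment ambiguous, or the tolerance is outside (0, 0.2].
    """
    if not 0 < rtt_tolerance <= 0.2:
        raise ValueError(f"rtt_tolerance must be in (0, 0.2], got {rtt_tolerance}")
    if reference_window is None:
        candidates = list(peaks)
    else:
        lo, hi = reference_window
        candidates = [p for p in peaks if lo <= p.apex_time <= hi]
    if not candidates:
        raise ValueError("no candidate reference peak found")
    ref_peak = max(candidates, key=lambda p: p.area)
    t_ref = ref_peak.apex_time

    # (deviation, -area, analyte, peak) over all in-tolerance pairs
    matches: list[tuple[float, float, str, Peak]] = []
    for entry in panel.analytes:
        for p in peaks:
            if entry.name == panel.reference_analyte and p is not ref_peak:
                continue  # the reference is pinned to the identified peak
            r = relative_retention_time(p.apex_time, t_ref)
            dev = abs(r - entry.expected_rtt) / entry.expected_rtt
            if dev <= rtt_tolerance:
                matches.append((dev, -p.area, entry.name, p))
    matches.sort(key=lambda m: (m[0], m[1]))

    assigned: dict[str, PeakAssignment] = {}
    used: set[int] = set()
    for i, (dev, neg_area, name, p) in enumerate(matches):
        if name in assigned or id(p) in used:
            continue
        if i + 1 < len(matches):
            ndev, nneg, nname, npeak = matches[i + 1]
            if (
                nname == name
                and id(npeak) not in used
                and npeak is not p
                and ndev == dev
                and nneg == neg_area
            ):
                raise ValueError(
                    f"ambiguous assignment for {name}: two peaks at identical "
                    f"deviation {dev:.4g} and area {-neg_area:.6g}"
                )
        r = relative_retention_time(p.apex_time, t_ref)
        entry = panel[name]
        assigned[name] = PeakAssignment(
            analyte=name,
            peak=Peak(
                apex_time=p.apex_time,
                start_time=p.start_time,
                end_time=p.end_time,
                height=p.height,
                area=p.area,
                width_half=p.width_half,
                analyte=name,
            ),
            rtt_observed=r,
            rtt_expected=entry.expected_rtt,
            rtt_deviation=(r - entry.expected_rtt) / entry.expected_rtt,
        )
        used.add(id(p))
    return [assigned[n] for n in panel.names if n in assigned]


def spectral_similarity(
    spectrum_a: tuple[np.ndarray, np.ndarray],
    spectrum_b: tuple[np.ndarray, np.ndarray],
) -> float:
    """Cosine similarity of two mean-centred UV spectra in [-1, 1].

    Each spectrum is (wavelengths nm, intensities); `spectrum_b` is linearly
    resampled onto the overlap of the two wavelength grids (>= 5 points
    required).  Scale-invariant: a peak and its diluted copy score 1.
    """
    wl_a, int_a = (np.asarray(v, dtype=float) for v in spectrum_a)
    wl_b, int_b = (np.asarray(v, dtype=float) for v in spectrum_b)
    lo, hi = max(wl_a.min(), wl_b.min()), min(wl_a.max(), wl_b.max())
    mask = (wl_a >= lo) & (wl_a <= hi)
    if mask.sum() < 5:
        raise ValueError("need >= 5 overlapping wavelengths")
    grid = wl_a[mask]
    a = int_a[mask] - int_a[mask].mean()
    b = np.interp(grid, wl_b, int_b)
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance spectrum: similarity undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def quantify_qams(area_k: float, rcf: RCFTable, analyte: str) -> float:
    """Single-marker concentration X = Y / (f_{K/S} * a_S), in ug/mL."""
    if area_k < 0:
        raise ValueError("area must be >= 0")
    if analyte not in rcf.factors:
        raise KeyError(f"analyte {analyte!r} not in factor table")
    return area_k / (rcf.factors[analyte] * rcf.reference_slope)


def quantify_es(area: float, curve: CalibrationCurve) -> float:
    """External-standard concentration X = (Y - b)/a (see :func:`invert_es`)."""
    return invert_es(curve, area)


def to_mass_fraction(conc: float, prep: SamplePrep) -> float:
    """Extract concentration (ug/mL) -> dry-material mass fraction (ug/g)."""
    return conc * prep.extract_volume / prep.sample_mass


def compare_methods(
    es: Mapping[str, float], qams: Mapping[str, float], threshold: float = 2.0
) -> tuple[dict[str, float], float, bool]:
    """Per-analyte relative error of the single-marker route vs the
    external-standard route.

    RE% = 100 * (qams - es) / es per analyte.  Returns (per-analyte RE%,
    max |RE%|, flag) where the flag marks max |RE%| > `threshold` (percent,
    default 2).
    """
    if set(es) != set(qams):
        raise ValueError(
            f"analyte sets differ: {sorted(set(es) ^ set(qams))}"
        )
    errors: dict[str, float] = {}
    for name, es_val in es.items():
        if es_val == 0:
            raise ZeroDivisionError(
                f"{name}: external-standard value is 0, relative error undefined"
            )
        errors[name] = 100.0 * (qams[name] - es_val) / es_val
    max_abs = max(abs(v) for v in errors.values()) if errors else 0.0
    return errors, max_abs, max_abs > threshold


def write_rcf_table(
    rcf: RCFTable, sink, ndigits: int | None = 4
) -> None:
    """Serialize a factor table as CSV (factors rounded to `ndigits`
    decimals for display; None writes full precision)."""
    from qams.chromio import _as_text_stream, _fmt_float  # shared helpers

    stream, should_close = _as_text_stream(sink, "w")
    try:
        stream.write(f"# reference: {rcf.reference_analyte}\n")
        stream.write(
            f"# reference_slope: {_fmt_float(rcf.reference_slope)}\n"
        )
        stream.write("analyte,wavelength,factor\n")
        for name, f in rcf.factors.items():
            wl = rcf.wavelength_map.get(name, float("nan"))
            shown = (
                _fmt_float(f) if ndigits is None else f"{round(f, ndigits)}"
            )
            stream.write(f"{name},{_fmt_float(wl)},{shown}\n")
    finally:
        if should_close:
            stream.close()


def read_rcf_table(source) -> RCFTable:
    """Inverse of :func:`write_rcf_table`."""
    from qams.chromio import _as_text_stream, _split_meta

    stream, should_close = _as_text_stream(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()
    meta, start = _split_meta(lines)
    if "reference" not in meta or "reference_slope" not in meta:
        raise ValueError("factor table missing reference metadata")
    rows = [ln for i, ln in enumerate(lines) if i >= start and ln.strip()]
    header = [c.strip() for c in rows[0].split(",")]
    if header[:3] != ["analyte", "wavelength", "factor"]:
        raise ValueError(f"unexpected factor-table header {header}")
    factors: dict[str, float] = {}
    wl_map: dict[str, float] = {}
    for line in rows[1:]:
        name, wl, f = (t.strip() for t in line.split(",")[:3])
        factors[name] = float(f)
        wl_map[name] = float(wl)
    return RCFTable(
        reference_analyte=meta["reference"],
        reference_slope=float(meta["reference_slope"]),
        factors=factors,
        wavelength_map=wl_map,
    )


class QamsQuantifier(BaseEstimator):
    """Sklearn-style wrapper around the single-marker method.

    `fit` ingests the panel's calibration curves and freezes the relative
    correction factors; `predict` maps peak areas to concentrations.

    Parameters
    ----------
    reference : str
        Internal-reference analyte name.
    mode : {"qams", "es"}
        Quantitation route: single-marker (default) or per-analyte
        external standard.

    Attributes
    ----------
    rcf_table_ : RCFTable
        Factors anchored to the reference (fitted).
    curves_ : dict of str -> CalibrationCurve
        The ingested calibrations (used by the "es" mode).
    analytes_ : list of str
        Column order expected by `predict`.
    """

    def __init__(self, reference: str = "cholesterol", mode: str = "qams"):
        self.reference = reference
        self.mode = mode

    def fit(self, X: Sequence[CalibrationCurve], y=None):
        if self.mode not in ("qams", "es"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.curves_ = {c.analyte: c for c in X}
        self.rcf_table_ = build_rcf_table(list(X), self.reference)
        self.analytes_ = list(self.curves_)
        return self

    def predict(self, X) -> np.ndarray:
        """Concentrations (ug/mL) from peak areas.

        `X` is (n_samples, n_analytes) in `analytes_` order, or a mapping
        analyte -> area for a single sample.
        """
        if isinstance(X, Mapping):
            areas = np.array([[X[name] for name in self.analytes_]])
            return self._predict_matrix(areas)[0]
        return self._predict_matrix(np.atleast_2d(np.asarray(X, dtype=float)))

    def _predict_matrix(self, areas: np.ndarray) -> np.ndarray:
        if areas.shape[1] != len(self.analytes_):
            raise ValueError(
                f"expected {len(self.analytes_)} analyte columns, "
                f"got {areas.shape[1]}"
            )
        out = np.empty_like(areas)
        for j, name in enumerate(self.analytes_):
            if self.mode == "qams":
                f = self.rcf_table_.factors[name]
                out[:, j] = areas[:, j] / (f * self.rcf_table_.reference_slope)
            else:
                curve = self.curves_[name]
                out[:, j] = (areas[:, j] - curve.intercept_b) / curve.slope_a
        return out
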