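"""Domain types and delimited-text I/O for chromatograms, peak tables,
calibration tables and analyte-panel configuration.

Unit convention, fixed package-wide and never inferred from files:
times in minutes, detector response in mAU, peak areas in mAU*min,
concentrations in ug/mL, mass fractions in ug/g, wavelengths in nm.

File format: comma-separated with a mandatory header row; an optional
leading block of ``#``-prefixed ``key: value`` lines carries acquisition
metadata (wavelength, instrument, column, ...).  Numeric fields are written
with the shortest decimal rendering that round-trips the IEEE double, so
read(write(x)) is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Chromatogram",
    "Peak",
    "CalibrationCurve",
    "AnalytePanel",
    "PanelEntry",
    "SamplePrep",
    "ChromatogramParseError",
    "read_chromatogram",
    "write_chromatogram",
    "read_calibration_table",
    "write_calibration_table",
    "read_peak_table",
    "write_peak_table",
    "load_panel",
    "panel_to_dict",
]


class ChromatogramParseError(ValueError):
    """Malformed delimited chromatography input (carries a line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Chromatogram:
    """A single-wavelength detector trace on a strictly increasing time grid.

    Parameters
    ----------
    times : array-like of float
        Acquisition times in minutes, strictly increasing, length >= 8.
    intensities : array-like of float
        Detector response in mAU, same length as `times`.
    wavelength : float
        Detection wavelength in nm (e.g. 205, 240, 280).
    meta : dict
        Free-form acquisition metadata (column, flow rate, temperature, ...).
    """

    times: np.ndarray
    intensities: np.ndarray
    wavelength: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("times and intensities must be 1-D")
        if len(self.times) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.times) < 8:
            raise ValueError(
                f"chromatogram needs at least 8 samples, got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0 nm, got {self.wavelength}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        """Median grid spacing in minutes."""
        return float(np.median(np.diff(self.times)))


@dataclass
class Peak:
    """A detected chromatographic peak (heights/areas are baseline-corrected)."""

    apex_time: float
    start_time: float
    end_time: float
    height: float
    area: float
    width_half: float
    analyte: str | None = None

    def __post_init__(self) -> None:
        if not self.start_time < self.apex_time < self.end_time:
            raise ValueError(
                f"require start < apex < end, got "
                f"{self.start_time}, {self.apex_time}, {self.end_time}"
            )
        if self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if not self.width_half > 0:
            raise ValueError(f"width_half must be > 0, got {self.width_half}")

    @property
    def base_width(self) -> float:
        """Baseline width (end - start) in minutes."""
        return self.end_time - self.start_time


@dataclass
class CalibrationCurve:
    """Linear response y = a*x + b for one analyte at one wavelength.

    `slope_a` is in area units per (ug/mL); `range_low`/`range_high` bound
    the concentrations the line was fitted over.
    """

    analyte: str
    wavelength: float
    slope_a: float
    intercept_b: float
    r_squared: float
    range_low: float
    range_high: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.slope_a > 0:
            raise ValueError(
                f"{self.analyte}: slope must be > 0, got {self.slope_a}"
            )
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(
                f"{self.analyte}: r_squared must be in [0, 1], got {self.r_squared}"
            )
        if not self.range_low < self.range_high:
            raise ValueError(
                f"{self.analyte}: require range_low < range_high, got "
                f"[{self.range_low}, {self.range_high}]"
            )

    def predict_area(self, concentration: float) -> float:
        """Forward evaluation a*x + b."""
        return self.slope_a * concentration + self.intercept_b


@dataclass
class PanelEntry:
    """One analyte of the panel: detection channel, expected relative
    retention time versus the reference, and stock concentration."""

    name: str
    detection_wavelength: float
    expected_rtt: float
    stock_concentration: float

    def __post_init__(self) -> None:
        if not self.detection_wavelength > 0:
            raise ValueError(f"{self.name}: wavelength must be > 0")
        if not self.expected_rtt > 0:
            raise ValueError(f"{self.name}: expected_rtt must be > 0")
        if not self.stock_concentration > 0:
            raise ValueError(
                f"{self.name}: stock concentration must be > 0, "
                f"got {self.stock_concentration}"
            )


@dataclass
class AnalytePanel:
    """The analyte panel: entries plus the internal-reference analyte.

    The reference is the single marker whose standard is actually run; its
    expected relative retention time is 1 by definition.
    """

    analytes: list[PanelEntry]
    reference_analyte: str

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in panel")
        if self.reference_analyte not in names:
            raise ValueError(
                f"reference analyte {self.reference_analyte!r} not in panel"
            )
        ref = self[self.reference_analyte]
        if ref.expected_rtt != 1.0:
            raise ValueError("reference analyte must have expected_rtt = 1")

    def __getitem__(self, name: str) -> PanelEntry:
        for entry in self.analytes:
            if entry.name == name:
                return entry
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @property
    def wavelengths(self) -> list[float]:
        """Distinct detection channels used by the panel, ascending."""
        return sorted({a.detection_wavelength for a in self.analytes})


@dataclass
class SamplePrep:
    """Sample mass (g) extracted into a final volume (mL); converts extract
    concentration to dry-material mass fraction."""

    sample_mass: float
    extract_volume: float

    def __post_init__(self) -> None:
        if not self.sample_mass > 0:
            raise ValueError(f"sample_mass must be > 0 g, got {self.sample_mass}")
        if not self.extract_volume > 0:
            raise ValueError(
                f"extract_volume must be > 0 mL, got {self.extract_volume}"
            )


# ---------------------------------------------------------------------------
# delimited-text helpers
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    """Shortest decimal rendering that round-trips the double exactly."""
    return repr(float(x))


def _as_text_stream(source: str | IO[str], mode: str = "r"):
    """Return (stream, should_close) for a path or an open text stream."""
    if isinstance(source, (str,)):
        return open(source, mode), True
    return source, False


def _split_meta(lines: list[str]) -> tuple[dict, int]:
    """Parse the leading '# key: value' block; returns (meta, first_data_idx)."""
    meta: dict = {}
    idx = 0
    for idx, line in enumerate(lines):
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        body = stripped.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    else:
        idx = len(lines)
    return meta, idx


def _parse_float(token: str, lineno: int, colname: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ChromatogramParseError(
            f"line {lineno}: cannot parse {colname} value {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# chromatogram I/O
# ---------------------------------------------------------------------------


def read_chromatogram(
    source: str | IO[str], wavelength: float | None = None
) -> Chromatogram:
    """Read a chromatogram from delimited text.

    Accepts the package's canonical narrow form (``time_min,intensity_mAU``
    with the wavelength in the ``#`` metadata block) and, on read only, a
    wide multi-channel form whose intensity columns are named by wavelength
    (``time_min,205,240,280`` or ``intensity_205,...``); `wavelength` then
    selects the channel.

    Raises
    ------
    ChromatogramParseError
        On malformed rows (with the offending line number) or when fewer
        than 8 data rows are present.
    """
    stream, should_close = _as_text_stream(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()

    meta, start = _split_meta(lines)
    data_lines = [
        (i + 1, ln) for i, ln in enumerate(lines) if i >= start and ln.strip()
    ]
    if not data_lines:
        raise ChromatogramParseError("empty chromatogram file")

    header_lineno, header = data_lines[0]
    columns = [c.strip() for c in header.split(",")]
    if columns[0] != "time_min":
        raise ChromatogramParseError(
            f"line {header_lineno}: first column must be 'time_min', "
            f"got {columns[0]!r}"
        )

    meta_wl = meta.pop("wavelength_nm", None)
    if len(columns) == 2:
        col_idx = 1
        if wavelength is None:
            if meta_wl is None:
                raise ChromatogramParseError(
                    "no wavelength given and none recorded in metadata"
                )
            wavelength = float(meta_wl)
    else:
        if wavelength is None:
            raise ChromatogramParseError(
                "wide multi-channel file: a wavelength must be requested"
            )
        wanted = None
        for i, name in enumerate(columns[1:], start=1):
            token = name.removeprefix("intensity_").removesuffix("nm").strip("_ ")
            try:
                if float(token) == float(wavelength):
                    wanted = i
                    break
            except ValueError:
                continue
        if wanted is None:
            raise ChromatogramParseError(
                f"no channel for {wavelength} nm among columns {columns[1:]}"
            )
        col_idx = wanted

    times: list[float] = []
    values: list[float] = []
    for lineno, line in data_lines[1:]:
        tokens = [t.strip() for t in line.split(",")]
        if len(tokens) != len(columns):
            raise ChromatogramParseError(
                f"line {lineno}: expected {len(columns)} fields, got {len(tokens)}"
            )
        times.append(_parse_float(tokens[0], lineno, "time_min"))
        values.append(_parse_float(tokens[col_idx], lineno, columns[col_idx]))

    if len(times) < 8:
        raise ChromatogramParseError(
            f"insufficient data: {len(times)} rows (need >= 8)"
        )
    t = np.asarray(times)
    if not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise ChromatogramParseError(
            f"time not strictly increasing at data row {bad + 2}"
        )
    return Chromatogram(t, np.asarray(values), float(wavelength), meta)


def write_chromatogram(chrom: Chromatogram, sink: str | IO[str]) -> None:
    """Write a chromatogram in the canonical narrow CSV form.

    Floats are rendered with 17 significant digits; `read_chromatogram`
    inverts this bit-for-bit.
    """
    stream, should_close = _as_text_stream(sink, "w")
    try:
        stream.write(f"# wavelength_nm: {_fmt_float(chrom.wavelength)}\n")
        for key, value in chrom.meta.items():
            stream.write(f"# {key}: {value}\n")
        stream.write("time_min,intensity_mAU\n")
        for t, y in zip(chrom.times, chrom.intensities):
            stream.write(f"{_fmt_float(t)},{_fmt_float(y)}\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# calibration-table I/O
# ---------------------------------------------------------------------------

_CAL_COLUMNS = [
    "analyte",
    "wavelength",
    "slope",
    "intercept",
    "r_squared",
    "range_low",
    "range_high",
]


def read_calibration_table(source: str | IO[str]) -> list[CalibrationCurve]:
    """Read per-analyte linear calibrations from CSV.

    Columns: analyte, wavelength, slope, intercept, r_squared, range_low,
    range_high (optional trailing n_points). Duplicate (analyte, wavelength)
    pairs and non-positive slopes are rejected.
    """
    stream, should_close = _as_text_stream(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()
    _, start = _split_meta(lines)
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if i >= start and ln.strip()]
    if not rows:
        return []
    header = [c.strip() for c in rows[0][1].split(",")]
    missing = [c for c in _CAL_COLUMNS if c not in header]
    if missing:
        raise ChromatogramParseError(f"calibration table missing columns {missing}")
    pos = {c: header.index(c) for c in header}

    curves: list[CalibrationCurve] = []
    seen: set[tuple[str, float]] = set()
    for lineno, line in rows[1:]:
        tok = [t.strip() for t in line.split(",")]
        if len(tok) != len(header):
            raise ChromatogramParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(tok)}"
            )
        analyte = tok[pos["analyte"]]
        wl = _parse_float(tok[pos["wavelength"]], lineno, "wavelength")
        key = (analyte, wl)
        if key in seen:
            raise ChromatogramParseError(
                f"line {lineno}: duplicate calibration for {analyte} at {wl} nm"
            )
        seen.add(key)
        curves.append(
            CalibrationCurve(
                analyte=analyte,
                wavelength=wl,
                slope_a=_parse_float(tok[pos["slope"]], lineno, "slope"),
                intercept_b=_parse_float(tok[pos["intercept"]], lineno, "intercept"),
                r_squared=_parse_float(tok[pos["r_squared"]], lineno, "r_squared"),
                range_low=_parse_float(tok[pos["range_low"]], lineno, "range_low"),
                range_high=_parse_float(tok[pos["range_high"]], lineno, "range_high"),
                n_points=int(tok[pos["n_points"]]) if "n_points" in pos else 0,
            )
        )
    return curves


def write_calibration_table(
    curves: Iterable[CalibrationCurve], sink: str | IO[str]
) -> None:
    stream, should_close = _as_text_stream(sink, "w")
    try:
        stream.write(",".join(_CAL_COLUMNS + ["n_points"]) + "\n")
        for c in curves:
            fields = [
                c.analyte,
                _fmt_float(c.wavelength),
                _fmt_float(c.slope_a),
                _fmt_float(c.intercept_b),
                _fmt_float(c.r_squared),
                _fmt_float(c.range_low),
                _fmt_float(c.range_high),
                str(c.n_points),
            ]
            stream.write(",".join(fields) + "\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# peak-table I/O
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["analyte", "apex_time", "start", "end", "height", "area", "width_half"]


def write_peak_table(peaks: Iterable[Peak], sink: str | IO[str]) -> None:
    stream, should_close = _as_text_stream(sink, "w")
    try:
        stream.write(",".join(_PEAK_COLUMNS) + "\n")
        for p in peaks:
            stream.write(
                ",".join(
                    [p.analyte or ""]
                    + [
                        _fmt_float(v)
                        for v in (
                            p.apex_time,
                            p.start_time,
                            p.end_time,
                            p.height,
                            p.area,
                            p.width_half,
                        )
                    ]
                )
                + "\n"
            )
    finally:
        if should_close:
            stream.close()


def read_peak_table(source: str | IO[str]) -> list[Peak]:
    stream, should_close = _as_text_stream(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()
    _, start = _split_meta(lines)
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if i >= start and ln.strip()]
    if not rows:
        return []
    header = [c.strip() for c in rows[0][1].split(",")]
    if header != _PEAK_COLUMNS:
        raise ChromatogramParseError(
            f"peak table header must be {_PEAK_COLUMNS}, got {header}"
        )
    peaks = []
    for lineno, line in rows[1:]:
        tok = [t.strip() for t in line.split(",")]
        if len(tok) != len(header):
            raise ChromatogramParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(tok)}"
            )
        nums = [_parse_float(t, lineno, c) for t, c in zip(tok[1:], header[1:])]
        peaks.append(
            Peak(
                analyte=tok[0] or None,
                apex_time=nums[0],
                start_time=nums[1],
                end_time=nums[2],
                height=nums[3],
                area=nums[4],
                width_half=nums[5],
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# panel configuration
# ---------------------------------------------------------------------------


def load_panel(config: str | IO[str] | Mapping) -> AnalytePanel:
    """Build an :class:`AnalytePanel` from a YAML/JSON-style mapping.

    Expected structure::

        reference: cholesterol
        analytes:
          cholesterol:
            wavelength: 205
            expected_rtt: 1.0
            stock_concentration: 4000.0
          ...

    The reference's expected_rtt is forced to exactly 1.0.
    """
    if isinstance(config, Mapping):
        doc = dict(config)
    else:
        stream, should_close = _as_text_stream(config)
        try:
            doc = yaml.safe_load(stream.read())
        finally:
            if should_close:
                stream.close()
    if not isinstance(doc, Mapping):
        raise ValueError("panel config must be a mapping")
    if "reference" not in doc:
        raise ValueError("panel config missing 'reference'")
    if "analytes" not in doc or not doc["analytes"]:
        raise ValueError("panel config missing 'analytes'")
    reference = str(doc["reference"])
    if reference not in doc["analytes"]:
        raise ValueError(f"reference {reference!r} not among configured analytes")

    entries = []
    for name, spec in doc["analytes"].items():
        rtt = 1.0 if name == reference else float(spec["expected_rtt"])
        entries.append(
            PanelEntry(
                name=str(name),
                detection_wavelength=float(spec["wavelength"]),
                expected_rtt=rtt,
                stock_concentration=float(spec["stock_concentration"]),
            )
        )
    return AnalytePanel(analytes=entries, reference_analyte=reference)


def panel_to_dict(panel: AnalytePanel) -> dict:
    """Inverse of :func:`load_panel` (load_panel(panel_to_dict(p)) == p)."""
    return {
        "reference": panel.reference_analyte,
        "analytes": {
            a.name: {
                "wavelength": a.detection_wavelength,
                "expected_rtt": a.expected_rtt,
                "stock_concentration": a.stock_concentration,
            }
            for a in panel.analytes
        },
    }
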