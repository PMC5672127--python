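"""Method-validation statistics: RSD-based precision/stability/repeatability,
spike recovery, cross-condition durability and reproducibility of relative
correction factors.

Everything reduces to the relative standard deviation
RSD% = 100 * s / mean with the sample (n-1) standard deviation — the
convention for small analytical replicate sets.  Pass thresholds default to
the bounds routinely quoted for this assay family (2.0% stability, 3.1%
durability, 1.19% within-lab / 2.0% cross-lab factor reproducibility) but
are plain arguments: they are observations about a validated method, not
specifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReplicateSet",
    "RecoveryDesign",
    "ConditionReport",
    "rsd",
    "recovery_rate",
    "stability_report",
    "rcf_reproducibility",
    "durability_report",
]


@dataclass
class ReplicateSet:
    """Repeated measurements of one quantity (areas, contents or factors)."""

    label: str
    values: list[float]
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(f"{self.label}: need >= 2 replicates")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.label}: non-finite replicate value")


@dataclass
class RecoveryDesign:
    """A spike-recovery experiment: known base content, known spike, measured
    total.  The standard design spikes 1:1 against the native content."""

    base_amount: float
    added_amount: float
    measured_spiked: float

    def __post_init__(self) -> None:
        if self.base_amount < 0 or self.measured_spiked < 0:
            raise ValueError("amounts must be >= 0")
        if not self.added_amount > 0:
            raise ValueError("added_amount must be > 0")


@dataclass
class ConditionReport:
    """RSD of one labelled series plus its pass/fail against a threshold."""

    label: str
    rsd_percent: float
    threshold: float
    passed: bool


def rsd(values: ReplicateSet | Sequence[float]) -> float:
    """Relative standard deviation, percent: 100 * sd(n-1) / mean."""
    v = np.asarray(values.values if isinstance(values, ReplicateSet) else values,
                   dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values for an RSD")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("zero mean: RSD undefined")
    return float(100.0 * v.std(ddof=1) / mean)


def recovery_rate(design: RecoveryDesign) -> float:
    """Spike recovery, percent: 100 * (measured - base) / added."""
    return 100.0 * (design.measured_spiked - design.base_amount) / design.added_amount


def stability_report(
    timepoint_areas: Mapping[str, Sequence[tuple[float, float]]],
    threshold: float = 2.0,
) -> dict[str, ConditionReport]:
    """Solution stability: per-analyte RSD of peak area over storage time.

    `timepoint_areas` maps analyte -> [(hours, area), ...] (>= 3 timepoints);
    the standard schedule is 0, 2, 4, 6, 8, 10, 12 and 24 h. Pass means
    RSD <= `threshold` percent.
    """
    out = {}
    for analyte, series in timepoint_areas.items():
        if len(series) < 3:
            raise ValueError(f"{analyte}: need >= 3 timepoints")
        areas = [a for _, a in series]
        r = rsd(ReplicateSet(label=analyte, values=list(areas), unit="mAU*min"))
        out[analyte] = ConditionReport(analyte, r, threshold, r <= threshold)
    return out


def rcf_reproducibility(
    rcf_by_condition: Mapping[str, Sequence[float]],
    within_threshold: float = 1.19,
    pooled_threshold: float = 2.0,
) -> tuple[dict[str, ConditionReport], ConditionReport]:
    """Reproducibility of relative correction factors across conditions.

    Each condition (instrument, column, temperature, flow, laboratory)
    contributes >= 2 factor values.  Returns per-condition RSDs checked
    against `within_threshold` and the pooled RSD over all values checked
    against `pooled_threshold` (both percent).
    """
    per: dict[str, ConditionReport] = {}
    pooled: list[float] = []
    for cond, values in rcf_by_condition.items():
        if len(values) < 2:
            raise ValueError(f"{cond}: need >= 2 factor values")
        r = rsd(ReplicateSet(label=str(cond), values=list(values)))
        per[cond] = ConditionReport(str(cond), r, within_threshold,
                                    r <= within_threshold)
        pooled.extend(values)
    overall = rsd(ReplicateSet(label="pooled", values=pooled))
    return per, ConditionReport("pooled", overall, pooled_threshold,
                                overall <= pooled_threshold)


def durability_report(
    mass_fractions_by_condition: Mapping[object, Mapping[str, float]],
    threshold: float = 3.1,
) -> dict[str, ConditionReport]:
    """Robustness: per-analyte RSD of mass fractions across instrument/
    column/flow/temperature conditions (>= 2 conditions).

    All conditions must report the same analyte set.
    """
    conditions = list(mass_fractions_by_condition.values())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    analytes = set(conditions[0])
    for cond_key, values in mass_fractions_by_condition.items():
        if set(values) != analytes:
            raise ValueError(
                f"condition {cond_key!r}: analyte set differs "
                f"({sorted(set(values) ^ analytes)})"
            )
    out = {}
    for analyte in sorted(analytes):
        series = [values[analyte] for values in conditions]
        r = rsd(ReplicateSet(label=analyte, values=series, unit="ug/g"))
        out[analyte] = ConditionReport(analyte, r, threshold, r <= threshold)
    return out
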