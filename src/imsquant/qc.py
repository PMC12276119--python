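"""Precision analysis and Shewhart-style property control charts.

Repeatability (within-day replicates) and intermediate precision
(across-day series) are summarised as relative standard deviations per
compound and per monitored quantity (signal intensity, retention time,
drift time).  Long-term series are visualised on property control charts
whose centre line is the series mean and whose warning/control limits sit
at +/-2 and +/-3 sample standard deviations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrecisionDesign",
    "PrecisionSeries",
    "ControlChartLimits",
    "PointFlag",
    "rsd_percent",
    "control_chart",
    "classify_points",
    "precision_report",
    "plot_control_chart",
]


class PrecisionDesign(str, enum.Enum):
    REPEATABILITY = "repeatability"
    INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class PrecisionSeries:
    """Replicate measurements of one quantity for one compound."""

    label: str  # compound name
    quantity: str  # e.g. "intensity_au", "retention_s", "drift_rel"
    design: PrecisionDesign
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a precision series needs at least 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class ControlChartLimits:
    """Centre line with 2-sigma warning and 3-sigma control limits."""

    CL: float
    SD: float
    UWL: float
    LWL: float
    UCL: float
    LCL: float

    @classmethod
    def from_stats(cls, cl: float, sd: float) -> "ControlChartLimits":
        """Limits from a known centre line and standard deviation."""
        if sd < 0:
            raise ValueError("SD must be non-negative")
        return cls(
            CL=cl,
            SD=sd,
            UWL=cl + 2 * sd,
            LWL=cl - 2 * sd,
            UCL=cl + 3 * sd,
            LCL=cl - 3 * sd,
        )


class PointFlag(str, enum.Enum):
    IN_CONTROL = "in_control"
    BEYOND_WARNING = "beyond_warning"
    BEYOND_CONTROL = "beyond_control"


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def control_chart(values: Sequence[float]) -> ControlChartLimits:
    """Control-chart limits: CL = mean, warning at +/-2 SD, control at +/-3 SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("control chart requires at least 2 values")
    cl = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ControlChartLimits(
        CL=cl,
        SD=sd,
        UWL=cl + 2 * sd,
        LWL=cl - 2 * sd,
        UCL=cl + 3 * sd,
        LCL=cl - 3 * sd,
    )


def classify_points(
    values: Sequence[float], limits: ControlChartLimits
) -> list[PointFlag]:
    """Flag each point against the chart limits (strict, two-sided).

    A point strictly beyond a 3-sigma control limit is ``beyond_control``;
    strictly beyond a 2-sigma warning limit, ``beyond_warning``; otherwise
    ``in_control``.  No run rules are applied.
    """
    flags = []
    for v in values:
        if v > limits.UCL or v < limits.LCL:
            flags.append(PointFlag.BEYOND_CONTROL)
        elif v > limits.UWL or v < limits.LWL:
            flags.append(PointFlag.BEYOND_WARNING)
        else:
            flags.append(PointFlag.IN_CONTROL)
    return flags


def precision_report(series: Sequence[PrecisionSeries]) -> pd.DataFrame:
    """Per compound x quantity x design: n, mean, sd and RSD%.

    The long-format table mirrors the usual precision-study layout, one row
    per (compound, quantity, design).
    """
    if not series:
        raise ValueError("precision_report needs at least one series")
    rows = []
    for s in series:
        arr = np.asarray(s.values, dtype=float)
        rows.append(
            {
                "compound": s.label,
                "quantity": s.quantity,
                "design": s.design.value,
                "n": arr.size,
                "mean": arr.mean(),
                "sd": arr.std(ddof=1),
                "rsd_pct": rsd_percent(arr),
            }
        )
    return pd.DataFrame(rows)


def plot_control_chart(values, limits: ControlChartLimits, ax=None, title: str = ""):
    """Plot a property control chart (points, CL, warning and control lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(1, len(values) + 1)
    ax.plot(x, values, "o-", ms=3, lw=0.8, color="tab:blue")
    ax.axhline(limits.CL, color="orange", ls="--", label="CL")
    for y, c in ((limits.UWL, "gold"), (limits.LWL, "gold"), (limits.UCL, "red"), (limits.LCL, "red")):
        ax.axhline(y, color=c, lw=1)
    ax.set_xlabel("measurement")
    ax.set_title(title)
    return ax
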