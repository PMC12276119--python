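"""Peak-height, noise and blank-statistics extraction.

Quantities follow the window-maximum convention used in drift-tube IMS
software: a peak's height is the largest intensity inside a user-defined
retention x drift window, measured relative to a local baseline.  The
baseline is taken as the median of the window's border cells (for a 1D MS
trace: the median of the first and last 5% of in-window points), which is
robust to the peak itself as long as the window brackets it.

Noise is quantified as gamma, the same window-maximum statistic evaluated
on a blank at the analyte's expected position — i.e. half the peak-to-peak
baseline fluctuation in the one-sided reading used by the EP-17 convention,
under which S/N = 2*H/gamma and a peak is detectable at S/N = 3.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import IMSChromatogram, MSTrace

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "PeakWindow",
    "PeakMeasurement",
    "NoiseEstimate",
    "BlankStats",
    "AggregationMode",
    "peak_height",
    "noise_gamma",
    "sn_ratio",
    "aggregate_species",
    "blank_statistics",
]


class Species(str, enum.Enum):
    MONOMER = "monomer"
    DIMER = "dimer"
    RIP = "RIP"


class AggregationMode(str, enum.Enum):
    MONOMER_ONLY = "monomer_only"
    MONOMER_PLUS_DIMER = "monomer_plus_dimer"


@dataclass(frozen=True)
class PeakWindow:
    """Rectangular search window for one compound/species.

    ``rt_range`` is in seconds for IMS chromatograms and minutes for MS
    traces; ``dt_range`` (RIP-relative drift time) is ``None`` for MS.
    A RIP window must bracket drift 1.0.
    """

    compound: str
    species: Species
    rt_range: tuple[float, float]
    dt_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rt_range[0] >= self.rt_range[1]:
            raise ValueError("rt_range must satisfy lo < hi")
        if self.dt_range is not None and self.dt_range[0] >= self.dt_range[1]:
            raise ValueError("dt_range must satisfy lo < hi")
        if self.species == Species.RIP and self.dt_range is not None:
            if not (self.dt_range[0] < 1.0 < self.dt_range[1]):
                raise ValueError("RIP window must bracket drift 1.0")


@dataclass(frozen=True)
class PeakMeasurement:
    window: PeakWindow
    height: float  # a.u., baseline-subtracted
    rt_at_max: float
    dt_at_max: float | None
    baseline_used: float


@dataclass(frozen=True)
class NoiseEstimate:
    window: PeakWindow
    gamma: float  # a.u.


@dataclass(frozen=True)
class BlankStats:
    """Blank aggregate-height statistics (sample sd, n-1 denominator)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("blank statistics require n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _window_slice(axis: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(axis, lo, side="left"))
    i1 = int(np.searchsorted(axis, hi, side="right"))
    if i1 <= i0:
        raise ValueError(f"window [{lo}, {hi}] selects no grid points")
    return slice(int(i0), int(i1))


def _border_median(block: np.ndarray) -> float:
    if block.shape[0] <= 2 or block.shape[1] <= 2:
        return float(np.median(block))
    mask = np.zeros(block.shape, dtype=bool)
    mask[0, :] = mask[-1, :] = True
    mask[:, 0] = mask[:, -1] = True
    return float(np.median(block[mask]))


def peak_height(
    chrom: IMSChromatogram | MSTrace, window: PeakWindow
) -> PeakMeasurement:
    """Window-maximum peak height relative to the local baseline.

    Ties at the maximum break towards the smallest retention time, then the
    smallest drift time, so extraction is deterministic.  The height is
    never negative: the maximum dominates the border median by construction.
    """
    lo, hi = window.rt_range
    if isinstance(chrom, IMSChromatogram):
        if window.dt_range is None:
            raise ValueError("IMS windows need a dt_range")
        if lo < chrom.retention_axis[0] or hi > chrom.retention_axis[-1]:
            raise ValueError("retention window outside chromatogram axes")
        if window.dt_range[0] < chrom.drift_axis[0] or window.dt_range[1] > chrom.drift_axis[-1]:
            raise ValueError("drift window outside chromatogram axes")
        rs = _window_slice(chrom.retention_axis, lo, hi)
        ds = _window_slice(chrom.drift_axis, *window.dt_range)
        block = chrom.intensity[rs, ds]
        baseline = _border_median(block)
        # C-order argmax = first occurrence = smallest rt, then smallest dt
        i, j = np.unravel_index(int(np.argmax(block)), block.shape)
        return PeakMeasurement(
            window=window,
            height=float(block[i, j] - baseline),
            rt_at_max=float(chrom.retention_axis[rs][i]),
            dt_at_max=float(chrom.drift_axis[ds][j]),
            baseline_used=baseline,
        )

    if lo < chrom.retention_axis[0] or hi > chrom.retention_axis[-1]:
        raise ValueError("retention window outside trace axis")
    rs = _window_slice(chrom.retention_axis, lo, hi)
    seg = chrom.intensity[rs]
    edge = max(1, math.ceil(0.05 * seg.size))
    baseline = float(np.median(np.concatenate([seg[:edge], seg[-edge:]])))
    i = int(np.argmax(seg))
    return PeakMeasurement(
        window=window,
        height=float(max(seg[i] - baseline, 0.0)),
        rt_at_max=float(chrom.retention_axis[rs][i]),
        dt_at_max=None,
        baseline_used=baseline,
    )


def noise_gamma(
    blank: IMSChromatogram | MSTrace, window: PeakWindow
) -> NoiseEstimate:
    """Baseline-fluctuation amplitude gamma in a blank at the analyte window.

    Operationally identical to :func:`peak_height` applied to a blank: the
    largest baseline excursion above the local baseline within the window
    where the analyte would appear.
    """
    measurement = peak_height(blank, window)
    return NoiseEstimate(window=window, gamma=measurement.height)


def sn_ratio(height: float, gamma: float) -> float:
    """EP-17 signal-to-noise ratio, S/N = 2*H/gamma.

    gamma is half the peak-to-peak noise band, so the factor 2 reads the
    noise one-sidedly, matching how positive peaks are judged against the
    baseline.  A peak at the detection threshold (H = 1.5*gamma) scores 3.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 2.0 * height / gamma


def aggregate_species(
    measurements: Sequence[PeakMeasurement],
    mode: AggregationMode | str = AggregationMode.MONOMER_ONLY,
) -> float:
    """Combine a compound's species heights into one calibration response.

    ``monomer_only`` returns the monomer height; ``monomer_plus_dimer``
    returns the monomer+dimer sum, the mode required when blanks already
    show dimer signal at the analyte position.  A missing dimer in sum mode
    counts as zero (low concentrations legitimately lack dimers) and is
    logged rather than raised.
    """
    mode = AggregationMode(mode)
    monomer = next(
        (m for m in measurements if m.window.species == Species.MONOMER), None
    )
    if monomer is None:
        raise ValueError("a monomer measurement is required")
    if mode == AggregationMode.MONOMER_ONLY:
        return monomer.height
    dimer = next((m for m in measurements if m.window.species == Species.DIMER), None)
    if dimer is None:
        logger.warning(
            "%s: no dimer measurement in sum mode; counting dimer as 0",
            monomer.window.compound,
        )
        return monomer.height
    return monomer.height + dimer.height


def blank_statistics(
    blanks: Sequence[IMSChromatogram | MSTrace],
    windows: Sequence[PeakWindow],
    mode: AggregationMode | str = AggregationMode.MONOMER_ONLY,
) -> BlankStats:
    """Mean and sample standard deviation of blank aggregate heights.

    ``windows`` lists the monomer (and, in sum mode, dimer) windows of one
    compound; each blank contributes one aggregated height.
    """
    if len(blanks) < 2:
        raise ValueError("blank statistics require at least 2 blanks")
    heights = [
        aggregate_species([peak_height(b, w) for w in windows], mode) for b in blanks
    ]
    arr = np.asarray(heights)
    return BlankStats(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
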