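"""Calibration fitting for IMS and MS responses.

Three calibration modes are supported:

``monomer``
    Monomer peak height vs amount — the default when blanks are clean.
``sum``
    Monomer+dimer summed height vs amount — required when blanks already
    carry dimer signal at the analyte position.
``cip``
    The reactant-ion normalization: CIP = AIP / (RIP - AIP), where AIP is
    the analyte ion peak (per the chosen aggregation) and RIP the reactant
    ion peak measured at the analyte's retention time.  Because analyte
    ions are created at the expense of reactant ions, RIP - AIP equals the
    surviving reactant intensity, and under the mass-action response the
    transform is exactly linear in amount when dimerization is negligible
    (CIP = alpha*c for beta = 0) and nearly linear well beyond the raw
    signal's saturation knee otherwise.

All fits are unweighted ordinary least squares.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationMode",
    "CalibrationPoint",
    "CalibrationFit",
    "cip_transform",
    "fit_linear",
    "detect_linear_range",
    "inverse_predict",
]


class CalibrationMode(str, enum.Enum):
    MONOMER = "monomer"
    SUM = "sum"
    CIP = "cip"


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation.

    ``intensity`` is the analyte ion peak (AIP) in the chosen aggregation;
    ``rip`` is the reactant ion peak measured at the analyte's retention
    window and is required for CIP fitting; ``cip`` may be supplied
    pre-computed, otherwise it is derived from intensity and rip.
    """

    amount: float  # ng/tube
    intensity: float  # a.u.
    rip: float | None = None  # a.u.
    cip: float | None = None  # dimensionless

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be non-negative")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.cip is None and self.rip is not None and self.rip <= self.intensity:
            raise ValueError(
                "rip must exceed intensity to derive cip (saturation regime)"
            )


@dataclass(frozen=True)
class CalibrationFit:
    mode: CalibrationMode
    slope: float  # response units per ng/tube
    intercept: float
    r2: float
    range: tuple[float, float]  # ng/tube
    n_points: int

    def __post_init__(self) -> None:
        if self.range[0] >= self.range[1]:
            raise ValueError("calibration range must satisfy lo < hi")
        if self.n_points < 3:
            raise ValueError("a calibration needs at least 3 points")

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept


def cip_transform(aip: float, rip: float) -> float:
    """Calculated ion peak: AIP / (RIP - AIP).

    Valid only below saturation, where reactant ions survive (RIP > AIP);
    at or beyond RIP <= AIP the normalization diverges and the
    linearization no longer applies.
    """
    if aip < 0:
        raise ValueError("aip must be non-negative")
    if rip <= aip:
        raise ValueError("rip must exceed aip (saturation regime, cip undefined)")
    return aip / (rip - aip)


def _response(point: CalibrationPoint, mode: CalibrationMode) -> float:
    if mode == CalibrationMode.CIP:
        if point.cip is not None:
            return point.cip
        if point.rip is None:
            raise ValueError("cip mode requires rip (or precomputed cip) per point")
        return cip_transform(point.intensity, point.rip)
    return point.intensity


def fit_linear(
    points: Sequence[CalibrationPoint],
    mode: CalibrationMode | str = CalibrationMode.MONOMER,
) -> CalibrationFit:
    """Ordinary least squares of the mode's response on amount."""
    mode = CalibrationMode(mode)
    if len(points) < 3:
        raise ValueError("at least 3 calibration points required")
    x = np.array([p.amount for p in points])
    if np.unique(x).size < 3:
        raise ValueError("at least 3 distinct amounts required")
    y = np.array([_response(p, mode) for p in points])
    res = stats.linregress(x, y)
    return CalibrationFit(
        mode=mode,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range=(float(x.min()), float(x.max())),
        n_points=len(points),
    )


def detect_linear_range(
    points: Sequence[CalibrationPoint],
    mode: CalibrationMode | str = CalibrationMode.MONOMER,
    r2_min: float = 0.99,
) -> tuple[float, float]:
    """Widest contiguous linear span starting at the lowest level.

    Points are grouped by amount (replicate means), and the fitted span is
    grown upward from the three lowest levels; the widest prefix whose OLS
    fit keeps R^2 >= ``r2_min`` is returned as (lo, hi) in ng/tube.  This
    mirrors how a linear working range is read off a saturating IMS
    calibration curve.
    """
    mode = CalibrationMode(mode)
    x = np.array([p.amount for p in points])
    y = np.array([_response(p, mode) for p in points])
    levels = np.unique(x)
    if levels.size < 4:
        raise ValueError("linear-range detection needs at least 4 levels")
    means = np.array([y[x == lv].mean() for lv in levels])

    best: tuple[float, float] | None = None
    for k in range(3, levels.size + 1):
        res = stats.linregress(levels[:k], means[:k])
        if res.rvalue**2 >= r2_min:
            best = (float(levels[0]), float(levels[k - 1]))
    if best is None:
        raise ValueError(
            f"no 3-level prefix reaches R^2 >= {r2_min}; no linear range found"
        )
    return best


def inverse_predict(fit: CalibrationFit, x: float) -> float:
    """Invert a calibration: response (a.u. or CIP units) -> ng/tube.

    Warns when the result falls outside the fitted amount range, since the
    calibration is only trusted within it.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    amount = (x - fit.intercept) / fit.slope
    if not (fit.range[0] <= amount <= fit.range[1]):
        warnings.warn(
            f"inverse prediction {amount:.4g} ng/tube lies outside the fitted "
            f"range {fit.range}",
            stacklevel=2,
        )
    return amount
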