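"""Limit of detection and quantification estimation.

Two estimators are provided, matching how they are used to compare an IMS
and an MS detector on the same thermal-desorption GC system:

*Blank-statistics method* (IUPAC-style, with a degrees-of-freedom-aware
factor).  From n replicate blanks with aggregate-height mean x_bar and
sample sd s::

    x_D = x_bar + k * s          k = t_{1-alpha, n-1} + t_{1-beta, n-1}
    x_Q = x_bar + 10 * s

The factor k controls both the false-positive rate alpha (deciding a blank
is a detection) and the false-negative rate beta (missing an analyte at the
detection limit); at alpha = beta = 0.05 and n = 12 (11 degrees of freedom)
the one-sided Student t quantile is 1.796 and k = 3.592.  As n grows, k
falls towards 2 * z_{1-alpha} = 3.29.  The classical k = 3 convention
corresponds to >= 99.86% one-sided normal confidence.

*S/N method* (EP-17 noise convention).  With gamma the blank's half
peak-to-peak noise amplitude in the analyte window::

    x_D = 1.5 * gamma      (S/N = 3)
    x_Q = 5   * gamma      (S/N = 10)

Both limits are expressed in detector intensity units (a.u.) and converted
to amounts (ng/tube) through a low-range calibration fit.  The classical
slope method LOD = k * SD / m is included for completeness; it ignores
blank contamination and is a poor fit for thermal-desorption systems whose
blanks are not signal-free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from scipy import stats

from .calibrate import CalibrationFit, inverse_predict
from .extract import BlankStats

__all__ = [
    "LimitMethod",
    "DetectionLimits",
    "detection_factor_k",
    "one_sided_confidence",
    "lod_presented",
    "loq_presented",
    "lod_loq_sn",
    "lod_slope",
    "limits_in_amount",
]


class LimitMethod(str, enum.Enum):
    PRESENTED = "presented"  # blank statistics + t-derived k
    SN = "sn"  # EP-17 signal-to-noise
    SLOPE = "slope"  # classical k*SD/m


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ under one method, in intensity units and in ng/tube."""

    method: LimitMethod
    k: float
    xD: float  # a.u.
    xQ: float  # a.u.
    cD: float  # ng/tube
    cQ: float  # ng/tube
    extrapolated: bool = False  # conversion left the calibration's fitted range
    clipped: bool = False  # negative amount clipped to zero


def detection_factor_k(n_blank: int, alpha: float = 0.05, beta: float = 0.05) -> float:
    """Degrees-of-freedom-aware detection factor k.

    k = t_{1-alpha, nu} + t_{1-beta, nu} with nu = n_blank - 1 (one-sided
    quantiles), so both error rates are controlled with the t distribution
    that the blank sd estimate actually follows.  For alpha = beta this is
    2 * t_{1-alpha, nu}; at n = 12, alpha = beta = 0.05 it equals 3.592.
    """
    if n_blank < 2:
        raise ValueError("k requires at least 2 blanks (1 degree of freedom)")
    if not (0 < alpha < 0.5) or not (0 < beta < 0.5):
        raise ValueError("alpha and beta must lie in (0, 0.5)")
    nu = n_blank - 1
    return float(stats.t.ppf(1 - alpha, nu) + stats.t.ppf(1 - beta, nu))


def one_sided_confidence(z: float) -> float:
    """One-sided normal confidence (%) at ``z`` standard deviations.

    At z = 3 this exceeds 99.86%, the rationale behind the classical k = 3
    detection convention.
    """
    return float(100.0 * stats.norm.cdf(z))


def lod_presented(blank: BlankStats, k: float) -> float:
    """Detection limit in intensity units: x_D = mean + k * sd."""
    if k <= 0:
        raise ValueError("k must be positive")
    return blank.mean + k * blank.sd


def loq_presented(blank: BlankStats) -> float:
    """Quantification limit in intensity units: x_Q = mean + 10 * sd."""
    return blank.mean + 10.0 * blank.sd


def lod_loq_sn(gamma: float) -> tuple[float, float]:
    """S/N-method limits (x_D, x_Q) = (1.5, 5) * gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.5 * gamma, 5.0 * gamma


def lod_slope(sd_blank: float, k: float, m: float) -> float:
    """Classical slope-method LOD in ng/tube: k * sd / m."""
    if m <= 0:
        raise ValueError("calibration slope must be positive")
    if sd_blank < 0:
        raise ValueError("sd must be non-negative")
    return k * sd_blank / m


def limits_in_amount(
    xD: float,
    xQ: float,
    fit: CalibrationFit,
    method: LimitMethod | str,
    k: float,
) -> DetectionLimits:
    """Convert intensity-unit limits to ng/tube via a calibration fit.

    Amounts are clipped at zero (a limit below the fit's intercept means
    the blank level sits under the calibration line) and flagged when the
    inversion extrapolates beyond the fitted range.
    """
    if fit.slope <= 0:
        raise ValueError("conversion requires a positive calibration slope")
    import warnings

    extrapolated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cD = inverse_predict(fit, xD)
        cQ = inverse_predict(fit, xQ)
        extrapolated = len(caught) > 0
    clipped = cD < 0 or cQ < 0
    return DetectionLimits(
        method=LimitMethod(method),
        k=k,
        xD=xD,
        xQ=xQ,
        cD=max(cD, 0.0),
        cQ=max(cQ, 0.0),
        extrapolated=extrapolated,
        clipped=clipped,
    )
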