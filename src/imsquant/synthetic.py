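"""Synthetic GC-IMS chromatograms and GC-MS TIC traces.

Drift-tube IMS with a radioactive APCI source does not respond linearly to
analyte amount: reactant ions (the RIP) protonate analyte molecules to form
monomers, which at higher concentration associate into proton-bound dimers,
while the reactant-ion reservoir is depleted.  This module renders that ion
chemistry onto 2D retention-time x drift-time grids, plus a linear GC-MS
total-ion-current channel, so that calibration, detection-limit and QC
analyses can be exercised end to end without instrument data.

The response model is a single-analyte two-step equilibrium (law of mass
action).  For an amount ``c`` loaded on the desorption tube::

    q      = 1 + alpha*c + alpha*beta*c**2
    M(c)   = alpha * c      * R0 / q      (protonated monomer)
    D(c)   = alpha * beta * c**2 * R0 / q (proton-bound dimer)
    R_free = R0 - M - D                   (= R0 / q, unconsumed reactant ions)

so that charge is conserved exactly: ``M + D + R_free == R0``.  The monomer
peaks at ``c* = 1/sqrt(alpha*beta)`` and then declines as dimers dominate;
the summed analyte signal saturates at ``R0``.  Oligomers beyond the dimer
are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ResponseModel",
    "CompoundSpec",
    "AxisSpec",
    "IMSChromatogram",
    "MSTrace",
    "IonSplit",
    "ionization_response",
    "render_chromatogram",
    "generate_blank",
    "generate_calibration_series",
    "generate_ms_trace",
    "default_detector",
    "default_contaminants",
    "example_compounds",
    "DEFAULT_AXES",
]


@dataclass(frozen=True)
class ResponseModel:
    """Parameters of the mass-action R-APCI response.

    Parameters
    ----------
    r0 : float
        Reactant-ion reservoir intensity (a.u.); the blank RIP height.
    alpha : float
        Monomer association strength (per ng/tube).
    beta : float
        Dimer association strength (per ng/tube).
    ceiling : float
        Detector saturation intensity (a.u.); rendered values are clipped here.
    baseline : float
        Additive baseline level (a.u.).
    noise_sd : float
        Standard deviation of the additive Gaussian baseline noise (a.u.).
    """

    r0: float = 6.0
    alpha: float = 1.0
    beta: float = 0.01
    ceiling: float = 15.0
    baseline: float = 0.10
    noise_sd: float = 0.015

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("reactant reservoir r0 must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("association strengths must be non-negative")
        if self.ceiling < self.r0:
            raise ValueError("saturation ceiling must be >= r0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CompoundSpec:
    """Position, width and response of one compound on the IMS plane.

    Drift positions are RIP-relative (dimensionless); the RIP sits at 1.0
    and dimers drift slower than monomers, hence ``dt_dimer > dt_monomer > 1``.
    """

    name: str
    rt_monomer: float  # retention time, s
    dt_monomer: float  # RIP-relative drift time
    dt_dimer: float
    rt_sigma: float = 6.0  # Gaussian width in retention, s
    dt_sigma: float = 0.012  # Gaussian width in drift, rel. units
    model: ResponseModel = field(default_factory=ResponseModel)

    def __post_init__(self) -> None:
        if not (self.dt_dimer > self.dt_monomer > 1.0):
            raise ValueError(
                f"{self.name}: require dt_dimer > dt_monomer > 1.0 "
                f"(got {self.dt_dimer}, {self.dt_monomer})"
            )
        if self.rt_sigma <= 0 or self.dt_sigma <= 0:
            raise ValueError(f"{self.name}: peak widths must be positive")


@dataclass(frozen=True)
class AxisSpec:
    """Grid on which chromatograms are rendered."""

    rt_start: float = 0.0
    rt_stop: float = 2400.0
    rt_step: float = 2.0
    dt_start: float = 0.9
    dt_stop: float = 2.2
    dt_step: float = 0.005

    def __post_init__(self) -> None:
        if self.rt_step <= 0 or self.dt_step <= 0:
            raise ValueError("axis steps must be positive")
        if self.rt_stop <= self.rt_start or self.dt_stop <= self.dt_start:
            raise ValueError("axis stop must exceed start")
        if self.dt_start > 1.0 or self.dt_stop < 1.0:
            raise ValueError("drift axis must bracket the RIP at 1.0")

    def retention(self) -> np.ndarray:
        n = int(round((self.rt_stop - self.rt_start) / self.rt_step)) + 1
        return self.rt_start + self.rt_step * np.arange(n)

    def drift(self) -> np.ndarray:
        n = int(round((self.dt_stop - self.dt_start) / self.dt_step)) + 1
        return self.dt_start + self.dt_step * np.arange(n)


DEFAULT_AXES = AxisSpec()


@dataclass
class IMSChromatogram:
    """A 2D GC-IMS measurement: intensity over retention x RIP-relative drift."""

    retention_axis: np.ndarray  # s, strictly increasing
    drift_axis: np.ndarray  # RIP-relative, strictly increasing
    intensity: np.ndarray  # (n_retention, n_drift), a.u.
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.retention_axis.size, self.drift_axis.size):
            raise ValueError("intensity shape must match axis lengths")
        if np.any(np.diff(self.retention_axis) <= 0) or np.any(
            np.diff(self.drift_axis) <= 0
        ):
            raise ValueError("axes must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class MSTrace:
    """A GC-MS total-ion-current trace over retention time in minutes."""

    retention_axis: np.ndarray  # min, strictly increasing
    intensity: np.ndarray  # a.u.
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.retention_axis.shape:
            raise ValueError("trace lengths must match")
        if np.any(np.diff(self.retention_axis) <= 0):
            raise ValueError("retention axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


class IonSplit(NamedTuple):
    monomer: float
    dimer: float
    reactant: float


def ionization_response(c: float, model: ResponseModel) -> IonSplit:
    """Partition the reactant-ion reservoir at analyte amount ``c`` (ng/tube).

    Returns the monomer, dimer and free-reactant intensities (a.u.).  The
    three components sum to ``model.r0`` exactly (``reactant`` is computed
    by subtraction, which coincides analytically with ``r0 / q``).
    """
    if c < 0:
        raise ValueError("amount must be non-negative")
    q = 1.0 + model.alpha * c + model.alpha * model.beta * c * c
    monomer = model.alpha * c * model.r0 / q
    dimer = model.alpha * model.beta * c * c * model.r0 / q
    return IonSplit(monomer, dimer, model.r0 - monomer - dimer)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def render_chromatogram(
    compounds: Sequence[CompoundSpec],
    amounts: Sequence[float],
    axes: AxisSpec = DEFAULT_AXES,
    seed: int | np.random.Generator = 0,
    detector: ResponseModel | None = None,
    rip_sigma: float = 0.010,
    label: str = "",
) -> IMSChromatogram:
    """Render compounds at the given amounts onto a 2D IMS grid.

    Each compound contributes a separable Gaussian monomer peak of height
    ``M(c)`` at (rt_monomer, dt_monomer) and a dimer peak of height ``D(c)``
    at (rt_monomer, dt_dimer).  The RIP ridge at drift 1.0 has height ``r0``
    away from analytes and is depleted towards ``R_free`` across each
    compound's retention window, weighted by the compound's retention
    profile, so every retention slice conserves charge.  Additive baseline
    and Gaussian noise are applied last; values are clipped to
    ``[0, ceiling]``.  Identical integer seeds give identical output.
    """
    if len(compounds) != len(amounts):
        raise ValueError("one amount per compound required")
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be non-negative")
    if detector is None:
        if compounds:
            detector = compounds[0].model
        else:
            detector = ResponseModel()
    for comp in compounds:
        m = comp.model
        if (m.r0, m.ceiling, m.baseline, m.noise_sd) != (
            detector.r0,
            detector.ceiling,
            detector.baseline,
            detector.noise_sd,
        ):
            raise ValueError(
                f"{comp.name}: compound model and detector disagree on "
                "reservoir/ceiling/baseline/noise"
            )

    rt = axes.retention()
    dt = axes.drift()
    for comp in compounds:
        if not (rt[0] <= comp.rt_monomer <= rt[-1]):
            raise ValueError(f"{comp.name}: retention position outside axes")
        if not (dt[0] <= comp.dt_monomer <= dt[-1] and dt[0] <= comp.dt_dimer <= dt[-1]):
            raise ValueError(f"{comp.name}: drift position outside axes")

    signal = np.zeros((rt.size, dt.size))
    rip_amplitude = np.full(rt.size, detector.r0)
    rip_profile = np.exp(-0.5 * ((dt - 1.0) / rip_sigma) ** 2)

    for comp, c in zip(compounds, amounts):
        mono, dim, _ = ionization_response(c, comp.model)
        g_rt = np.exp(-0.5 * ((rt - comp.rt_monomer) / comp.rt_sigma) ** 2)
        g_mono = np.exp(-0.5 * ((dt - comp.dt_monomer) / comp.dt_sigma) ** 2)
        g_dim = np.exp(-0.5 * ((dt - comp.dt_dimer) / comp.dt_sigma) ** 2)
        signal += np.outer(g_rt, mono * g_mono + dim * g_dim)
        # local RIP depletion: at the peak apex the ridge drops to R_free
        rip_amplitude -= (mono + dim) * g_rt

    signal += np.outer(np.clip(rip_amplitude, 0.0, None), rip_profile)
    signal += detector.baseline
    if detector.noise_sd > 0:
        rng = _as_rng(seed)
        signal += rng.normal(0.0, detector.noise_sd, size=signal.shape)
    intensity = np.clip(signal, 0.0, detector.ceiling)

    meta = {
        "label": label,
        "amounts_ng_per_tube": {c.name: float(a) for c, a in zip(compounds, amounts)},
        "seed": seed if isinstance(seed, int) else None,
    }
    return IMSChromatogram(rt, dt, intensity, meta)


def generate_blank(
    contaminants: Sequence[tuple[CompoundSpec, float, float]],
    n: int,
    seed: int,
    axes: AxisSpec = DEFAULT_AXES,
    detector: ResponseModel | None = None,
) -> list[IMSChromatogram]:
    """Simulate ``n`` replicate blank injections.

    ``contaminants`` lists (compound, mean ng/tube, sd ng/tube); each blank
    draws every contaminant amount from a normal distribution truncated at
    zero, emulating tube/trap background such as adsorbent degradation
    products.  At least two blanks are required, since blank statistics
    (mean, sd) are undefined for fewer.
    """
    if n < 2:
        raise ValueError("at least 2 blanks required for blank statistics")
    if detector is None and contaminants:
        detector = contaminants[0][0].model
    rng = np.random.default_rng(seed)
    blanks = []
    for i in range(n):
        amounts = []
        for comp, mean, sd in contaminants:
            if sd < 0 or mean < 0:
                raise ValueError(f"{comp.name}: contaminant mean/sd must be >= 0")
            if sd == 0:
                amounts.append(mean)
            else:
                a, b = (0.0 - mean) / sd, np.inf
                amounts.append(
                    float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
                )
        blanks.append(
            render_chromatogram(
                [c for c, _, _ in contaminants],
                amounts,
                axes=axes,
                seed=rng,
                detector=detector,
                label=f"blank_{i:02d}",
            )
        )
    return blanks


def generate_calibration_series(
    compound: CompoundSpec,
    levels: Sequence[float],
    replicates: int,
    seed: int,
    axes: AxisSpec = DEFAULT_AXES,
) -> list[IMSChromatogram]:
    """Render a calibration series: ``replicates`` injections per level.

    Levels must be non-empty, non-negative and sorted ascending (the usual
    low-to-high measurement order).  The true loaded amount is recorded in
    each chromatogram's metadata.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(lv < 0 for lv in levels):
        raise ValueError("levels must be non-negative")
    if sorted(levels) != levels:
        raise ValueError("levels must be sorted ascending")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    out = []
    for lv in levels:
        for rep in range(replicates):
            out.append(
                render_chromatogram(
                    [compound],
                    [lv],
                    axes=axes,
                    seed=rng,
                    label=f"{compound.name}_{lv:g}ng_r{rep}",
                )
            )
            out[-1].meta["amount_ng_per_tube"] = float(lv)
            out[-1].meta["replicate"] = rep
    return out


def generate_ms_trace(
    positions_min: Sequence[float],
    amounts: Sequence[float],
    ms_gain: float = 1.0,
    ms_noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
    rt_start: float = 0.0,
    rt_stop: float = 40.0,
    rt_step: float = 0.005,
    peak_sigma: float = 0.04,
    baseline: float = 1.0,
    ceiling: float = 1.0e6,
    label: str = "",
) -> MSTrace:
    """Render a GC-MS TIC trace with a linear detector response.

    Peak height is ``ms_gain * amount`` — linear over the whole working
    range (the MS channel stays linear for several decades, unlike IMS) —
    plus baseline and Gaussian noise, clipped to ``[0, ceiling]``.
    """
    if ms_gain < 0:
        raise ValueError("ms_gain must be non-negative")
    if len(positions_min) != len(amounts):
        raise ValueError("one amount per peak position required")
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be non-negative")
    n = int(round((rt_stop - rt_start) / rt_step)) + 1
    rt = rt_start + rt_step * np.arange(n)
    signal = np.full(n, float(baseline))
    for pos, amount in zip(positions_min, amounts):
        if not (rt[0] <= pos <= rt[-1]):
            raise ValueError(f"peak position {pos} min outside trace axis")
        signal += ms_gain * amount * np.exp(-0.5 * ((rt - pos) / peak_sigma) ** 2)
    if ms_noise_sd > 0:
        rng = _as_rng(seed)
        signal += rng.normal(0.0, ms_noise_sd, size=n)
    meta = {
        "label": label,
        "amounts_ng_per_tube": [float(a) for a in amounts],
        "seed": seed if isinstance(seed, int) else None,
    }
    return MSTrace(rt, np.clip(signal, 0.0, ceiling), meta)


def default_detector() -> ResponseModel:
    """The default IMS detector model used across the synthetic scenarios."""
    return ResponseModel()


def example_compounds() -> dict[str, CompoundSpec]:
    """Synthetic stand-ins for the reference VOCs.

    Retention times follow the chromatographic order of the real compounds;
    drift positions are literature-plausible RIP-relative values.  Response
    parameters encode each scenario's role: the ketones carry low-to-moderate
    dimerization, while the blank contaminants (nonanal, 2-butanone) are
    strong dimer formers so that blanks show both species.
    """
    low_dimer = ResponseModel(beta=0.01)
    moderate = ResponseModel(beta=0.05)
    strong = ResponseModel(beta=30.0)
    return {
        "2-butanone": CompoundSpec("2-butanone", 406.7, 1.100, 1.297, model=strong),
        "1-butanol": CompoundSpec("1-butanol", 612.0, 1.180, 1.380, model=moderate),
        "2-hexanone": CompoundSpec("2-hexanone", 980.0, 1.190, 1.470, model=low_dimer),
        "2-octanone": CompoundSpec("2-octanone", 1426.7, 1.330, 1.859, model=moderate),
        "nonanal": CompoundSpec("nonanal", 1580.0, 1.470, 1.940, model=strong),
    }


def default_contaminants() -> list[tuple[CompoundSpec, float, float]]:
    """Blank contamination: nonanal (adsorbent degradation) and 2-butanone
    (solvent impurity), at levels that produce both monomer and dimer peaks.

    The nonanal level targets a summed monomer+dimer blank height of roughly
    0.35 +/- 0.08 a.u. under the default detector.
    """
    comps = example_compounds()
    return [
        (comps["nonanal"], 0.030, 0.005),
        (comps["2-butanone"], 0.035, 0.007),
    ]
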