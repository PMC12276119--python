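"""End-to-end IMS-vs-MS quantification performance pipeline.

Stages: synthesize blanks and calibration series for both detectors;
extract peak heights, noise and RIP intensities; route each compound to
monomer-only or monomer+dimer calibration depending on whether blanks show
dimer signal at its position; fit calibrations (raw and CIP-linearized);
estimate LOD/LOQ by the blank-statistics and S/N methods; convert to
ng/tube through a low-range fit; and compare detectors (LOD ratios,
linear-range widths in decades) alongside a repeatability QC summary.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iomod
from .calibrate import (
    CalibrationFit,
    CalibrationMode,
    CalibrationPoint,
    detect_linear_range,
    fit_linear,
)
from .extract import (
    AggregationMode,
    BlankStats,
    PeakWindow,
    Species,
    aggregate_species,
    peak_height,
)
from .limits import (
    DetectionLimits,
    LimitMethod,
    detection_factor_k,
    limits_in_amount,
    lod_loq_sn,
    lod_presented,
    loq_presented,
)
from .qc import PrecisionDesign, PrecisionSeries, control_chart, precision_report
from .synthetic import (
    AxisSpec,
    CompoundSpec,
    ResponseModel,
    default_contaminants,
    example_compounds,
    generate_blank,
    generate_calibration_series,
    generate_ms_trace,
    render_chromatogram,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CompoundResult",
    "PipelineResult",
    "default_config",
    "config_from_dict",
    "load_config",
    "run_pipeline",
    "compare_detectors",
    "write_report",
]


@dataclass
class PipelineConfig:
    """Study design for the full comparison.

    Defaults emulate the measurement campaign the analysis expects: 12
    replicate blanks, triplicate calibration levels spanning four decades
    on the IMS side (0.01-100 ng/tube) and >3 decades on the MS side, a
    0.05 false-positive/false-negative budget for the detection factor,
    and a 16-replicate repeatability set at 10 ng/tube.
    """

    compounds: list[CompoundSpec] = field(
        default_factory=lambda: [
            example_compounds()["2-hexanone"],
            example_compounds()["nonanal"],
        ]
    )
    contaminants: list[tuple[CompoundSpec, float, float]] = field(
        default_factory=default_contaminants
    )
    ims_levels: list[float] = field(
        default_factory=lambda: [round(float(v), 4) for v in np.geomspace(0.01, 100, 18)]
    )
    ms_levels: list[float] = field(
        default_factory=lambda: [round(float(v), 4) for v in np.geomspace(0.5, 1000, 13)]
    )
    replicates: int = 3
    n_blanks: int = 12
    seed: int = 0
    alpha: float = 0.05  # false-positive budget for the detection factor
    beta: float = 0.05  # false-negative budget
    r2_min: float = 0.99  # linear-range acceptance
    cip_max_level: float = 8.0  # ng/tube; CIP fit restricted below saturation
    dimer_presence_factor: float = 2.0  # blank dimer vs reference noise routing
    axes: AxisSpec = field(default_factory=AxisSpec)
    ms_gain: float = 1.0  # a.u. per ng/tube
    ms_noise_sd: float = 0.3  # a.u.
    ms_peak_sigma: float = 0.04  # min
    qc_replicates: int = 16
    qc_amount: float = 10.0  # ng/tube

    def __post_init__(self) -> None:
        if self.n_blanks < 2:
            raise ValueError("synthetic_gcims: n_blanks must be >= 2")
        if self.replicates < 1:
            raise ValueError("synthetic_gcims: replicates must be >= 1")
        if not self.compounds:
            raise ValueError("pipeline needs at least one compound")


@dataclass
class CompoundResult:
    """Per-compound, per-detector outcome of the pipeline."""

    compound: str
    detector: str  # "ims" | "ms"
    mode: AggregationMode
    blank_stats: BlankStats
    gamma: float  # mean blank noise amplitude in the analyte window, a.u.
    fits: dict[str, CalibrationFit]
    conversion_fit: CalibrationFit
    linear_range: tuple[float, float]
    decades: float
    limits: dict[str, DetectionLimits]  # method -> limits


@dataclass
class PipelineResult:
    config: PipelineConfig
    peak_table: pd.DataFrame
    ims: dict[str, CompoundResult]
    ms: dict[str, CompoundResult]
    comparison: pd.DataFrame
    qc_report: pd.DataFrame
    qc_limits: dict[str, dict]


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


# ----------------------------------------------------------------- windows


def windows_for(compound: CompoundSpec, half_widths: float = 4.0) -> dict[str, PeakWindow]:
    """Monomer/dimer search windows spanning +/- ``half_widths`` sigma."""
    rt = (
        compound.rt_monomer - half_widths * compound.rt_sigma,
        compound.rt_monomer + half_widths * compound.rt_sigma,
    )
    ddt = half_widths * compound.dt_sigma
    return {
        "monomer": PeakWindow(
            compound.name, Species.MONOMER, rt,
            (compound.dt_monomer - ddt, compound.dt_monomer + ddt),
        ),
        "dimer": PeakWindow(
            compound.name, Species.DIMER, rt,
            (compound.dt_dimer - ddt, compound.dt_dimer + ddt),
        ),
    }


def _reference_window(compound: CompoundSpec) -> PeakWindow:
    # signal-free drift band used to judge dimer presence in blanks
    rt = (
        compound.rt_monomer - 4 * compound.rt_sigma,
        compound.rt_monomer + 4 * compound.rt_sigma,
    )
    return PeakWindow(compound.name, Species.MONOMER, rt, (2.05, 2.15))


def _rip_window(compound: CompoundSpec, rt_apex: float, rt_step: float) -> PeakWindow:
    # single retention slice at the analyte apex, so depletion is read there
    return PeakWindow(
        compound.name,
        Species.RIP,
        (rt_apex - 0.51 * rt_step, rt_apex + 0.51 * rt_step),
        # wide enough that the window median (the baseline estimate for a
        # single-row block) falls on the off-ridge floor, not the RIP flank
        (0.94, 1.06),
    )


# ---------------------------------------------------------------- IMS side


def _route_mode(
    blanks, compound: CompoundSpec, factor: float
) -> tuple[AggregationMode, float]:
    """Monomer-only vs monomer+dimer routing from blank dimer evidence.

    A compound whose blanks already show dimer signal (mean blank dimer
    height exceeding ``factor`` times the noise amplitude in a signal-free
    reference band) must be calibrated on the monomer+dimer sum.
    """
    wins = windows_for(compound)
    ref = _reference_window(compound)
    dimer_heights = [peak_height(b, wins["dimer"]).height for b in blanks]
    ref_heights = [peak_height(b, ref).height for b in blanks]
    ref_mean = float(np.mean(ref_heights))
    dimer_mean = float(np.mean(dimer_heights))
    threshold = factor * ref_mean if ref_mean > 0 else 0.0
    if dimer_mean > threshold:
        return AggregationMode.MONOMER_PLUS_DIMER, dimer_mean
    return AggregationMode.MONOMER_ONLY, dimer_mean


def _blank_heights(blanks, compound: CompoundSpec, mode: AggregationMode) -> list[float]:
    wins = windows_for(compound)
    use = [wins["monomer"]]
    if mode == AggregationMode.MONOMER_PLUS_DIMER:
        use.append(wins["dimer"])
    return [
        aggregate_species([peak_height(b, w) for w in use], mode) for b in blanks
    ]


def _conversion_fit(
    points: Sequence[CalibrationPoint],
    mode: CalibrationMode,
    linear_range: tuple[float, float],
) -> CalibrationFit:
    low = [p for p in points if p.amount <= linear_range[1]]
    return fit_linear(low, mode)


def _analyze_ims_compound(
    compound: CompoundSpec,
    blanks,
    config: PipelineConfig,
    rng: np.random.Generator,
    peak_rows: list[dict],
) -> CompoundResult:
    mode, _ = _route_mode(blanks, compound, config.dimer_presence_factor)
    logger.info("signal_extraction: %s routed to %s", compound.name, mode.value)

    heights = _blank_heights(blanks, compound, mode)
    arr = np.asarray(heights)
    blank_stats = BlankStats(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
    gamma = float(arr.mean())  # blank amplitude at the analyte position

    series = generate_calibration_series(
        compound,
        config.ims_levels,
        config.replicates,
        seed=int(rng.integers(2**31)),
        axes=config.axes,
    )
    wins = windows_for(compound)
    points_routed: list[CalibrationPoint] = []
    points_monomer: list[CalibrationPoint] = []
    points_sum: list[CalibrationPoint] = []
    points_cip: list[CalibrationPoint] = []
    for chrom in series:
        amount = chrom.meta["amount_ng_per_tube"]
        mono = peak_height(chrom, wins["monomer"])
        dim = peak_height(chrom, wins["dimer"])
        rip = peak_height(
            chrom, _rip_window(compound, mono.rt_at_max, config.axes.rt_step)
        )
        for m in (mono, dim, rip):
            w = m.window
            peak_rows.append(
                {
                    "compound": compound.name,
                    "species": w.species.value,
                    "rt_lo": w.rt_range[0],
                    "rt_hi": w.rt_range[1],
                    "dt_lo": w.dt_range[0],
                    "dt_hi": w.dt_range[1],
                    "height": m.height,
                    "rt_at_max": m.rt_at_max,
                    "dt_at_max": m.dt_at_max,
                    "sample_id": chrom.meta.get("label", ""),
                    "amount_ng_per_tube": amount,
                }
            )
        aip_sum = mono.height + dim.height
        aip_routed = aip_sum if mode == AggregationMode.MONOMER_PLUS_DIMER else mono.height
        points_monomer.append(CalibrationPoint(amount, mono.height))
        points_sum.append(CalibrationPoint(amount, aip_sum))
        points_routed.append(CalibrationPoint(amount, aip_routed))
        # CIP against the RIP measured in the same spectrum: the measured RIP
        # is already the depleted reservoir, so CIP = AIP / RIP_measured
        # (identical, under charge conservation, to AIP/(RIP_blank - AIP)).
        if amount <= config.cip_max_level and rip.height > 0.05 * compound.model.r0:
            points_cip.append(
                CalibrationPoint(
                    amount, aip_routed, rip=rip.height, cip=aip_routed / rip.height
                )
            )

    fits = {
        "monomer": fit_linear(points_monomer, CalibrationMode.MONOMER),
        "sum": fit_linear(points_sum, CalibrationMode.SUM),
    }
    if len(points_cip) >= 3:
        fits["cip"] = fit_linear(points_cip, CalibrationMode.CIP)

    routed_mode = (
        CalibrationMode.SUM
        if mode == AggregationMode.MONOMER_PLUS_DIMER
        else CalibrationMode.MONOMER
    )
    linear_range = detect_linear_range(points_routed, routed_mode, config.r2_min)
    conversion = _conversion_fit(points_routed, routed_mode, linear_range)

    k = detection_factor_k(blank_stats.n, config.alpha, config.beta)
    xd_p = lod_presented(blank_stats, k)
    xq_p = loq_presented(blank_stats)
    xd_sn, xq_sn = lod_loq_sn(gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lims = {
            "presented": limits_in_amount(xd_p, xq_p, conversion, LimitMethod.PRESENTED, k),
            "sn": limits_in_amount(xd_sn, xq_sn, conversion, LimitMethod.SN, k),
        }
    return CompoundResult(
        compound=compound.name,
        detector="ims",
        mode=mode,
        blank_stats=blank_stats,
        gamma=gamma,
        fits=fits,
        conversion_fit=conversion,
        linear_range=linear_range,
        decades=math.log10(linear_range[1] / linear_range[0]),
        limits=lims,
    )


# ----------------------------------------------------------------- MS side


def _analyze_ms_compound(
    compound: CompoundSpec,
    config: PipelineConfig,
    rng: np.random.Generator,
    peak_rows: list[dict],
) -> CompoundResult:
    pos_min = compound.rt_monomer / 60.0
    window = PeakWindow(
        compound.name,
        Species.MONOMER,
        (pos_min - 4 * config.ms_peak_sigma, pos_min + 4 * config.ms_peak_sigma),
    )

    def trace(amount: float, label: str):
        return generate_ms_trace(
            [pos_min],
            [amount],
            ms_gain=config.ms_gain,
            ms_noise_sd=config.ms_noise_sd,
            peak_sigma=config.ms_peak_sigma,
            seed=rng,
            label=label,
        )

    blank_h = [
        peak_height(trace(0.0, f"ms_blank_{i:02d}"), window).height
        for i in range(config.n_blanks)
    ]
    arr = np.asarray(blank_h)
    blank_stats = BlankStats(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
    gamma = float(arr.mean())

    points: list[CalibrationPoint] = []
    for lv in config.ms_levels:
        for rep in range(config.replicates):
            t = trace(lv, f"{compound.name}_ms_{lv:g}ng_r{rep}")
            m = peak_height(t, window)
            points.append(CalibrationPoint(lv, m.height))
            peak_rows.append(
                {
                    "compound": compound.name,
                    "species": "TIC",
                    "rt_lo": window.rt_range[0],
                    "rt_hi": window.rt_range[1],
                    "dt_lo": np.nan,
                    "dt_hi": np.nan,
                    "height": m.height,
                    "rt_at_max": m.rt_at_max,
                    "dt_at_max": np.nan,
                    "sample_id": t.meta["label"],
                    "amount_ng_per_tube": lv,
                }
            )

    linear_range = detect_linear_range(points, CalibrationMode.MONOMER, config.r2_min)
    conversion = _conversion_fit(points, CalibrationMode.MONOMER, linear_range)
    fits = {"monomer": fit_linear(points, CalibrationMode.MONOMER)}

    k = detection_factor_k(blank_stats.n, config.alpha, config.beta)
    xd_p = lod_presented(blank_stats, k)
    xq_p = loq_presented(blank_stats)
    xd_sn, xq_sn = lod_loq_sn(gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lims = {
            "presented": limits_in_amount(xd_p, xq_p, conversion, LimitMethod.PRESENTED, k),
            "sn": limits_in_amount(xd_sn, xq_sn, conversion, LimitMethod.SN, k),
        }
    return CompoundResult(
        compound=compound.name,
        detector="ms",
        mode=AggregationMode.MONOMER_ONLY,
        blank_stats=blank_stats,
        gamma=gamma,
        fits=fits,
        conversion_fit=conversion,
        linear_range=linear_range,
        decades=math.log10(linear_range[1] / linear_range[0]),
        limits=lims,
    )


# ---------------------------------------------------------------------- QC


def _qc_stage(
    config: PipelineConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, dict]]:
    series: list[PrecisionSeries] = []
    chart_limits: dict[str, dict] = {}
    for compound in config.compounds:
        wins = windows_for(compound)
        intens, rts, dts = [], [], []
        for rep in range(config.qc_replicates):
            chrom = render_chromatogram(
                [compound],
                [config.qc_amount],
                axes=config.axes,
                seed=rng,
                label=f"{compound.name}_qc_r{rep}",
            )
            mono = peak_height(chrom, wins["monomer"])
            dim = peak_height(chrom, wins["dimer"])
            intens.append(mono.height + dim.height)
            rts.append(mono.rt_at_max)
            dts.append(dim.dt_at_max)
        for quantity, vals in (
            ("intensity_au", intens),
            ("retention_s", rts),
            ("drift_rel", dts),
        ):
            try:
                series.append(
                    PrecisionSeries(
                        compound.name,
                        quantity,
                        PrecisionDesign.REPEATABILITY,
                        tuple(vals),
                    )
                )
            except ValueError:
                continue
        chart_limits[compound.name] = dataclasses.asdict(control_chart(intens))
    # RSD of a constant series (zero mean jitter) is legitimate; zero-mean
    # series cannot occur for the positive quantities monitored here.
    return precision_report(series), chart_limits


# ----------------------------------------------------------------- driver


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and assemble the comparison report bundle."""
    master = np.random.default_rng(config.seed)
    rng_blanks = np.random.default_rng(int(master.integers(2**31)))
    rng_ims = np.random.default_rng(int(master.integers(2**31)))
    rng_ms = np.random.default_rng(int(master.integers(2**31)))
    rng_qc = np.random.default_rng(int(master.integers(2**31)))

    logger.info(
        "synthetic_gcims: %d blanks, %d IMS levels x%d, %d MS levels x%d, seed=%d",
        config.n_blanks,
        len(config.ims_levels),
        config.replicates,
        len(config.ms_levels),
        config.replicates,
        config.seed,
    )
    try:
        blanks = generate_blank(
            config.contaminants,
            config.n_blanks,
            seed=int(rng_blanks.integers(2**31)),
            axes=config.axes,
        )
    except ValueError as exc:
        raise ValueError(f"synthetic_gcims: {exc}") from exc

    peak_rows: list[dict] = []
    ims: dict[str, CompoundResult] = {}
    ms: dict[str, CompoundResult] = {}
    for compound in config.compounds:
        try:
            ims[compound.name] = _analyze_ims_compound(
                compound, blanks, config, rng_ims, peak_rows
            )
        except ValueError as exc:
            raise ValueError(f"ims/{compound.name}: {exc}") from exc
        try:
            ms[compound.name] = _analyze_ms_compound(
                compound, config, rng_ms, peak_rows
            )
        except ValueError as exc:
            raise ValueError(f"ms/{compound.name}: {exc}") from exc

    comparison = compare_detectors(
        {n: r.limits["presented"] for n, r in ims.items()},
        {n: r.limits["presented"] for n, r in ms.items()},
        ims_ranges={n: r.linear_range for n, r in ims.items()},
        ms_ranges={n: r.linear_range for n, r in ms.items()},
    )
    qc_report, qc_limits = _qc_stage(config, rng_qc)
    return PipelineResult(
        config=config,
        peak_table=pd.DataFrame(peak_rows, columns=iomod.PEAK_TABLE_COLUMNS),
        ims=ims,
        ms=ms,
        comparison=comparison,
        qc_report=qc_report,
        qc_limits=qc_limits,
    )


def compare_detectors(
    ims: Mapping[str, DetectionLimits],
    ms: Mapping[str, DetectionLimits],
    ims_ranges: Mapping[str, tuple[float, float]] | None = None,
    ms_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-compound sensitivity comparison: cD ratio MS/IMS and range widths."""
    if not ims or not ms:
        raise ValueError("compare_detectors needs non-empty inputs")
    if set(ims) != set(ms):
        raise ValueError(
            f"unmatched compounds: {sorted(set(ims) ^ set(ms))}"
        )
    rows = []
    for name in sorted(ims):
        cd_ims, cd_ms = ims[name].cD, ms[name].cD
        ratio = cd_ms / cd_ims if cd_ims > 0 else math.inf
        row = {
            "compound": name,
            "cD_ims_ng_per_tube": cd_ims,
            "cD_ms_ng_per_tube": cd_ms,
            "lod_ratio_ms_over_ims": ratio,
            "log10_ratio": math.log10(ratio) if 0 < ratio < math.inf else math.nan,
        }
        if ims_ranges is not None:
            lo, hi = ims_ranges[name]
            row["ims_decades"] = math.log10(hi / lo)
        if ms_ranges is not None:
            lo, hi = ms_ranges[name]
            row["ms_decades"] = math.log10(hi / lo)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ report


def _result_payload(r: CompoundResult) -> dict:
    return {
        "detector": r.detector,
        "calibration_mode": r.mode.value,
        "n_blank": r.blank_stats.n,
        "mean_au": r.blank_stats.mean,
        "sd_au": r.blank_stats.sd,
        "gamma_au": r.gamma,
        "linear_range_ng_per_tube": list(r.linear_range),
        "linear_range_decades": r.decades,
        "fit_range": list(r.conversion_fit.range),
        "fits": {
            name: {
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r2,
                "n_points": f.n_points,
            }
            for name, f in r.fits.items()
        },
        "limits": {
            method: {
                "k": lim.k,
                "xD_au": lim.xD,
                "xQ_au": lim.xQ,
                "cD_ng_per_tube": lim.cD,
                "cQ_ng_per_tube": lim.cQ,
                "extrapolated": lim.extrapolated,
                "clipped": lim.clipped,
            }
            for method, lim in r.limits.items()
        },
    }


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write the report bundle: peak table, limits, comparison, QC (CSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_peak_table(result.peak_table, outdir / "peak_table.csv")
    result.comparison.to_csv(outdir / "comparison.csv", index=False, float_format="%.6g")
    result.qc_report.to_csv(outdir / "qc_precision.csv", index=False, float_format="%.6g")
    payload = {
        "seed": result.config.seed,
        "ims": {n: _result_payload(r) for n, r in result.ims.items()},
        "ms": {n: _result_payload(r) for n, r in result.ms.items()},
        "qc_control_limits": result.qc_limits,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


# ----------------------------------------------------------------- config


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (YAML/JSON payload)."""
    data = dict(data)

    def comp(entry: dict) -> CompoundSpec:
        model = ResponseModel(**entry.pop("model", {}))
        return CompoundSpec(model=model, **entry)

    if "compounds" in data:
        data["compounds"] = [comp(dict(e)) for e in data["compounds"]]
    if "contaminants" in data:
        data["contaminants"] = [
            (comp(dict(e["compound"])), float(e["mean_ng"]), float(e["sd_ng"]))
            for e in data["contaminants"]
        ]
    if "axes" in data:
        data["axes"] = AxisSpec(**data["axes"])
    return PipelineConfig(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return default_config()
    return config_from_dict(data)
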