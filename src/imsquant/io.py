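"""File formats: chromatogram CSV, MS-trace CSV, peak tables, fit reports.

The chromatogram dialect is "axes-first": row 1 holds the drift axis
(RIP-relative), column 1 holds the retention axis (s), and cell (i, j) is
the intensity in a.u.; sample metadata travels in a JSON sidecar next to
the CSV (``<name>.meta.json``).  MS traces are two-column CSV
(retention_min, intensity).  Every writer round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationFit, CalibrationMode, CalibrationPoint
from .limits import DetectionLimits
from .synthetic import IMSChromatogram, MSTrace

__all__ = [
    "write_chromatogram",
    "read_chromatogram",
    "write_ms_trace",
    "read_ms_trace",
    "write_peak_table",
    "read_peak_table",
    "read_calibration_points",
    "write_fit_report",
    "read_fit_report",
    "write_limits_report",
]

PEAK_TABLE_COLUMNS = [
    "compound",
    "species",
    "rt_lo",
    "rt_hi",
    "dt_lo",
    "dt_hi",
    "height",
    "rt_at_max",
    "dt_at_max",
    "sample_id",
    "amount_ng_per_tube",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_chromatogram(chrom: IMSChromatogram, path: str | Path) -> None:
    path = Path(path)
    header = "," + ",".join(f"{v:.6g}" for v in chrom.drift_axis)
    lines = [header]
    for rt, row in zip(chrom.retention_axis, chrom.intensity):
        lines.append(f"{rt:.6g}," + ",".join(f"{v:.8g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    _sidecar(path).write_text(json.dumps(chrom.meta, indent=1, sort_keys=True))


def read_chromatogram(path: str | Path) -> IMSChromatogram:
    path = Path(path)
    raw = np.genfromtxt(path, delimiter=",")
    drift = raw[0, 1:]
    retention = raw[1:, 0]
    intensity = raw[1:, 1:]
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return IMSChromatogram(retention, drift, intensity, meta)


def write_ms_trace(trace: MSTrace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"retention_min": trace.retention_axis, "intensity": trace.intensity}
    )
    df.to_csv(path, index=False, float_format="%.8g")
    _sidecar(path).write_text(json.dumps(trace.meta, indent=1, sort_keys=True))


def read_ms_trace(path: str | Path) -> MSTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return MSTrace(df["retention_min"].to_numpy(), df["intensity"].to_numpy(), meta)


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    table[PEAK_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.8g")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_calibration_points(path: str | Path) -> list[CalibrationPoint]:
    """Read a calibration CSV: amount_ng_per_tube, intensity_au[, rip_au, replicate]."""
    df = pd.read_csv(path)
    has_rip = "rip_au" in df.columns
    return [
        CalibrationPoint(
            amount=float(row["amount_ng_per_tube"]),
            intensity=float(row["intensity_au"]),
            rip=float(row["rip_au"]) if has_rip and pd.notna(row["rip_au"]) else None,
        )
        for _, row in df.iterrows()
    ]


def write_fit_report(fit: CalibrationFit, path: str | Path) -> None:
    payload = {
        "mode": fit.mode.value,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r2": fit.r2,
        "range": list(fit.range),
        "n_points": fit.n_points,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fit_report(path: str | Path) -> CalibrationFit:
    payload = json.loads(Path(path).read_text())
    return CalibrationFit(
        mode=CalibrationMode(payload["mode"]),
        slope=payload["slope"],
        intercept=payload["intercept"],
        r2=payload["r2"],
        range=tuple(payload["range"]),
        n_points=payload["n_points"],
    )


def write_limits_report(
    limits: dict[str, DetectionLimits], path: str | Path, extra: dict | None = None
) -> None:
    """Per-compound detection-limit JSON report."""
    payload: dict = {}
    for name, lim in limits.items():
        entry = dataclasses.asdict(lim)
        entry["method"] = lim.method.value
        payload[name] = entry
    if extra:
        payload["_meta"] = extra
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
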