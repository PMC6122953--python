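"""Format readers and writers.

All on-disk formats are text (CSV, JSON) except movies, which are
multi-page TIFF. Units are normalized on read: localization coordinates in
nm (ThunderSTORM-style ``x [nm]`` headers are accepted, and pixel-unit
tables are converted when a calibration is supplied), times in ms or s as
declared per format, impedance in Ω.
"""

from __future__ import annotations

import json
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile

from perinexus.ecg import EcgTrace
from perinexus.ecis import ImpedanceSeries, ResistanceTrace
from perinexus.storm_rla import LocalizationTable, RelativeLocalizationSummary
from perinexus.synth.truth import SceneTruth
from perinexus.ultrastructure import MembraneTracePair, WidthProfile

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_movie",
    "write_movie",
    "read_impedance",
    "write_impedance",
    "write_resistance_trace",
    "read_membrane_traces",
    "write_membrane_traces",
    "read_ecg",
    "write_ecg",
    "write_summary",
    "write_histogram",
    "write_width_profile",
]

# accepted header spellings, normalized to our canonical column names
_LOC_ALIASES = {
    "x_nm": ["x_nm", "x [nm]"],
    "y_nm": ["y_nm", "y [nm]"],
    "z_nm": ["z_nm", "z [nm]"],
    "frame": ["frame"],
    "precision_nm": ["precision_nm", "uncertainty [nm]", "uncertainty_xy [nm]"],
}
_LOC_PX = {"x_nm": ["x_px", "x [px]", "x"], "y_nm": ["y_px", "y [px]", "y"], "z_nm": ["z_px", "z [px]", "z"]}


def read_localizations(
    path,
    channel: str = "",
    calibration_nm_per_px: Optional[float] = None,
) -> LocalizationTable:
    """Read a localization table (CSV), normalizing column names to nm.

    Headers may be our canonical ``x_nm, y_nm, z_nm, frame, precision_nm``
    or ThunderSTORM-style ``x [nm]`` etc. Pixel-unit columns (``x_px`` or
    bare ``x``) are converted with ``calibration_nm_per_px``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse localization CSV {path}: {exc}") from exc

    out = {}
    for canon, names in _LOC_ALIASES.items():
        for name in names:
            if name in df.columns:
                out[canon] = df[name].to_numpy()
                break
    for canon, names in _LOC_PX.items():
        if canon in out:
            continue
        for name in names:
            if name in df.columns:
                if calibration_nm_per_px is None:
                    raise ValueError(
                        f"column {name!r} is in pixels; supply calibration_nm_per_px"
                    )
                out[canon] = df[name].to_numpy() * calibration_nm_per_px
                break
    missing = {"x_nm", "y_nm", "z_nm"} - set(out)
    if missing:
        raise ValueError(f"localization file {path} missing columns: {sorted(missing)}")
    n = len(out["x_nm"])
    out.setdefault("frame", np.zeros(n, dtype=int))
    out.setdefault("precision_nm", np.full(n, np.nan))
    frame = pd.DataFrame(out)[["x_nm", "y_nm", "z_nm", "frame", "precision_nm"]]
    if frame["precision_nm"].isna().all():
        frame = frame.drop(columns=["precision_nm"])
    return LocalizationTable(points=frame, channel=channel)


def write_localizations(path, table: LocalizationTable) -> None:
    table.points.to_csv(path, index=False)


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def read_impedance(path) -> List[ImpedanceSeries]:
    """Read a long-format impedance CSV; one series per (well, condition)."""
    df = pd.read_csv(path)
    required = {"time_s", "frequency_hz", "re_ohm", "im_ohm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"impedance file {path} missing columns: {sorted(missing)}")
    for col, default in (("well", "W1"), ("condition", "")):
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    series = []
    for (well, cond), grp in df.groupby(["well", "condition"], sort=True):
        series.append(ImpedanceSeries.from_long_frame(grp, well=str(well), condition=str(cond)))
    return series


def write_impedance(path, series: ImpedanceSeries) -> None:
    series.to_long_frame().to_csv(path, index=False)


def write_resistance_trace(path, trace: ResistanceTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "resistance_ohm": trace.resistance_ohm}
    ).to_csv(path, index=False)


def read_membrane_traces(path, calibration_nm_per_px: float = 1.0) -> List[MembraneTracePair]:
    """Read digitized membrane trace pairs from CSV.

    Expected columns: ``trace_id, point_index, x_nm, y_nm, role`` with role
    in {A, B}; optional ``heart`` and ``condition`` labels per trace.
    """
    df = pd.read_csv(path)
    required = {"trace_id", "point_index", "x_nm", "y_nm", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"membrane trace file {path} missing columns: {sorted(missing)}")
    pairs = []
    for tid, grp in df.groupby("trace_id", sort=True):
        polys = {}
        for role in ("A", "B"):
            sel = grp[grp["role"] == role].sort_values("point_index")
            if len(sel) < 2:
                raise ValueError(f"trace {tid}: polyline {role} has fewer than 2 points")
            polys[role] = sel[["x_nm", "y_nm"]].to_numpy(dtype=float)
        pairs.append(
            MembraneTracePair(
                polyline_a=polys["A"],
                polyline_b=polys["B"],
                calibration_nm_per_px=calibration_nm_per_px,
                label=str(tid),
                heart=str(grp["heart"].iloc[0]) if "heart" in grp.columns else "",
                condition=str(grp["condition"].iloc[0]) if "condition" in grp.columns else "",
            )
        )
    return pairs


def write_membrane_traces(path, pairs: List[MembraneTracePair]) -> None:
    rows = []
    for pair in pairs:
        for role, poly in (("A", pair.polyline_a), ("B", pair.polyline_b)):
            for i, (x, y) in enumerate(poly):
                rows.append(
                    {
                        "trace_id": pair.label or "trace0",
                        "point_index": i,
                        "x_nm": x,
                        "y_nm": y,
                        "role": role,
                        "heart": pair.heart,
                        "condition": pair.condition,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_width_profile(path, profile: WidthProfile) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_ecg(path, pacing_path=None) -> EcgTrace:
    """Read an ECG CSV with columns ``time_ms, mv``; pacing times optional.

    Pacing stimulus times may come from a second CSV (column ``time_ms``)
    or a ``pacing`` 0/1 column in the main file.
    """
    df = pd.read_csv(path)
    missing = {"time_ms", "mv"} - set(df.columns)
    if missing:
        raise ValueError(f"ECG file {path} missing columns: {sorted(missing)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("ECG sampling interval is not constant")
        fs = 1000.0 / dt[0]
    else:
        fs = 1000.0
    pacing = None
    if pacing_path is not None:
        pdf = pd.read_csv(pacing_path)
        pacing = pdf["time_ms"].to_numpy(dtype=float)
    elif "pacing" in df.columns:
        pacing = t[df["pacing"].to_numpy(dtype=bool)]
    return EcgTrace(signal_mv=df["mv"].to_numpy(dtype=float), fs_hz=fs, pacing_times_ms=pacing)


def write_ecg(path, trace: EcgTrace) -> None:
    df = pd.DataFrame({"time_ms": trace.time_ms, "mv": trace.signal_mv})
    if trace.pacing_times_ms is not None and len(trace.pacing_times_ms):
        idx = np.zeros(len(df), dtype=int)
        sample = np.round(np.asarray(trace.pacing_times_ms) * trace.fs_hz / 1000.0).astype(int)
        idx[sample[(sample >= 0) & (sample < len(df))]] = 1
        df["pacing"] = idx
    df.to_csv(path, index=False)


def write_summary(path, summary: RelativeLocalizationSummary) -> None:
    """Write a relative-localization summary as JSON (per-cluster + population)."""
    payload = {
        "adjacency_nm": summary.adjacency_nm,
        "fractions": summary.fractions,
        "n_partner_clusters": int(summary.table.shape[0]),
        "overlap_degrees": [float(v) for v in summary.overlap_degrees],
        "clusters": summary.table.replace({np.inf: "inf"}).to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_histogram(path, summary: RelativeLocalizationSummary) -> None:
    """Signed-distance histogram as CSV (bin edges in nm)."""
    pd.DataFrame(
        {
            "bin_left_nm": summary.histogram_edges_nm[:-1],
            "bin_right_nm": summary.histogram_edges_nm[1:],
            "count": summary.histogram_counts,
        }
    ).to_csv(path, index=False)
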