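"""Stage orchestration with reproducibility manifests.

Every stage run writes its outputs plus a ``manifest.json`` recording the
stage name, the full effective configuration (so every default is visible
in the run record), the seed, the package version and the SHA-256 of every
output file — enough to re-run the stage bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from perinexus import __version__, io
from perinexus.synth import (
    EcgConfig,
    EcisConfig,
    MembraneTraceConfig,
    OpticalMovieConfig,
    StormSceneConfig,
    gen_ecg,
    gen_ecis_series,
    gen_membrane_traces,
    gen_optical_movie,
    gen_storm_scene,
)
from perinexus.synth.truth import _jsonable

logger = logging.getLogger("perinexus")

STAGES = ("synth", "storm-rla", "conduction", "ecis", "ultrastructure", "ecg")

_SYNTH_CONFIGS = {
    "storm": StormSceneConfig,
    "optical": OpticalMovieConfig,
    "ecis": EcisConfig,
    "membranes": MembraneTraceConfig,
    "ecg": EcgConfig,
}


def build_config(cls, overrides: Optional[dict] = None):
    """Instantiate a stage config dataclass, rejecting unknown keys."""
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    # coerce YAML lists back to tuples where the default is a tuple
    for f in dataclasses.fields(cls):
        if f.name in overrides and isinstance(getattr(cls(), f.name, None), tuple):
            overrides[f.name] = tuple(overrides[f.name])
    return cls(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, config, seed: Optional[int], outputs) -> Path:
    config_json = json.dumps(_jsonable(config), sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": __version__,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_synth(modality: str, out_dir, seed: int = 0, overrides: Optional[dict] = None) -> list:
    """Generate one synthetic modality into ``out_dir``; returns output paths."""
    if modality not in _SYNTH_CONFIGS:
        raise ValueError(f"unknown modality {modality!r}; choose from {sorted(_SYNTH_CONFIGS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = build_config(_SYNTH_CONFIGS[modality], overrides)
    logger.info("synth %s seed=%d config=%s", modality, seed, cfg)

    outputs = []
    if modality == "storm":
        tables, fiducials, truth = gen_storm_scene(cfg, seed=seed)
        for ch, table in tables.items():
            p = out_dir / f"channel_{ch}.csv"
            io.write_localizations(p, table)
            outputs.append(p)
        for ch, fid in fiducials.items():
            p = out_dir / f"fiducials_{ch}.csv"
            fid.to_csv(p, index=False)
            outputs.append(p)
    elif modality == "optical":
        movie, truth = gen_optical_movie(cfg, seed=seed)
        p = out_dir / "movie.tif"
        io.write_movie(p, movie)
        outputs.append(p)
    elif modality == "ecis":
        series, truth = gen_ecis_series(cfg, seed=seed)
        p = out_dir / "impedance.csv"
        io.write_impedance(p, series)
        outputs.append(p)
    elif modality == "membranes":
        pair, truth = gen_membrane_traces(cfg, seed=seed)
        p = out_dir / "traces.csv"
        io.write_membrane_traces(p, [pair])
        outputs.append(p)
    else:  # ecg
        trace, truth = gen_ecg(cfg, seed=seed)
        p = out_dir / "ecg.csv"
        io.write_ecg(p, trace)
        outputs.append(p)

    p = out_dir / "truth.json"
    truth.to_json(p)
    outputs.append(p)
    write_manifest(out_dir, f"synth:{modality}", cfg, seed, outputs)
    return outputs


def run_storm_rla(
    channel_a,
    channel_b,
    out_dir,
    fiducials_a=None,
    fiducials_b=None,
    overrides: Optional[dict] = None,
) -> dict:
    """Full relative-localization analysis from CSV inputs; writes summary JSON."""
    from perinexus.storm_rla import (
        ClusterDetector,
        RelativeLocalizationClassifier,
        register_channels,
    )

    defaults = {
        "radius_nm": 30.0,
        "min_points": 5,
        "min_cluster_size": 10,
        "adjacency_nm": 200.0,
        "voxel_nm": 20.0,
        "dilation_nm": None,
        "gate_nm": 500.0,
    }
    unknown = set(overrides or {}) - set(defaults)
    if unknown:
        raise ValueError(f"unknown storm-rla config keys: {sorted(unknown)}")
    cfg = {**defaults, **(overrides or {})}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_a = io.read_localizations(channel_a, channel="A")
    table_b = io.read_localizations(channel_b, channel="B")
    registration = None
    if fiducials_a is not None and fiducials_b is not None:
        import pandas as pd

        fa = pd.read_csv(fiducials_a)
        fb = pd.read_csv(fiducials_b)
        table_b, transform = register_channels(fa, fb, table_b, gate_nm=cfg["gate_nm"])
        registration = {
            "rotation": transform.rotation.tolist(),
            "translation_nm": transform.translation_nm.tolist(),
            "residual_rms_nm": transform.residual_rms_nm,
            "n_pairs": transform.n_pairs,
        }
        logger.info("registered channel B: residual %.2f nm", transform.residual_rms_nm)

    det = ClusterDetector(
        radius_nm=cfg["radius_nm"],
        min_points=cfg["min_points"],
        min_cluster_size=cfg["min_cluster_size"],
    )
    set_a = det.fit(table_a).cluster_set_
    set_b = ClusterDetector(**det.get_params()).fit(table_b).cluster_set_
    clf = RelativeLocalizationClassifier(
        adjacency_nm=cfg["adjacency_nm"], voxel_nm=cfg["voxel_nm"], dilation_nm=cfg["dilation_nm"]
    ).fit(set_b, set_a)
    summary = clf.summary_

    summary_path = out_dir / "summary.json"
    io.write_summary(summary_path, summary)
    hist_path = out_dir / "distance_histogram.csv"
    io.write_histogram(hist_path, summary)
    outputs = [summary_path, hist_path]
    write_manifest(out_dir, "storm-rla", {**cfg, "registration": registration}, None, outputs)
    return {"summary": summary, "registration": registration, "outputs": outputs}


def run_conduction(movie_path, out_dir, overrides: Optional[dict] = None) -> dict:
    """Conduction analysis of a movie TIFF; writes CV summary JSON."""
    from perinexus.conduction import ConductionVelocityEstimator

    est = ConductionVelocityEstimator()
    unknown = set(overrides or {}) - set(est.get_params())
    if unknown:
        raise ValueError(f"unknown conduction config keys: {sorted(unknown)}")
    est.set_params(**(overrides or {}))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie = io.read_movie(movie_path)
    est.fit(movie)
    result = {
        "cv_l_cm_s": est.cv_l_cm_s_,
        "cv_t_cm_s": est.cv_t_cm_s_,
        "anisotropy_ratio": est.anisotropy_ratio_,
        "fast_axis_deg": est.fast_axis_deg_,
        "pacing_pixel": list(est.activation_map_.pacing_pixel),
        "n_valid_pixels": int(est.activation_map_.valid.sum()),
    }
    p = out_dir / "cv_summary.json"
    p.write_text(json.dumps(result, indent=2))
    np.savetxt(out_dir / "activation_ms.csv", est.activation_map_.times_ms, delimiter=",", fmt="%.4f")
    outputs = [p, out_dir / "activation_ms.csv"]
    write_manifest(out_dir, "conduction", est.get_params(), None, outputs)
    return {**result, "outputs": outputs}


def run_ecis(series_path, out_dir, band=(62.5, 4000.0), baseline=None) -> dict:
    """Band-averaged resistance traces for every series in the file."""
    from perinexus.ecis import normalize_to_baseline, resistance_trace

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    traces = {}
    for series in io.read_impedance(series_path):
        trace = resistance_trace(series, band_hz=tuple(band))
        if baseline is not None:
            trace = normalize_to_baseline(trace, tuple(baseline))
        name = f"resistance_{series.well or 'W1'}.csv"
        p = out_dir / name
        io.write_resistance_trace(p, trace)
        outputs.append(p)
        traces[series.well] = trace
    write_manifest(out_dir, "ecis", {"band_hz": list(band), "baseline": baseline}, None, outputs)
    return {"traces": traces, "outputs": outputs}


def run_ultrastructure(traces_path, out_dir, step_nm=5.0, zone_end_nm=150.0) -> dict:
    """Width profiles plus per-zone hierarchical summaries."""
    from perinexus.ultrastructure import summarize_widths, width_profile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = io.read_membrane_traces(traces_path)
    profiles = [width_profile(p, step_nm=step_nm, zone_end_nm=zone_end_nm) for p in pairs]
    outputs = []
    for prof in profiles:
        p = out_dir / f"profile_{prof.label or 'trace0'}.csv"
        io.write_width_profile(p, prof)
        outputs.append(p)
    summary = {}
    for zone in ("perinexal", "nonjunctional"):
        try:
            summary[zone] = summarize_widths(profiles, zone=zone)
        except ValueError:
            summary[zone] = None
    p = out_dir / "width_summary.json"
    p.write_text(json.dumps(_jsonable(summary), indent=2))
    outputs.append(p)
    write_manifest(
        out_dir, "ultrastructure", {"step_nm": step_nm, "zone_end_nm": zone_end_nm}, None, outputs
    )
    return {"profiles": profiles, "summary": summary, "outputs": outputs}


def run_ecg(ecg_path, out_dir, pacing_path=None, overrides: Optional[dict] = None) -> dict:
    """Beat detection, VT screening and interval measurement; writes JSON."""
    from perinexus.ecg import BeatDetector, detect_vt, measure_intervals

    defaults = {
        "min_prominence_mv": 0.3,
        "refractory_ms": 50.0,
        "pacing_gate_ms": 10.0,
        "cl_threshold_ms": 130.0,
        "min_run": 3,
        "mode": "every",
    }
    unknown = set(overrides or {}) - set(defaults)
    if unknown:
        raise ValueError(f"unknown ecg config keys: {sorted(unknown)}")
    cfg = {**defaults, **(overrides or {})}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace = io.read_ecg(ecg_path, pacing_path=pacing_path)
    det = BeatDetector(
        min_prominence_mv=cfg["min_prominence_mv"],
        refractory_ms=cfg["refractory_ms"],
        pacing_gate_ms=cfg["pacing_gate_ms"],
    ).fit(trace)
    episodes = detect_vt(
        det.beat_times_ms_,
        det.paced_,
        cl_threshold_ms=cfg["cl_threshold_ms"],
        min_run=cfg["min_run"],
        mode=cfg["mode"],
    )
    intervals = []
    for t in det.beat_times_ms_:
        try:
            intervals.append(measure_intervals(trace, t))
        except ValueError:
            intervals.append(None)
    result = {
        "beat_times_ms": det.beat_times_ms_.tolist(),
        "paced": det.paced_.tolist(),
        "intervals": intervals,
        "vt_episodes": [
            {
                "start_index": e.start_index,
                "end_index": e.end_index,
                "n_beats": e.n_beats,
                "mean_cycle_length_ms": e.mean_cycle_length_ms,
                "duration_ms": e.duration_ms,
            }
            for e in episodes
        ],
    }
    p = out_dir / "ecg_analysis.json"
    p.write_text(json.dumps(_jsonable(result), indent=2))
    write_manifest(out_dir, "ecg", cfg, None, [p])
    return {**result, "outputs": [p]}
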