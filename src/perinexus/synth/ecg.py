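"""Synthetic paced ECGs with optional inserted tachycardia runs.

The trace is a sum of stereotyped beat complexes: a raised-cosine QRS of
configurable width and a later, broader raised-cosine T wave. Paced beats
occur at a fixed cycle length and are flagged in the ground truth (with
matching pacing-stimulus times); an optional run of short-cycle non-paced
beats emulates ventricular tachycardia. T waves are omitted for beats whose
successor arrives before repolarization would complete, as happens during
rapid runs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from perinexus.ecg import EcgTrace
from perinexus.synth.truth import SceneTruth


@dataclass
class EcgConfig:
    """Configuration for :func:`gen_ecg`.

    Defaults: ten beats paced at 300 ms cycle length, 1 kHz sampling,
    30 ms QRS, no tachycardia run, no noise.
    """

    n_paced: int = 10
    paced_cl_ms: float = 300.0
    first_beat_ms: float = 100.0
    fs_hz: float = 1000.0
    duration_ms: Optional[float] = None  # default: auto
    qrs_width_ms: float = 30.0
    qrs_amplitude_mv: float = 1.0
    t_amplitude_mv: float = 0.25
    t_width_ms: float = 100.0
    t_offset_ms: float = 160.0  # R peak to T-wave centre
    vt_n_beats: int = 0
    vt_cl_ms: float = 120.0
    vt_start_ms: Optional[float] = None  # default: one paced CL after last paced beat
    noise_sigma_mv: float = 0.0
    vt_rule_cl_ms: float = 130.0
    vt_rule_min_run: int = 3

    def validate(self):
        if self.paced_cl_ms <= 0 or (self.vt_n_beats and self.vt_cl_ms <= 0):
            raise ValueError("cycle lengths must be > 0")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be > 0")


def _raised_cosine(t_ms: np.ndarray, center_ms: float, width_ms: float, amp: float) -> np.ndarray:
    dt = t_ms - center_ms
    inside = np.abs(dt) < width_ms / 2
    out = np.zeros_like(t_ms)
    out[inside] = amp / 2 * (1 + np.cos(2 * np.pi * dt[inside] / width_ms))
    return out


def _planted_vt_runs(times, paced, cl_ms, min_run):
    """Enumerate maximal qualifying runs directly from the planted beats."""
    runs = []
    n = len(times)
    i = 0
    ok = [
        (not paced[k]) and (not paced[k + 1]) and (times[k + 1] - times[k] < cl_ms)
        for k in range(n - 1)
    ]
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if j - i + 2 >= min_run:
                runs.append(
                    {
                        "start_beat": i,
                        "n_beats": j - i + 2,
                        "start_ms": float(times[i]),
                        "cycle_length_ms": float(np.diff(times[i : j + 2]).mean()),
                    }
                )
            i = j + 1
        i += 1
    return runs


def gen_ecg(config: EcgConfig | None = None, seed: int = 0):
    """Generate a synthetic ECG; returns ``(EcgTrace, SceneTruth)``.

    Raises
    ------
    ValueError
        If any two beats fall closer together than the QRS width.
    """
    cfg = config or EcgConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    paced_times = cfg.first_beat_ms + cfg.paced_cl_ms * np.arange(cfg.n_paced)
    beats = [(float(t), True) for t in paced_times]
    if cfg.vt_n_beats > 0:
        start = (
            cfg.vt_start_ms
            if cfg.vt_start_ms is not None
            else (paced_times[-1] + cfg.paced_cl_ms if cfg.n_paced else cfg.first_beat_ms)
        )
        beats += [
            (float(start + k * cfg.vt_cl_ms), False) for k in range(cfg.vt_n_beats)
        ]
    beats.sort(key=lambda b: b[0])
    times = np.array([b[0] for b in beats])
    paced = np.array([b[1] for b in beats])

    if len(times) > 1 and (np.diff(times) < cfg.qrs_width_ms).any():
        raise ValueError("overlapping beats: cycle length shorter than the QRS width")

    if cfg.duration_ms is None:
        duration = float((times[-1] if len(times) else 0.0) + cfg.t_offset_ms + cfg.t_width_ms + 100.0)
    else:
        duration = float(cfg.duration_ms)
    n = int(round(duration * cfg.fs_hz / 1000.0))
    t_ms = np.arange(n) * 1000.0 / cfg.fs_hz

    x = np.zeros(n)
    for i, (tb, _) in enumerate(beats):
        x += _raised_cosine(t_ms, tb, cfg.qrs_width_ms, cfg.qrs_amplitude_mv)
        next_gap = times[i + 1] - tb if i + 1 < len(times) else np.inf
        if next_gap >= cfg.t_offset_ms + cfg.t_width_ms / 2:
            x += _raised_cosine(t_ms, tb + cfg.t_offset_ms, cfg.t_width_ms, cfg.t_amplitude_mv)
    if cfg.noise_sigma_mv > 0:
        x = x + rng.normal(0.0, cfg.noise_sigma_mv, size=n)

    trace = EcgTrace(
        signal_mv=x,
        fs_hz=cfg.fs_hz,
        pacing_times_ms=times[paced] if paced.any() else np.array([]),
    )
    vt_runs = _planted_vt_runs(times, paced, cfg.vt_rule_cl_ms, cfg.vt_rule_min_run)
    truth = SceneTruth(
        modality="ecg",
        seed=seed,
        params=asdict(cfg),
        records={
            "beat_times_ms": times.tolist(),
            "paced": paced.tolist(),
            "vt_runs": vt_runs,
            "qrs_width_ms": cfg.qrs_width_ms,
            # geometric QT of the template: QRS onset to end of the T bump
            "qt_ms": cfg.qrs_width_ms / 2 + cfg.t_offset_ms + cfg.t_width_ms / 2,
        },
    )
    return trace, truth
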