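"""Beat detection, tachycardia-rule screening and interval measurement
for volume-conducted ECGs sampled at 1 kHz.

Ventricular tachycardia (VT) is detected with an explicit rule: three or
more consecutive, non-paced heartbeats with a cycle length shorter than
130 ms. The default interpretation applies the cycle-length criterion to
*every* inter-beat interval within the run (a run's first beat qualifies
through the interval to its successor); an alternative ``mode="mean"``
applies it to the run's mean cycle length.

QRS duration is measured by derivative-threshold crossings (a fraction of
the maximum |dV/dt| around the R peak); the QT interval runs from QRS
onset to the T-wave end located by the tangent method (intersection of the
steepest T-downslope tangent with the isoelectric baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

__all__ = [
    "EcgTrace",
    "VTEpisode",
    "BeatDetector",
    "detect_beats",
    "detect_vt",
    "measure_intervals",
]


@dataclass
class EcgTrace:
    """An ECG voltage trace with optional pacing-stimulus times."""

    signal_mv: np.ndarray
    fs_hz: float = 1000.0
    pacing_times_ms: Optional[np.ndarray] = None

    def __post_init__(self):
        self.signal_mv = np.asarray(self.signal_mv, dtype=float)
        if not np.isfinite(self.signal_mv).all():
            raise ValueError("ECG samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.pacing_times_ms is not None:
            self.pacing_times_ms = np.asarray(self.pacing_times_ms, dtype=float)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.signal_mv)) * 1000.0 / self.fs_hz

    @property
    def duration_ms(self) -> float:
        return len(self.signal_mv) * 1000.0 / self.fs_hz


@dataclass
class VTEpisode:
    """A detected run of rapid non-paced beats."""

    start_index: int
    end_index: int  # inclusive
    beat_times_ms: np.ndarray

    def __post_init__(self):
        self.beat_times_ms = np.asarray(self.beat_times_ms, dtype=float)
        if len(self.beat_times_ms) < 3:
            raise ValueError("a VT episode requires >= 3 beats")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times_ms)

    @property
    def mean_cycle_length_ms(self) -> float:
        return float(np.diff(self.beat_times_ms).mean())

    @property
    def duration_ms(self) -> float:
        return float(self.beat_times_ms[-1] - self.beat_times_ms[0])


class BeatDetector(BaseEstimator):
    """QRS detection by peak finding on the rectified, band-passed signal.

    Peaks must exceed ``min_prominence_mv`` and be separated by at least
    ``refractory_ms``. Each detected beat is flagged *paced* when it falls
    within ``pacing_gate_ms`` of a pacing-stimulus time.

    Fitted attributes: ``beat_times_ms_``, ``paced_``.
    """

    def __init__(
        self,
        min_prominence_mv: float = 0.3,
        refractory_ms: float = 50.0,
        pacing_gate_ms: float = 10.0,
        band_hz: Tuple[float, float] = (10.0, 40.0),
    ):
        self.min_prominence_mv = min_prominence_mv
        self.refractory_ms = refractory_ms
        self.pacing_gate_ms = pacing_gate_ms
        self.band_hz = band_hz

    def fit(self, trace: EcgTrace, y=None):
        x = trace.signal_mv
        if len(x) == 0:
            raise ValueError("empty ECG trace")
        fs = trace.fs_hz
        nyq = fs / 2.0
        lo, hi = self.band_hz
        hi = min(hi, 0.95 * nyq)
        sos = sps.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
        filtered = np.abs(sps.sosfiltfilt(sos, x - np.median(x)))

        distance = max(int(self.refractory_ms * fs / 1000.0), 1)
        peaks, _ = sps.find_peaks(
            filtered, prominence=self.min_prominence_mv, distance=distance
        )
        # refine to the local extremum of the raw (baseline-removed) signal
        half = max(int(10 * fs / 1000.0), 1)
        raw = np.abs(x - np.median(x))
        times = []
        for p in peaks:
            lo_i, hi_i = max(p - half, 0), min(p + half + 1, len(x))
            times.append((lo_i + int(raw[lo_i:hi_i].argmax())) * 1000.0 / fs)
        times = np.asarray(sorted(times), dtype=float)

        paced = np.zeros(len(times), dtype=bool)
        if trace.pacing_times_ms is not None and len(trace.pacing_times_ms):
            for i, t in enumerate(times):
                paced[i] = np.abs(trace.pacing_times_ms - t).min() <= self.pacing_gate_ms
        self.beat_times_ms_ = times
        self.paced_ = paced
        return self


def detect_beats(
    trace: EcgTrace,
    min_prominence_mv: float = 0.3,
    refractory_ms: float = 50.0,
    pacing_gate_ms: float = 10.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Detect beats; returns (beat times in ms, paced flags)."""
    det = BeatDetector(
        min_prominence_mv=min_prominence_mv,
        refractory_ms=refractory_ms,
        pacing_gate_ms=pacing_gate_ms,
    ).fit(trace)
    return det.beat_times_ms_, det.paced_


def detect_vt(
    beat_times_ms: Sequence[float],
    paced: Sequence[bool],
    cl_threshold_ms: float = 130.0,
    min_run: int = 3,
    mode: str = "every",
    min_duration_ms: Optional[float] = None,
) -> List[VTEpisode]:
    """Detect ventricular-tachycardia episodes among detected beats.

    A VT episode is a maximal run of at least ``min_run`` consecutive
    non-paced beats that are fast: in ``mode="every"`` (default) every
    inter-beat interval within the run must be shorter than
    ``cl_threshold_ms``; in ``mode="mean"`` the run's mean cycle length
    must be. ``min_duration_ms`` optionally filters short episodes at the
    reporting stage (detection itself is duration-free).
    """
    t = np.asarray(beat_times_ms, dtype=float)
    p = np.asarray(paced, dtype=bool)
    if len(t) != len(p):
        raise ValueError("beat times and paced flags must have equal length")
    if len(t) > 1 and (np.diff(t) < 0).any():
        raise ValueError("beat times must be ordered")

    episodes: List[VTEpisode] = []
    if mode == "every":
        # eligible interval i connects beats i and i+1
        ok = np.zeros(max(len(t) - 1, 0), dtype=bool)
        for i in range(len(ok)):
            ok[i] = (not p[i]) and (not p[i + 1]) and (t[i + 1] - t[i] < cl_threshold_ms)
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                n_beats = j - i + 2
                if n_beats >= min_run:
                    episodes.append(
                        VTEpisode(start_index=i, end_index=j + 1, beat_times_ms=t[i : j + 2])
                    )
                i = j + 1
            i += 1
    elif mode == "mean":
        i = 0
        while i < len(t):
            if not p[i]:
                j = i
                while j + 1 < len(t) and not p[j + 1]:
                    j += 1
                n_beats = j - i + 1
                if n_beats >= min_run and float(np.diff(t[i : j + 1]).mean()) < cl_threshold_ms:
                    episodes.append(
                        VTEpisode(start_index=i, end_index=j, beat_times_ms=t[i : j + 1])
                    )
                i = j
            i += 1
    else:
        raise ValueError(f"unknown VT mode {mode!r}")

    if min_duration_ms is not None:
        episodes = [e for e in episodes if e.duration_ms >= min_duration_ms]
    return episodes


def measure_intervals(
    trace: EcgTrace,
    beat_time_ms: float,
    derivative_fraction: float = 0.1,
    qrs_search_ms: float = 80.0,
    t_search_ms: Tuple[float, float] = (80.0, 250.0),
    t_min_amplitude_mv: float = 0.05,
) -> dict:
    """Measure QRS duration and QT interval around one beat.

    QRS onset/offset are the outermost crossings of
    ``derivative_fraction × max |dV/dt|`` within ``±qrs_search_ms`` of the
    R peak. The T-wave end is found by the tangent method; if no T wave
    exceeding ``t_min_amplitude_mv`` is found, ``qt_ms`` is NaN and a
    warning is issued.
    """
    x = trace.signal_mv
    fs = trace.fs_hz
    baseline = float(np.median(x))
    d = np.gradient(x) * fs / 1000.0  # mV per ms
    r_idx = int(round(beat_time_ms * fs / 1000.0))
    if not 0 <= r_idx < len(x):
        raise ValueError("beat time outside the trace")

    w = int(qrs_search_ms * fs / 1000.0)
    lo, hi = max(r_idx - w, 0), min(r_idx + w + 1, len(x))
    seg_d = np.abs(d[lo:hi])
    dmax = seg_d.max() if len(seg_d) else 0.0
    if dmax <= 1e-12:
        raise ValueError("baseline-only window: no QRS deflection found")
    thr = derivative_fraction * dmax

    above = np.flatnonzero(seg_d >= thr)
    onset_idx = lo + above[0]
    offset_idx = lo + above[-1]
    qrs_ms = (offset_idx - onset_idx) * 1000.0 / fs

    # T-wave end by the tangent method
    t_lo = min(r_idx + int(t_search_ms[0] * fs / 1000.0), len(x) - 1)
    t_hi = min(r_idx + int(t_search_ms[1] * fs / 1000.0), len(x))
    qt_ms = np.nan
    if t_hi - t_lo > 3:
        seg = x[t_lo:t_hi] - baseline
        t_peak = t_lo + int(np.abs(seg).argmax())
        t_amp = x[t_peak] - baseline
        if abs(t_amp) < t_min_amplitude_mv:
            warnings.warn("unidentifiable T wave: below amplitude floor", stacklevel=2)
        else:
            sign = np.sign(t_amp)
            down = sign * d[t_peak:t_hi]  # stay inside the T window
            if len(down) and down.min() < 0:
                s_idx = t_peak + int(down.argmin())
                slope = d[s_idx]  # mV/ms, steepest return to baseline
                t_end_ms = s_idx * 1000.0 / fs + (baseline - x[s_idx]) / slope
                qt_ms = t_end_ms - onset_idx * 1000.0 / fs
            else:
                warnings.warn("unidentifiable T wave: no downslope found", stacklevel=2)
    else:
        warnings.warn("unidentifiable T wave: search window beyond trace", stacklevel=2)

    return {
        "qrs_ms": float(qrs_ms),
        "qt_ms": float(qt_ms),
        "qrs_onset_ms": onset_idx * 1000.0 / fs,
        "qrs_offset_ms": offset_idx * 1000.0 / fs,
    }
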