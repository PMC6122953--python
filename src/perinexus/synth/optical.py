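"""Synthetic optical-mapping movies with an elliptically propagating wave.

The wave is kinematic (no ionic model): activation time at a pixel is the
elliptical travel time from the pacing site,

    t(p) = sqrt((u / CV_L)² + (v / CV_T)²),

with ``(u, v)`` the pixel offset rotated into the fast/slow frame. The
pixel trace is a stereotyped optical action potential — sigmoidal upstroke
centred at the activation time (so its maximum derivative marks activation
by construction), a plateau, and exponential repolarization — plus white
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

from perinexus.synth.truth import SceneTruth


@dataclass
class OpticalMovieConfig:
    """Configuration for :func:`gen_optical_movie`.

    Defaults emulate epicardial mapping at 1000 frames/s with guinea-pig
    ventricular conduction velocities (CV_L 50 cm/s, CV_T 20 cm/s).
    """

    grid: Tuple[int, int] = (100, 100)  # (ny, nx), emulating a 100×100 mapping camera
    cv_l_cm_s: float = 50.0
    cv_t_cm_s: float = 20.0
    fast_axis_deg: float = 30.0
    pixel_size_mm: float = 0.1
    frame_rate: float = 1000.0
    pacing_site: Optional[Tuple[int, int]] = None  # (row, col); default centre
    upstroke_tau_ms: float = 1.5
    plateau_ms: float = 30.0
    repol_tau_ms: float = 30.0
    amplitude: float = 1.0
    noise_sigma: float = 0.05  # fraction of amplitude
    baseline_pad_ms: float = 10.0
    duration_ms: Optional[float] = None  # default: auto from the wave

    def validate(self) -> None:
        if self.cv_l_cm_s <= 0 or self.cv_t_cm_s <= 0:
            raise ValueError("CV_L and CV_T must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be > 0")


def elliptical_activation_times(cfg: OpticalMovieConfig) -> np.ndarray:
    """Ground-truth activation time (ms, excluding baseline pad) per pixel."""
    ny, nx = cfg.grid
    pr, pc = cfg.pacing_site if cfg.pacing_site is not None else (ny // 2, nx // 2)
    rows, cols = np.indices((ny, nx))
    dx = (cols - pc) * cfg.pixel_size_mm
    dy = (rows - pr) * cfg.pixel_size_mm
    alpha = np.deg2rad(cfg.fast_axis_deg)
    u = dx * np.cos(alpha) + dy * np.sin(alpha)
    v = -dx * np.sin(alpha) + dy * np.cos(alpha)
    vl = cfg.cv_l_cm_s / 100.0  # mm/ms
    vt = cfg.cv_t_cm_s / 100.0
    return np.sqrt((u / vl) ** 2 + (v / vt) ** 2)


def ap_template(t_ms: np.ndarray, t_act_ms: float, cfg: OpticalMovieConfig) -> np.ndarray:
    """Stereotyped optical AP: sigmoid upstroke, plateau, exponential decay."""
    dt = t_ms - t_act_ms
    upstroke = 1.0 / (1.0 + np.exp(-dt / cfg.upstroke_tau_ms))
    repol = np.where(
        dt <= cfg.plateau_ms, 1.0, np.exp(-(np.maximum(dt - cfg.plateau_ms, 0.0)) / cfg.repol_tau_ms)
    )
    return cfg.amplitude * upstroke * repol


def gen_optical_movie(config: OpticalMovieConfig | None = None, seed: int = 0):
    """Generate a synthetic optical-mapping movie.

    Returns ``(movie, truth)`` where ``movie`` is a float array of shape
    ``(n_frames, ny, nx)`` and ``truth`` stores the planted CV_L/CV_T,
    fast-axis angle, pacing site, frame rate and the exact per-pixel
    activation times (in absolute movie ms, baseline pad included).

    Raises
    ------
    ValueError
        If an explicit ``duration_ms`` ends the movie before any pixel
        activates (the wave exits the grid unseen).
    """
    cfg = config or OpticalMovieConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    ny, nx = cfg.grid
    pacing = cfg.pacing_site if cfg.pacing_site is not None else (ny // 2, nx // 2)
    t_act = elliptical_activation_times(cfg) + cfg.baseline_pad_ms

    if cfg.duration_ms is None:
        duration = float(t_act.max() + cfg.plateau_ms + 5.0 * cfg.repol_tau_ms)
    else:
        duration = float(cfg.duration_ms)
        if duration < float(t_act.min()) + 2.0 * cfg.upstroke_tau_ms:
            raise ValueError(
                "movie ends before any pixel activates: increase duration_ms"
            )

    frame_dt = 1000.0 / cfg.frame_rate
    times = np.arange(0.0, duration + frame_dt / 2, frame_dt)
    movie = cfg.amplitude / (
        1.0 + np.exp(-(times[:, None, None] - t_act[None]) / cfg.upstroke_tau_ms)
    )
    dt = times[:, None, None] - t_act[None]
    repol = np.where(
        dt <= cfg.plateau_ms,
        1.0,
        np.exp(-np.maximum(dt - cfg.plateau_ms, 0.0) / cfg.repol_tau_ms),
    )
    movie = movie * repol
    if cfg.noise_sigma > 0:
        movie = movie + rng.normal(0.0, cfg.noise_sigma * cfg.amplitude, size=movie.shape)

    truth = SceneTruth(
        modality="optical",
        seed=seed,
        params=asdict(cfg),
        records={
            "cv_l_cm_s": cfg.cv_l_cm_s,
            "cv_t_cm_s": cfg.cv_t_cm_s,
            "anisotropy_ratio": cfg.cv_l_cm_s / cfg.cv_t_cm_s,
            "fast_axis_deg": cfg.fast_axis_deg % 180.0,
            "pacing_site": list(pacing),
            "frame_rate": cfg.frame_rate,
            "pixel_size_mm": cfg.pixel_size_mm,
            "activation_ms": t_act.tolist(),
            "n_frames": len(times),
        },
    )
    return movie, truth
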