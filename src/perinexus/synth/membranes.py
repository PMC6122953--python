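"""Synthetic paired membrane traces emulating digitized TEM polylines.

Trace A is a gently curved polyline with the gap-junction edge anchored at
arc length 0; trace B is offset from A along the local normal by a
configurable separation function d(s) > 0, emulating two apposed membranes
that diverge (or stay parallel) away from the plaque edge. Optional jitter
emulates hand-tracing noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence, Union

import numpy as np

from perinexus.ultrastructure import MembraneTracePair
from perinexus.synth.truth import SceneTruth

Separation = Union[float, Sequence[float], Callable[[np.ndarray], np.ndarray]]


@dataclass
class MembraneTraceConfig:
    """Configuration for :func:`gen_membrane_traces`.

    Defaults give a 400 nm trace sampled every 2 nm with a constant 20 nm
    separation — a typical perinexal membrane pair at its resting width.
    """

    length_nm: float = 400.0
    sampling_step_nm: float = 2.0
    separation_nm: Separation = 20.0
    #: sinusoidal deflection of trace A (amplitude, wavelength), nm
    curvature_amplitude_nm: float = 0.0
    curvature_wavelength_nm: float = 200.0
    jitter_sigma_nm: float = 0.0
    calibration_nm_per_px: float = 1.0
    heart: str = ""
    condition: str = ""


def _evaluate_separation(sep: Separation, s: np.ndarray) -> np.ndarray:
    if callable(sep):
        d = np.asarray(sep(s), dtype=float)
    else:
        arr = np.atleast_1d(np.asarray(sep, dtype=float))
        d = np.full_like(s, float(arr[0])) if arr.size == 1 else arr
    if d.shape != s.shape:
        raise ValueError("separation array must match the sampling grid")
    return d


def gen_membrane_traces(config: MembraneTraceConfig | None = None, seed: int = 0):
    """Generate a membrane trace pair; returns ``(MembraneTracePair, SceneTruth)``.

    Raises
    ------
    ValueError
        If d(s) is not strictly positive, or the requested curvature makes
        the offset trace self-intersect (separation exceeding the radius of
        curvature).
    """
    cfg = config or MembraneTraceConfig()
    if cfg.length_nm <= 0 or cfg.sampling_step_nm <= 0:
        raise ValueError("length and sampling step must be > 0")
    rng = np.random.default_rng(seed)

    s = np.arange(0.0, cfg.length_nm + cfg.sampling_step_nm / 2, cfg.sampling_step_nm)
    d = _evaluate_separation(cfg.separation_nm, s)
    if (d <= 0).any():
        raise ValueError("separation d(s) must be > 0 everywhere")

    amp, lam = cfg.curvature_amplitude_nm, cfg.curvature_wavelength_nm
    if amp > 0:
        # max curvature of A·sin(2πs/λ) is A(2π/λ)²; the parallel offset
        # curve self-intersects when d exceeds the radius of curvature
        min_radius = 1.0 / (amp * (2 * np.pi / lam) ** 2)
        if d.max() >= min_radius:
            raise ValueError(
                "self-intersecting trace requested: separation "
                f"{d.max():.1f} nm exceeds the minimum radius of curvature "
                f"{min_radius:.1f} nm"
            )
        y = amp * np.sin(2 * np.pi * s / lam)
        dy = amp * (2 * np.pi / lam) * np.cos(2 * np.pi * s / lam)
    else:
        y = np.zeros_like(s)
        dy = np.zeros_like(s)

    a = np.column_stack([s, y])
    tangent = np.column_stack([np.ones_like(s), dy])
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    b = a + d[:, None] * normal

    if cfg.jitter_sigma_nm > 0:
        # tracing noise acts across the membrane: jitter along the local
        # normal only, so the digitized polylines stay simple (no crossings
        # from reordered vertices along the trace)
        a = a + normal * rng.normal(0.0, cfg.jitter_sigma_nm, size=len(s))[:, None]
        b = b + normal * rng.normal(0.0, cfg.jitter_sigma_nm, size=len(s))[:, None]

    pair = MembraneTracePair(
        polyline_a=a,
        polyline_b=b,
        calibration_nm_per_px=cfg.calibration_nm_per_px,
        heart=cfg.heart,
        condition=cfg.condition,
    )
    params = asdict(cfg)
    if callable(cfg.separation_nm):
        params["separation_nm"] = "see records.d_nm"
    truth = SceneTruth(
        modality="membranes",
        seed=seed,
        params=params,
        records={"s_nm": s.tolist(), "d_nm": d.tolist()},
    )
    return pair, truth
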