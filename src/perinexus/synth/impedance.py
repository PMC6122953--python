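"""Synthetic ECIS impedance series with a known junctional resistance.

The circuit form is a simple additive model chosen so the band-average
analysis is exactly invertible on noiseless data:

    Re Z(f, t) = R_electrode(f) + R_junction(t) · g(f)
    Im Z(f, t) = −1 / (2π f C)

with ``g(f) = 1`` on the 62.5–4000 Hz junctional band by construction and
rolling off as ``(4000/f)`` above it, mimicking the shunting of junctional
resistance by membrane capacitance at high frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Callable, Sequence, Tuple, Union

import numpy as np

from perinexus.ecis import ImpedanceSeries
from perinexus.synth.truth import SceneTruth

#: default ECIS frequency sweep (Hz), doubling steps 62.5 .. 64000
DEFAULT_FREQUENCIES_HZ = tuple(62.5 * 2**k for k in range(11))

RTrajectory = Union[float, Sequence[float], Callable[[np.ndarray], np.ndarray]]


@dataclass
class EcisConfig:
    """Configuration for :func:`gen_ecis_series`.

    Defaults emulate a 3 h run sampled every 90 s (121 time points) with a
    constant 500 Ω junctional resistance.
    """

    r_junction_ohm: RTrajectory = 500.0
    duration_s: float = 3 * 3600.0
    sample_interval_s: float = 90.0
    frequencies_hz: Tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    r_electrode_ohm: RTrajectory = 0.0  # evaluated over frequency, not time
    junction_band_hz: Tuple[float, float] = (62.5, 4000.0)
    capacitance_f: float = 1e-8
    noise_sigma_ohm: float = 0.0
    well: str = "W1"
    condition: str = ""


def _evaluate(traj: RTrajectory, grid: np.ndarray, what: str) -> np.ndarray:
    if callable(traj):
        return np.asarray(traj(grid), dtype=float)
    arr = np.atleast_1d(np.asarray(traj, dtype=float))
    if arr.size == 1:
        return np.full_like(grid, float(arr[0]), dtype=float)
    if arr.size != grid.size:
        raise ValueError(f"{what} trajectory length {arr.size} != grid length {grid.size}")
    return arr


def gen_ecis_series(config: EcisConfig | None = None, seed: int = 0):
    """Generate an impedance series; returns ``(ImpedanceSeries, SceneTruth)``."""
    cfg = config or EcisConfig()
    if len(cfg.frequencies_hz) == 0:
        raise ValueError("frequency list must be non-empty")
    rng = np.random.default_rng(seed)

    times = np.arange(0.0, cfg.duration_s + cfg.sample_interval_s / 2, cfg.sample_interval_s)
    freqs = np.asarray(sorted(cfg.frequencies_hz), dtype=float)

    r_j = _evaluate(cfg.r_junction_ohm, times, "R_junction")
    r_el = _evaluate(cfg.r_electrode_ohm, freqs, "R_electrode")

    hi = cfg.junction_band_hz[1]
    g = np.where(freqs <= hi, 1.0, hi / freqs)

    re_z = r_el[:, None] + r_j[None, :] * g[:, None]
    im_z = np.broadcast_to(-1.0 / (2 * np.pi * freqs * cfg.capacitance_f)[:, None], re_z.shape).copy()
    if cfg.noise_sigma_ohm > 0:
        re_z = re_z + rng.normal(0.0, cfg.noise_sigma_ohm, size=re_z.shape)
        im_z = im_z + rng.normal(0.0, cfg.noise_sigma_ohm, size=im_z.shape)

    series = ImpedanceSeries(
        time_s=times,
        frequency_hz=freqs,
        z_ohm=re_z + 1j * im_z,
        well=cfg.well,
        condition=cfg.condition,
    )
    params = asdict(cfg)
    # callables are not JSON-serializable; record their evaluation instead
    params["r_junction_ohm"] = "see records.r_junction_ohm"
    params["r_electrode_ohm"] = r_el.tolist()
    truth = SceneTruth(
        modality="ecis",
        seed=seed,
        params=params,
        records={
            "time_s": times.tolist(),
            "r_junction_ohm": r_j.tolist(),
            "r_electrode_ohm": r_el.tolist(),
            "band_hz": list(cfg.junction_band_hz),
            "n_in_band_freq": int(((freqs >= cfg.junction_band_hz[0]) & (freqs <= hi)).sum()),
        },
    )
    return series, truth
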