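"""Junctional-resistance analysis of ECIS impedance series.

Electric cell-substrate impedance sensing measures the complex impedance
of a cell monolayer over a frequency sweep. At low frequencies current is
forced through the paracellular route, so the real impedance averaged over
the 62.5–4000 Hz band reflects intercellular junctional resistance. The
operations here are deliberately simple band statistics — no
equivalent-circuit inversion — matching how the assay is quantified in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ImpedanceSeries",
    "ResistanceTrace",
    "resistance_trace",
    "normalize_to_baseline",
    "attachment_delta",
    "dose_response_table",
]

DEFAULT_BAND_HZ = (62.5, 4000.0)


@dataclass
class ImpedanceSeries:
    """Complex impedance Z(f, t) for one well/condition.

    ``z_ohm`` has shape ``(n_freq, n_time)``; frequencies must be strictly
    increasing.
    """

    time_s: np.ndarray
    frequency_hz: np.ndarray
    z_ohm: np.ndarray
    well: str = ""
    condition: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.z_ohm = np.asarray(self.z_ohm, dtype=complex)
        if len(self.frequency_hz) == 0:
            raise ValueError("frequency list must be non-empty")
        if not (np.diff(self.frequency_hz) > 0).all():
            raise ValueError("frequencies must be strictly increasing")
        if self.z_ohm.shape != (len(self.frequency_hz), len(self.time_s)):
            raise ValueError("z_ohm must be (n_freq, n_time)")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, well: str = "", condition: str = ""):
        """Build from a long table with columns time_s, frequency_hz, re_ohm, im_ohm."""
        required = {"time_s", "frequency_hz", "re_ohm", "im_ohm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"impedance table missing columns: {sorted(missing)}")
        piv_re = df.pivot_table(index="frequency_hz", columns="time_s", values="re_ohm")
        piv_im = df.pivot_table(index="frequency_hz", columns="time_s", values="im_ohm")
        return cls(
            time_s=piv_re.columns.to_numpy(dtype=float),
            frequency_hz=piv_re.index.to_numpy(dtype=float),
            z_ohm=piv_re.to_numpy() + 1j * piv_im.to_numpy(),
            well=well,
            condition=condition,
        )

    def to_long_frame(self) -> pd.DataFrame:
        f, t = np.meshgrid(self.frequency_hz, self.time_s, indexing="ij")
        return pd.DataFrame(
            {
                "time_s": t.ravel(),
                "frequency_hz": f.ravel(),
                "re_ohm": self.z_ohm.real.ravel(),
                "im_ohm": self.z_ohm.imag.ravel(),
                "well": self.well,
                "condition": self.condition,
            }
        )


@dataclass
class ResistanceTrace:
    """Time-resolved junctional resistance (band-averaged real impedance)."""

    time_s: np.ndarray
    resistance_ohm: np.ndarray
    band_hz: Tuple[float, float] = DEFAULT_BAND_HZ
    baseline_mean_ohm: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        if not np.isfinite(self.resistance_ohm).all():
            raise ValueError("resistance values must be finite")


def resistance_trace(
    series: ImpedanceSeries, band_hz: Tuple[float, float] = DEFAULT_BAND_HZ
) -> ResistanceTrace:
    """Junctional resistance: mean over in-band frequencies of Re Z(f, t).

    In-band means ``band_hz[0] <= f <= band_hz[1]`` inclusive; the mean is
    unweighted over whatever frequencies the instrument provides in band.
    """
    lo, hi = band_hz
    mask = (series.frequency_hz >= lo) & (series.frequency_hz <= hi)
    if not mask.any():
        raise ValueError(
            f"no frequencies inside the [{lo}, {hi}] Hz band "
            f"(available: {series.frequency_hz.tolist()})"
        )
    r = series.z_ohm.real[mask].mean(axis=0)
    return ResistanceTrace(
        time_s=series.time_s, resistance_ohm=r, band_hz=(lo, hi), label=series.condition
    )


def normalize_to_baseline(
    trace: ResistanceTrace, baseline_window_s: Tuple[float, float]
) -> ResistanceTrace:
    """Divide a trace by its baseline-window mean (reported on the result)."""
    t0, t1 = baseline_window_s
    mask = (trace.time_s >= t0) & (trace.time_s <= t1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = float(trace.resistance_ohm[mask].mean())
    if base == 0.0:
        raise ValueError("baseline mean is zero; cannot normalize")
    return ResistanceTrace(
        time_s=trace.time_s,
        resistance_ohm=trace.resistance_ohm / base,
        band_hz=trace.band_hz,
        baseline_mean_ohm=base,
        label=trace.label,
    )


def attachment_delta(
    trace: ResistanceTrace, t0_s: float, t1_s: Optional[float] = None
) -> float:
    """Change in resistance R(t1) − R(t0), default over 24 h from t0.

    Times resolve to the nearest sample; both must lie within the trace span.
    """
    if t1_s is None:
        t1_s = t0_s + 24 * 3600.0
    span = (trace.time_s.min(), trace.time_s.max())
    for name, t in (("t0", t0_s), ("t1", t1_s)):
        if not span[0] - 1e-9 <= t <= span[1] + 1e-9:
            raise ValueError(f"{name}={t} s outside trace span {span}")
    i0 = int(np.abs(trace.time_s - t0_s).argmin())
    i1 = int(np.abs(trace.time_s - t1_s).argmin())
    return float(trace.resistance_ohm[i1] - trace.resistance_ohm[i0])


def dose_response_table(
    traces_per_dose: dict,
    endpoint: str = "final",
    baseline_window_s: Optional[Tuple[float, float]] = None,
    attachment_t0_s: float = 0.0,
    attachment_t1_s: Optional[float] = None,
) -> pd.DataFrame:
    """Per-dose endpoint summary (mean ± SE over replicate traces).

    ``traces_per_dose`` maps dose → list of :class:`ResistanceTrace`.
    ``endpoint`` is ``"final"`` (last resistance value, normalized first if
    a baseline window is given) or ``"attachment"`` (resistance change over
    the attachment window). Single-replicate doses report SE as NaN.
    """
    if len(traces_per_dose) < 2:
        raise ValueError("need >= 2 doses for a dose-response table")
    rows = []
    for dose, traces in sorted(traces_per_dose.items()):
        vals = []
        for tr in traces:
            if endpoint == "final":
                use = (
                    normalize_to_baseline(tr, baseline_window_s)
                    if baseline_window_s is not None
                    else tr
                )
                vals.append(float(use.resistance_ohm[-1]))
            elif endpoint == "attachment":
                vals.append(attachment_delta(tr, attachment_t0_s, attachment_t1_s))
            else:
                raise ValueError(f"unknown endpoint {endpoint!r}")
        vals = np.asarray(vals, dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(
            {"dose": dose, "effect_mean": float(vals.mean()), "effect_se": se, "n": len(vals)}
        )
    return pd.DataFrame(rows)
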