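"""Inter-membrane width profiling from digitized TEM membrane traces.

Input is a pair of manually traced membrane polylines (nm) with the
gap-junction (GJ) plaque edge anchored at arc length ``s = 0`` on trace A.
The width profile samples trace A at fixed arc-length steps and measures,
at each sample, the minimum Euclidean distance to polyline B
(point-to-segment, not normal projection — robust to local curvature).
Samples with ``0 < s ≤ zone_end`` (default 150 nm at 5 nm steps) form the
perinexal zone; later samples are non-junctional intercalated-disk
membrane. Summaries average hierarchically — profiles within a heart
first, then across hearts — because biological replication is at the level
of hearts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = [
    "MembraneTracePair",
    "WidthProfile",
    "width_profile",
    "summarize_widths",
    "profile_asymmetry",
]


@dataclass
class MembraneTracePair:
    """Paired membrane polylines in nm, GJ edge at arc length 0 on A."""

    polyline_a: np.ndarray  # (n, 2) nm, ordered, s=0 at first vertex
    polyline_b: np.ndarray
    calibration_nm_per_px: float = 1.0
    label: str = ""
    heart: str = ""
    condition: str = ""

    def __post_init__(self):
        self.polyline_a = np.asarray(self.polyline_a, dtype=float)
        self.polyline_b = np.asarray(self.polyline_b, dtype=float)
        for name, poly in (("A", self.polyline_a), ("B", self.polyline_b)):
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
                raise ValueError(f"polyline {name} must be (n >= 2, 2)")
            if not LineString(poly).is_simple:
                raise ValueError(f"polyline {name} is self-intersecting")
        if self.calibration_nm_per_px <= 0:
            raise ValueError("calibration must be > 0")


@dataclass
class WidthProfile:
    """Inter-membrane distance vs arc-length position from the GJ edge."""

    s_nm: np.ndarray
    d_nm: np.ndarray  # NaN where masked
    zone: np.ndarray  # "edge" | "perinexal" | "nonjunctional"
    zone_end_nm: float
    step_nm: float
    label: str = ""
    heart: str = ""
    condition: str = ""

    def __post_init__(self):
        self.s_nm = np.asarray(self.s_nm, dtype=float)
        self.d_nm = np.asarray(self.d_nm, dtype=float)
        if not (np.diff(self.s_nm) > 0).all():
            raise ValueError("sample positions must be strictly increasing")
        finite = self.d_nm[np.isfinite(self.d_nm)]
        if (finite < 0).any():
            raise ValueError("distances must be >= 0")

    def zone_values(self, zone: str) -> np.ndarray:
        vals = self.d_nm[self.zone == zone]
        return vals[np.isfinite(vals)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s_nm": self.s_nm, "d_nm": self.d_nm, "zone": self.zone}
        )


def _arclength_points(poly: np.ndarray, s: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


def width_profile(
    pair: MembraneTracePair,
    step_nm: float = 5.0,
    zone_end_nm: float = 150.0,
    max_s_nm: Optional[float] = None,
) -> WidthProfile:
    """Sample the inter-membrane distance along trace A.

    At each multiple of ``step_nm`` from the GJ edge the distance is the
    minimum point-to-polyline distance to trace B. Samples whose nearest
    point on B is one of B's endpoints are masked (B does not span opposite
    A there) with a warning.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    a_len = float(np.linalg.norm(np.diff(pair.polyline_a, axis=0), axis=1).sum())
    if a_len < zone_end_nm:
        raise ValueError(
            f"trace A ({a_len:.0f} nm) does not cover the perinexal zone "
            f"(0..{zone_end_nm:.0f} nm from the GJ edge)"
        )
    s_max = a_len if max_s_nm is None else min(max_s_nm, a_len)
    s = np.arange(0.0, s_max + step_nm / 2, step_nm)
    s = s[s <= a_len + 1e-9]
    samples = _arclength_points(pair.polyline_a, s)

    line_b = LineString(pair.polyline_b)
    d = np.empty(len(s))
    masked = 0
    for i, p in enumerate(samples):
        pt = Point(p)
        proj = line_b.project(pt)
        if proj <= 1e-9 or proj >= line_b.length - 1e-9:
            d[i] = np.nan
            masked += 1
        else:
            d[i] = line_b.distance(pt)
    if masked:
        warnings.warn(
            f"{masked} samples masked: trace B does not span opposite trace A there",
            stacklevel=2,
        )

    zone = np.where(s <= 0, "edge", np.where(s <= zone_end_nm, "perinexal", "nonjunctional"))
    return WidthProfile(
        s_nm=s,
        d_nm=d,
        zone=zone,
        zone_end_nm=zone_end_nm,
        step_nm=step_nm,
        label=pair.label,
        heart=pair.heart,
        condition=pair.condition,
    )


def summarize_widths(profiles, zone: str = "perinexal") -> dict:
    """Hierarchical mean ± SE of zone widths for one condition.

    ``profiles`` is either a flat list of :class:`WidthProfile` (grouped by
    their ``heart`` attribute; profiles with no heart label pool into one
    group) or a mapping ``heart -> list of profiles``. Profiles are pooled
    to per-heart means first; the condition mean and standard error are
    computed across hearts (n = hearts). SE is NaN for a single heart.
    """
    if isinstance(profiles, dict):
        by_heart = profiles
    else:
        by_heart: Dict[str, List[WidthProfile]] = {}
        for p in profiles:
            by_heart.setdefault(p.heart or "pooled", []).append(p)

    heart_means = {}
    for heart, plist in by_heart.items():
        vals = np.concatenate([p.zone_values(zone) for p in plist]) if plist else np.array([])
        if vals.size == 0:
            raise ValueError(f"zone {zone!r} empty for heart {heart!r}")
        heart_means[heart] = float(vals.mean())
    if not heart_means:
        raise ValueError("no profiles supplied")

    means = np.array(list(heart_means.values()))
    se = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else np.nan
    return {
        "mean_nm": float(means.mean()),
        "se_nm": se,
        "n_hearts": len(means),
        "per_heart_mean_nm": heart_means,
        "zone": zone,
    }


def profile_asymmetry(pair: MembraneTracePair, step_nm: float = 5.0) -> float:
    """QC metric: mean |d(A→B) − d(B→A)| over matched arc positions.

    For smooth, near-parallel traces this should be small; large values
    indicate strongly curved or diverging traces where the one-sided
    distance convention matters.
    """
    line_a = LineString(pair.polyline_a)
    line_b = LineString(pair.polyline_b)
    n = max(int(min(line_a.length, line_b.length) // step_nm), 2)
    s = np.linspace(0.0, 1.0, n)
    d_ab = np.array(
        [line_b.distance(line_a.interpolate(f, normalized=True)) for f in s]
    )
    d_ba = np.array(
        [line_a.distance(line_b.interpolate(f, normalized=True)) for f in s]
    )
    return float(np.abs(d_ab - d_ba).mean())
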