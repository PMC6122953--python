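"""Conduction analysis of optical-mapping movies.

From a voltage-sensitive-dye movie this module extracts per-pixel
activation times (time of the maximum first derivative of the optical
action potential, with sub-frame parabolic refinement), fits activation
surfaces, derives a velocity vector field, and summarizes longitudinal and
transverse conduction velocities (CV_L, CV_T) and their ratio, the
anisotropy ratio (AR), by wedge-averaging speeds within ±15° of the fast
and slow propagation axes.

Velocity estimation follows the gradient method: if ``T(x, y)`` is the
activation surface then ``v = ∇T / |∇T|²`` points along propagation with
speed ``1/|∇T|``. Two surface modes are provided: a single global parabolic
surface ``T = ax² + by² + cxy + dx + ey + f`` (exact for planar and
quadratic maps), and the default local mode that fits the same quadratic in
a sliding window around every pixel — necessary because the activation
surface of a focally paced wave is conical, which a single global quadratic
cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

__all__ = [
    "ActivationMap",
    "ParabolicSurface",
    "VelocityField",
    "CVSummary",
    "ActivationMapper",
    "ConductionVelocityEstimator",
    "compute_activation_map",
    "fit_parabolic_surface",
    "velocity_field",
    "cv_summary",
    "apd",
    "activation_delay",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ActivationMap:
    """Per-pixel activation times in ms with a validity mask."""

    times_ms: np.ndarray  # (ny, nx)
    valid: np.ndarray  # bool (ny, nx)
    pixel_size_mm: float
    frame_rate: float
    pacing_pixel: Tuple[int, int]  # (row, col) of earliest valid activation

    def __post_init__(self):
        t = self.times_ms[self.valid]
        if t.size and (not np.isfinite(t).all() or (t < 0).any()):
            raise ValueError("valid activation times must be finite and >= 0")


@dataclass
class ParabolicSurface:
    """Global quadratic activation surface T(x,y) = ax²+by²+cxy+dx+ey+f."""

    coefficients: np.ndarray  # (a, b, c, d, e, f), x/y in mm, T in ms
    rms_ms: float

    def __post_init__(self):
        if self.rms_ms < 0:
            raise ValueError("fit RMS must be >= 0")

    def gradient(self, x_mm: np.ndarray, y_mm: np.ndarray):
        a, b, c, d, e, _ = self.coefficients
        return 2 * a * x_mm + c * y_mm + d, 2 * b * y_mm + c * x_mm + e

    def evaluate(self, x_mm, y_mm):
        a, b, c, d, e, f = self.coefficients
        return a * x_mm**2 + b * y_mm**2 + c * x_mm * y_mm + d * x_mm + e * y_mm + f


@dataclass
class VelocityField:
    """Per-pixel conduction velocity vectors in cm/s."""

    vx_cm_s: np.ndarray
    vy_cm_s: np.ndarray
    valid: np.ndarray

    @property
    def speed_cm_s(self) -> np.ndarray:
        return np.hypot(self.vx_cm_s, self.vy_cm_s)

    @property
    def angle_deg(self) -> np.ndarray:
        """Propagation direction folded onto [0, 180) (axis, not direction)."""
        return np.degrees(np.arctan2(self.vy_cm_s, self.vx_cm_s)) % 180.0


@dataclass
class CVSummary:
    """Wedge-averaged conduction velocities and anisotropy ratio."""

    cv_l_cm_s: float
    cv_t_cm_s: float
    fast_axis_deg: float
    wedge_half_angle_deg: float = 15.0

    def __post_init__(self):
        if self.cv_l_cm_s < self.cv_t_cm_s:
            raise ValueError("CV_L must be >= CV_T by the fast-axis definition")

    @property
    def anisotropy_ratio(self) -> float:
        return self.cv_l_cm_s / self.cv_t_cm_s


# ---------------------------------------------------------------------------
# activation mapping
# ---------------------------------------------------------------------------


class ActivationMapper(BaseEstimator):
    """Per-pixel activation detection by maximum upstroke derivative.

    Each pixel trace is smoothed with a moving average of ``smooth_window``
    frames, differentiated, and the derivative peak located; the peak time
    is refined to sub-frame precision by a parabolic fit through the three
    samples around the maximum. Pixels whose derivative peak does not exceed
    ``snr_min`` times a robust (median-absolute-deviation) noise estimate of
    the derivative are masked invalid.
    """

    def __init__(
        self,
        frame_rate: float = 1000.0,
        pixel_size_mm: float = 0.1,
        smooth_window: int = 5,
        snr_min: float = 5.0,
    ):
        self.frame_rate = frame_rate
        self.pixel_size_mm = pixel_size_mm
        self.smooth_window = smooth_window
        self.snr_min = snr_min

    def fit(self, movie: np.ndarray, y=None):
        movie = np.asarray(movie, dtype=float)
        if movie.ndim != 3 or movie.shape[0] < 3:
            raise ValueError("movie must be (n_frames >= 3, ny, nx)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

        sm = movie
        if self.smooth_window > 1:
            sm = ndimage.uniform_filter1d(movie, size=self.smooth_window, axis=0, mode="nearest")
        deriv = np.gradient(sm, axis=0)

        peak_idx = deriv.argmax(axis=0)
        nt = deriv.shape[0]
        rows, cols = np.indices(peak_idx.shape)
        peak_val = deriv[peak_idx, rows, cols]

        med = np.median(deriv, axis=0)
        mad = np.median(np.abs(deriv - med), axis=0)
        noise = 1.4826 * mad
        valid = peak_val > np.maximum(self.snr_min * noise, 1e-12)

        # parabolic sub-frame refinement around the derivative peak
        i = np.clip(peak_idx, 1, nt - 2)
        d0 = deriv[i - 1, rows, cols]
        d1 = deriv[i, rows, cols]
        d2 = deriv[i + 1, rows, cols]
        denom = d0 - 2 * d1 + d2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (d0 - d2) / denom
        delta = np.where(np.isfinite(delta), np.clip(delta, -0.5, 0.5), 0.0)
        delta = np.where(peak_idx == i, delta, 0.0)  # no refinement at trace edges

        times = (peak_idx + delta) * 1000.0 / self.frame_rate
        if not valid.any():
            raise ValueError("no activations detected: every pixel failed the SNR gate")
        times = np.where(valid, times, np.nan)

        masked = np.where(valid, times, np.inf)
        pace = np.unravel_index(np.argmin(masked), masked.shape)
        self.map_ = ActivationMap(
            times_ms=times,
            valid=valid,
            pixel_size_mm=self.pixel_size_mm,
            frame_rate=self.frame_rate,
            pacing_pixel=(int(pace[0]), int(pace[1])),
        )
        return self


def compute_activation_map(
    movie: np.ndarray,
    frame_rate: float,
    pixel_size_mm: float = 0.1,
    smooth_window: int = 5,
    snr_min: float = 5.0,
) -> ActivationMap:
    """Activation times as the per-pixel maximum of the first derivative."""
    mapper = ActivationMapper(
        frame_rate=frame_rate,
        pixel_size_mm=pixel_size_mm,
        smooth_window=smooth_window,
        snr_min=snr_min,
    ).fit(movie)
    return mapper.map_


# ---------------------------------------------------------------------------
# surface fitting and velocity field
# ---------------------------------------------------------------------------


def _pixel_coords_mm(amap: ActivationMap):
    ny, nx = amap.times_ms.shape
    x = (np.arange(nx) + 0.5) * amap.pixel_size_mm
    y = (np.arange(ny) + 0.5) * amap.pixel_size_mm
    return np.meshgrid(x, y)


def fit_parabolic_surface(amap: ActivationMap) -> ParabolicSurface:
    """Ordinary least-squares fit of a single quadratic to the valid pixels."""
    xx, yy = _pixel_coords_mm(amap)
    m = amap.valid & np.isfinite(amap.times_ms)
    if m.sum() < 6:
        raise ValueError("need >= 6 valid pixels to fit a parabolic surface")
    x, y, t = xx[m], yy[m], amap.times_ms[m]
    design = np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])
    coeffs, _, rank, _ = np.linalg.lstsq(design, t, rcond=None)
    if rank < 6:
        raise ValueError(
            "rank-deficient activation surface fit: valid pixels are "
            "degenerate (e.g. collinear); a unique quadratic does not exist"
        )
    rms = float(np.sqrt(np.mean((design @ coeffs - t) ** 2)))
    return ParabolicSurface(coefficients=coeffs, rms_ms=rms)


def _local_gradient_kernels(halfwidth: int, pixel_size_mm: float):
    """Correlation kernels giving the x/y gradient of a local quadratic fit."""
    offs = np.arange(-halfwidth, halfwidth + 1) * pixel_size_mm
    ox, oy = np.meshgrid(offs, offs)
    x, y = ox.ravel(), oy.ravel()
    design = np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])
    pinv = np.linalg.pinv(design)
    w = 2 * halfwidth + 1
    return pinv[3].reshape(w, w), pinv[4].reshape(w, w)


def velocity_field(
    amap: ActivationMap,
    surface: Optional[ParabolicSurface] = None,
    mode: str = "local",
    window_halfwidth: int = 4,
    pacing_exclusion_px: float = 8.0,
    grad_floor_ms_per_mm: float = 1e-3,
    radial_mask: bool = True,
) -> VelocityField:
    """Per-pixel conduction velocity vectors from the activation surface.

    ``mode="local"`` (default) fits a quadratic patch in a sliding
    ``(2·halfwidth+1)²`` window around every pixel and evaluates its
    gradient at the window centre; ``mode="global"`` differentiates the
    supplied (or freshly fitted) single :class:`ParabolicSurface`. Pixels
    within ``pacing_exclusion_px`` of the pacing site, pixels whose local
    window contains invalid neighbours, and pixels with near-zero gradient
    (the singularity at the pacing site) are masked.

    ``radial_mask`` additionally restricts vectors to the largest circle
    around the pacing site inscribed in the field, so directional
    statistics (the wedge scan in :func:`cv_summary`) sample every
    propagation direction with equal area; without it the corners of a
    rectangular field bias the fast-axis estimate toward the diagonals.
    """
    xx, yy = _pixel_coords_mm(amap)
    valid = amap.valid & np.isfinite(amap.times_ms)

    if mode == "global":
        if surface is None:
            surface = fit_parabolic_surface(amap)
        gx, gy = surface.gradient(xx, yy)
        ok = valid
    elif mode == "local":
        kx, ky = _local_gradient_kernels(window_halfwidth, amap.pixel_size_mm)
        t = np.where(valid, amap.times_ms, 0.0)
        gx = ndimage.correlate(t, kx, mode="constant")
        gy = ndimage.correlate(t, ky, mode="constant")
        w = 2 * window_halfwidth + 1
        full = ndimage.uniform_filter(valid.astype(float), size=w, mode="constant")
        ok = valid & (full > 1.0 - 1e-9)
        ok[:window_halfwidth, :] = False
        ok[-window_halfwidth:, :] = False
        ok[:, :window_halfwidth] = False
        ok[:, -window_halfwidth:] = False
    else:
        raise ValueError(f"unknown velocity mode {mode!r}")

    pr, pc = amap.pacing_pixel
    ny, nx = amap.times_ms.shape
    rows, cols = np.indices(amap.times_ms.shape)
    r = np.hypot(rows - pr, cols - pc)
    ok = ok & (r > pacing_exclusion_px)
    if radial_mask:
        rmax = min(pr, pc, ny - 1 - pr, nx - 1 - pc) - (
            window_halfwidth if mode == "local" else 0
        )
        if rmax > pacing_exclusion_px:
            ok = ok & (r <= rmax)

    g2 = gx**2 + gy**2
    ok = ok & (np.sqrt(g2) > grad_floor_ms_per_mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = np.where(ok, gx / g2, 0.0) * 100.0  # mm/ms -> cm/s
        vy = np.where(ok, gy / g2, 0.0) * 100.0
    return VelocityField(vx_cm_s=vx, vy_cm_s=vy, valid=ok)


def _fit_conduction_ellipse_axis(vx: np.ndarray, vy: np.ndarray) -> Optional[float]:
    """Fast-axis angle from the conduction-ellipse fit, or None if degenerate.

    For an elliptically spreading wave the time gradients ``g = v/|v|²``
    satisfy ``gᵀ S g = 1`` exactly, where S shares eigenvectors with the
    velocity ellipse and its larger eigenvalue belongs to the fast axis.
    Fitting S by least squares over all vectors pools the whole field into
    one axis estimate, far steadier than locating the maximum of a flat
    wedge-mean curve.
    """
    v2 = vx**2 + vy**2
    gx, gy = vx / v2, vy / v2
    design = np.column_stack([gx**2, gy**2, 2 * gx * gy])
    coeffs, _, rank, _ = np.linalg.lstsq(design, np.ones(len(gx)), rcond=None)
    if rank < 3:
        return None
    s = np.array([[coeffs[0], coeffs[2]], [coeffs[2], coeffs[1]]])
    evals, evecs = np.linalg.eigh(s)
    if not np.isfinite(evals).all() or evals[0] <= 0:
        return None
    fast = evecs[:, int(np.argmax(evals))]
    return float(np.degrees(np.arctan2(fast[1], fast[0])) % 180.0)


def cv_summary(
    field: VelocityField,
    wedge_half_angle_deg: float = 15.0,
    angle_step_deg: float = 1.0,
    min_vectors: int = 10,
    axis_method: str = "ellipse",
) -> CVSummary:
    """CV_L, CV_T and anisotropy ratio by wedge averaging.

    CV_L is the mean speed of velocity vectors pointing within
    ±``wedge_half_angle_deg`` of the fast axis; CV_T the mean within the
    perpendicular wedge. The fast axis is identified either by fitting the
    conduction ellipse to the time gradients (``axis_method="ellipse"``,
    default; falls back to the scan when the fit is degenerate, e.g. a
    planar wave) or by a dense angular scan for the direction maximizing
    the wedge-mean speed (``axis_method="scan"``, ``angle_step_deg``
    increments). If the perpendicular wedge turns out faster the axes are
    swapped, so CV_L ≥ CV_T always holds.
    """
    speeds = field.speed_cm_s[field.valid]
    angles = field.angle_deg[field.valid]
    if speeds.size == 0:
        raise ValueError("empty velocity field")

    def wedge_stats(phi: float):
        diff = np.abs(angles - phi)
        diff = np.minimum(diff, 180.0 - diff)
        sel = diff <= wedge_half_angle_deg
        n = int(sel.sum())
        return (float(speeds[sel].mean()) if n else -np.inf), n

    fast_angle = None
    if axis_method == "ellipse":
        fast_angle = _fit_conduction_ellipse_axis(
            field.vx_cm_s[field.valid], field.vy_cm_s[field.valid]
        )
    elif axis_method != "scan":
        raise ValueError(f"unknown axis_method {axis_method!r}")
    if fast_angle is None:
        phis = np.arange(0.0, 180.0, angle_step_deg)
        means = np.array([wedge_stats(p)[0] for p in phis])
        fast_angle = float(phis[int(np.argmax(means))])

    cv_l, n_fast = wedge_stats(fast_angle)
    cv_t, n_slow = wedge_stats((fast_angle + 90.0) % 180.0)
    if cv_t > cv_l:  # near-isotropic fields: keep the fast-axis convention
        cv_l, cv_t = cv_t, cv_l
        n_fast, n_slow = n_slow, n_fast
        fast_angle = (fast_angle + 90.0) % 180.0
    if n_fast < min_vectors or n_slow < min_vectors:
        raise ValueError(
            f"too few vectors in the fast/slow wedges "
            f"({n_fast}/{n_slow} < {min_vectors})"
        )
    return CVSummary(
        cv_l_cm_s=cv_l,
        cv_t_cm_s=cv_t,
        fast_axis_deg=fast_angle,
        wedge_half_angle_deg=wedge_half_angle_deg,
    )


class ConductionVelocityEstimator(BaseEstimator):
    """End-to-end CV extraction: movie → activation map → wedge CV summary.

    Fitted attributes: ``activation_map_``, ``velocity_field_``,
    ``cv_l_cm_s_``, ``cv_t_cm_s_``, ``anisotropy_ratio_``,
    ``fast_axis_deg_``, ``summary_``.
    """

    def __init__(
        self,
        frame_rate: float = 1000.0,
        pixel_size_mm: float = 0.1,
        smooth_window: int = 5,
        snr_min: float = 5.0,
        mode: str = "local",
        window_halfwidth: int = 4,
        pacing_exclusion_px: float = 8.0,
        wedge_half_angle_deg: float = 15.0,
        min_vectors: int = 10,
    ):
        self.frame_rate = frame_rate
        self.pixel_size_mm = pixel_size_mm
        self.smooth_window = smooth_window
        self.snr_min = snr_min
        self.mode = mode
        self.window_halfwidth = window_halfwidth
        self.pacing_exclusion_px = pacing_exclusion_px
        self.wedge_half_angle_deg = wedge_half_angle_deg
        self.min_vectors = min_vectors

    def fit(self, movie: np.ndarray, y=None):
        amap = compute_activation_map(
            movie,
            frame_rate=self.frame_rate,
            pixel_size_mm=self.pixel_size_mm,
            smooth_window=self.smooth_window,
            snr_min=self.snr_min,
        )
        field = velocity_field(
            amap,
            mode=self.mode,
            window_halfwidth=self.window_halfwidth,
            pacing_exclusion_px=self.pacing_exclusion_px,
        )
        summary = cv_summary(
            field,
            wedge_half_angle_deg=self.wedge_half_angle_deg,
            min_vectors=self.min_vectors,
        )
        self.activation_map_ = amap
        self.velocity_field_ = field
        self.summary_ = summary
        self.cv_l_cm_s_ = summary.cv_l_cm_s
        self.cv_t_cm_s_ = summary.cv_t_cm_s
        self.anisotropy_ratio_ = summary.anisotropy_ratio
        self.fast_axis_deg_ = summary.fast_axis_deg
        return self


# ---------------------------------------------------------------------------
# single-trace measures
# ---------------------------------------------------------------------------


def apd(
    trace: np.ndarray,
    frame_rate: float,
    repolarization_level: float = 0.8,
    on_zero_level: str = "error",
) -> float:
    """Action-potential duration (ms) at a repolarization level.

    Duration runs from the activation time (maximum derivative) to the
    first crossing of ``peak − level·amplitude`` after the peak, linearly
    interpolated between frames. ``repolarization_level`` 0.8 measures
    APD80. A level of 0 raises by default; set ``on_zero_level="full"`` to
    return the full span from activation to the last frame instead.
    """
    trace = np.asarray(trace, dtype=float)
    dt_ms = 1000.0 / frame_rate
    if repolarization_level <= 0.0:
        if on_zero_level == "full":
            deriv = np.gradient(trace)
            return float((len(trace) - 1 - deriv.argmax()) * dt_ms)
        raise ValueError("repolarization_level must be in (0, 1)")
    if not 0 < repolarization_level < 1:
        raise ValueError("repolarization_level must be in (0, 1)")

    deriv = np.gradient(trace)
    act_idx = int(deriv.argmax())
    peak_idx = act_idx + int(trace[act_idx:].argmax())
    peak = trace[peak_idx]
    baseline = float(trace[: act_idx + 1].min()) if act_idx > 0 else float(trace.min())
    threshold = peak - repolarization_level * (peak - baseline)

    after = trace[peak_idx:]
    below = np.flatnonzero(after <= threshold)
    if below.size == 0:
        raise ValueError("no repolarization crossing within the trace")
    j = int(below[0])
    if j == 0:
        cross = float(peak_idx)
    else:
        v0, v1 = after[j - 1], after[j]
        frac = (v0 - threshold) / (v0 - v1) if v0 != v1 else 0.0
        cross = peak_idx + j - 1 + frac
    return float((cross - act_idx) * dt_ms)


def activation_delay(amap: ActivationMap, site_a: Tuple[int, int], site_b: Tuple[int, int]) -> float:
    """Activation-time difference T(site_b) − T(site_a) in ms."""
    for name, site in (("site_a", site_a), ("site_b", site_b)):
        r, c = site
        if not (0 <= r < amap.times_ms.shape[0] and 0 <= c < amap.times_ms.shape[1]):
            raise ValueError(f"{name} {site} outside the map")
        if not amap.valid[r, c]:
            raise ValueError(f"{name} {site} has no valid activation")
    return float(amap.times_ms[site_b] - amap.times_ms[site_a])
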