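"""Synthetic two-channel 3D localization scenes with planted cluster geometry.

The generator emulates dual-colour stochastic optical reconstruction
microscopy (STORM) of the intercalated disk: channel A holds plaque-like
reference clusters (oriented disks, standing in for connexin43 gap
junctions), channel B holds partner clusters (ellipsoids, standing in for
sodium-channel clusters) planted at an exact, known hull-to-hull edge
distance from their reference cluster. Negative planted distances produce
interpenetrating (overlapping) clusters, distances in ``(0, adjacency]``
produce perinexally adjacent clusters, larger distances produce distant
clusters.

The planted edge distance is exact by construction: the partner is placed
along a random direction ``u`` such that the support point of the reference
body in ``u`` and the support point of the partner body in ``-u`` are
aligned and separated by exactly the requested gap. For two convex bodies
this makes the minimum hull-to-hull distance equal the gap.

Each molecule position is a uniform draw inside its cluster body plus
anisotropic Gaussian localization noise; a uniform Poisson background is
added per channel; an optional rigid misregistration (rotation about z plus
translation) is applied to channel B and to its fiducial beads so the
channel-registration step has something to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import pandas as pd

from perinexus.synth.truth import SceneTruth


@dataclass
class StormSceneConfig:
    """Configuration for :func:`gen_storm_scene`.

    Defaults emulate the imaging conditions of the study: ~10 nm
    localization precision (σ_xy 10 nm, σ_z 25 nm reflecting the poorer
    axial resolution), a 10 × 10 µm field with 3 µm depth, plaque-like
    reference disks of 100–200 nm radius and ~40 nm thickness, and partner
    ellipsoids of 40–100 nm semi-axes. Molecule counts are chosen so the
    local point density comfortably exceeds the density-clustering
    threshold downstream (typical point spacing ≲ 25 nm inside a cluster).
    """

    n_pairs: int = 24
    field_um: Tuple[float, float, float] = (10.0, 10.0, 3.0)
    ref_radius_nm: Tuple[float, float] = (100.0, 200.0)
    ref_thickness_nm: float = 40.0
    partner_radii_nm: Tuple[float, float] = (40.0, 100.0)
    gap_range_nm: Tuple[float, float] = (-100.0, 600.0)
    #: planted gaps within this margin of the class boundaries (0 and
    #: ``adjacency_nm``) are rejected so planted labels are unambiguous.
    boundary_exclusion_nm: float = 75.0
    adjacency_nm: float = 200.0
    ref_molecules: int = 600
    partner_molecules: int = 300
    background_per_um3: float = 2.0
    sigma_lateral_nm: float = 10.0
    sigma_axial_nm: float = 25.0
    precision_mean_nm: float = 10.0
    n_frames: int = 1000
    n_fiducials: int = 8
    fiducial_sigma_nm: float = 2.0
    misreg_rotation_z_deg: float = 0.0
    misreg_translation_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: extra hull-to-hull clearance guaranteed between neighbouring pairs,
    #: beyond the adjacency threshold, so planted labels cannot be
    #: corrupted by a foreign reference cluster.
    pair_clearance_nm: float = 150.0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if any(f <= 0 for f in self.field_um):
            raise ValueError("field dimensions must be positive")
        if self.sigma_lateral_nm < 0 or self.sigma_axial_nm < 0:
            raise ValueError("localization sigmas must be >= 0")
        if self.background_per_um3 < 0:
            raise ValueError("background density must be >= 0")
        if self.ref_thickness_nm <= 0:
            raise ValueError("reference thickness must be positive")


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _disk_support(u: np.ndarray, normal: np.ndarray, radius: float, half_thickness: float) -> np.ndarray:
    """Support point (offset from centre) of an oriented disk/short cylinder."""
    ax = float(np.dot(u, normal))
    offset = np.sign(ax) * half_thickness * normal
    perp = u - ax * normal
    norm_perp = np.linalg.norm(perp)
    if norm_perp > 1e-12:
        offset = offset + radius * perp / norm_perp
    return offset


def _ellipsoid_support(u: np.ndarray, rot: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Support point (offset from centre) of a rotated ellipsoid."""
    w = rot.T @ u
    denom = np.linalg.norm(radii * w)
    if denom < 1e-12:  # pragma: no cover - u is a unit vector
        raise ValueError("degenerate support direction")
    return rot @ ((radii**2) * w) / denom


def _sample_disk(rng, n, normal, radius, half_thickness):
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, normal)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    z = rng.uniform(-half_thickness, half_thickness, size=n)
    return (
        r[:, None] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        + z[:, None] * normal
    )


def _sample_ellipsoid(rng, n, rot, radii):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=n) ** (1.0 / 3.0)
    pts = v * r[:, None] * radii
    return pts @ rot.T


def _draw_gap(rng, cfg: StormSceneConfig) -> float:
    lo, hi = cfg.gap_range_nm
    excl = cfg.boundary_exclusion_nm
    for _ in range(10_000):
        g = rng.uniform(lo, hi)
        if abs(g) < excl or abs(g - cfg.adjacency_nm) < excl:
            continue
        return float(g)
    raise ValueError(
        "gap_range_nm leaves no room outside the boundary-exclusion zones"
    )


def classify_gap(gap_nm: float, adjacency_nm: float = 200.0) -> str:
    """Class label implied by a planted hull-to-hull edge distance."""
    if gap_nm < 0:
        return "overlapping"
    if gap_nm <= adjacency_nm:
        return "adjacent"
    return "distant"


def gen_storm_scene(config: StormSceneConfig | None = None, seed: int = 0):
    """Generate a two-channel localization scene with planted cluster pairs.

    Returns
    -------
    tables : dict
        ``{"A": LocalizationTable, "B": LocalizationTable}`` — reference and
        partner channels, in the *observed* (possibly misregistered) frame
        for channel B.
    fiducials : dict
        ``{"A": DataFrame, "B": DataFrame}`` of fiducial bead localizations
        (columns ``x_nm, y_nm, z_nm``), channel B misregistered identically
        to its molecules.
    truth : SceneTruth
        Planted clusters, gaps, class labels, misregistration and seed.

    Raises
    ------
    ValueError
        If the requested number of pairs cannot be placed in the field with
        guaranteed label-preserving separation ("impossible placement").
    """
    from perinexus.storm_rla import LocalizationTable

    cfg = config or StormSceneConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    field_nm = np.asarray(cfg.field_um, dtype=float) * 1000.0
    ref_ext = max(cfg.ref_radius_nm[1], cfg.ref_thickness_nm / 2.0)
    part_ext = cfg.partner_radii_nm[1]
    pair_radius = ref_ext + max(cfg.gap_range_nm[1], 0.0) + 2.0 * part_ext
    spacing = pair_radius + ref_ext + cfg.adjacency_nm + cfg.pair_clearance_nm

    n_cells = np.maximum(np.floor(field_nm / spacing).astype(int), 0)
    if int(np.prod(n_cells)) < cfg.n_pairs:
        raise ValueError(
            f"impossible placement: field {tuple(cfg.field_um)} µm admits "
            f"{int(np.prod(n_cells))} well-separated pairs of this geometry "
            f"(spacing {spacing:.0f} nm) but {cfg.n_pairs} were requested; "
            "enlarge the field or shrink the cluster geometry"
        )

    # anchor grid, centred in the field
    origin = (field_nm - n_cells * spacing) / 2.0
    cells = np.array(
        [
            origin + (np.array([i, j, k]) + 0.5) * spacing
            for i in range(n_cells[0])
            for j in range(n_cells[1])
            for k in range(n_cells[2])
        ]
    )
    anchors = cells[rng.permutation(len(cells))[: cfg.n_pairs]]

    margin = pair_radius + 5.0 * max(cfg.sigma_lateral_nm, cfg.sigma_axial_nm)
    bounds = np.array([[-margin, -margin, -margin], field_nm + margin]).T  # (3, 2)

    sigma = np.array([cfg.sigma_lateral_nm, cfg.sigma_lateral_nm, cfg.sigma_axial_nm])

    pts_a, pts_b = [], []
    clusters = []
    for pair_id, anchor in enumerate(anchors):
        ref_radius = rng.uniform(*cfg.ref_radius_nm)
        ref_normal = _unit_vector(rng)
        half_t = cfg.ref_thickness_nm / 2.0
        part_radii = rng.uniform(*cfg.partner_radii_nm, size=3)
        part_rot = _random_rotation(rng)
        gap = _draw_gap(rng, cfg)
        u = _unit_vector(rng)

        p_ref = anchor + _disk_support(u, ref_normal, ref_radius, half_t)
        part_center = p_ref + gap * u - _ellipsoid_support(-u, part_rot, part_radii)

        n_ref = max(30, int(rng.poisson(cfg.ref_molecules)))
        n_part = max(30, int(rng.poisson(cfg.partner_molecules)))
        ref_pts = anchor + _sample_disk(rng, n_ref, ref_normal, ref_radius, half_t)
        part_pts = part_center + _sample_ellipsoid(rng, n_part, part_rot, part_radii)
        if cfg.sigma_lateral_nm > 0 or cfg.sigma_axial_nm > 0:
            ref_pts = ref_pts + rng.normal(size=ref_pts.shape) * sigma
            part_pts = part_pts + rng.normal(size=part_pts.shape) * sigma
        pts_a.append(ref_pts)
        pts_b.append(part_pts)

        clusters.append(
            {
                "pair_id": pair_id,
                "channel": "A",
                "shape": "disk",
                "centroid_nm": anchor.tolist(),
                "radii_nm": [ref_radius, ref_radius, half_t],
                "normal": ref_normal.tolist(),
                "n_molecules": n_ref,
                "planted_gap_nm": None,
                "class_label": None,
            }
        )
        clusters.append(
            {
                "pair_id": pair_id,
                "channel": "B",
                "shape": "ellipsoid",
                "centroid_nm": part_center.tolist(),
                "radii_nm": part_radii.tolist(),
                "normal": None,
                "n_molecules": n_part,
                "planted_gap_nm": gap,
                "class_label": classify_gap(gap, cfg.adjacency_nm),
            }
        )

    # uniform Poisson background over the declared bounds, per channel
    vol_um3 = float(np.prod((bounds[:, 1] - bounds[:, 0]) / 1000.0))
    for dest in (pts_a, pts_b):
        n_bg = rng.poisson(cfg.background_per_um3 * vol_um3)
        if n_bg > 0:
            bg = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_bg, 3))
            dest.append(bg)

    def _table(point_blocks, channel):
        pts = (
            np.concatenate(point_blocks, axis=0)
            if point_blocks
            else np.empty((0, 3))
        )
        n = len(pts)
        frames = rng.integers(0, cfg.n_frames, size=n)
        precision = rng.gamma(16.0, cfg.precision_mean_nm / 16.0, size=n)
        return pts, frames, precision, channel

    raw_a = _table(pts_a, "A")
    raw_b = _table(pts_b, "B")

    # fiducial beads, localized in both channels with small noise
    fid_true = rng.uniform(
        np.zeros(3), field_nm, size=(cfg.n_fiducials, 3)
    )
    fid_a = fid_true + rng.normal(size=fid_true.shape) * cfg.fiducial_sigma_nm
    fid_b = fid_true + rng.normal(size=fid_true.shape) * cfg.fiducial_sigma_nm

    # rigid misregistration applied to channel B molecules and fiducials
    theta = np.deg2rad(cfg.misreg_rotation_z_deg)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    trans = np.asarray(cfg.misreg_translation_nm, dtype=float)
    pts_b_obs = raw_b[0] @ rot.T + trans
    fid_b_obs = fid_b @ rot.T + trans

    def _frame(pts, frames, precision):
        return pd.DataFrame(
            {
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
                "frame": frames,
                "precision_nm": precision,
            }
        )

    # widen bounds to cover any misregistration excursion of channel B
    all_pts = np.concatenate([raw_a[0], pts_b_obs], axis=0) if len(raw_a[0]) + len(pts_b_obs) else np.empty((0, 3))
    if len(all_pts):
        lo = np.minimum(bounds[:, 0], all_pts.min(axis=0) - 1.0)
        hi = np.maximum(bounds[:, 1], all_pts.max(axis=0) + 1.0)
        bounds = np.stack([lo, hi], axis=1)

    table_a = LocalizationTable(
        points=_frame(raw_a[0], raw_a[1], raw_a[2]),
        channel="A",
        bounds_nm=bounds.tolist(),
    )
    table_b = LocalizationTable(
        points=_frame(pts_b_obs, raw_b[1], raw_b[2]),
        channel="B",
        bounds_nm=bounds.tolist(),
    )
    fiducials = {
        "A": pd.DataFrame(fid_a, columns=["x_nm", "y_nm", "z_nm"]),
        "B": pd.DataFrame(fid_b_obs, columns=["x_nm", "y_nm", "z_nm"]),
    }

    labels = [c["class_label"] for c in clusters if c["channel"] == "B"]
    fractions = {
        cls: labels.count(cls) / len(labels)
        for cls in ("overlapping", "adjacent", "distant")
    }
    truth = SceneTruth(
        modality="storm",
        seed=seed,
        params=asdict(cfg),
        records={
            "clusters": clusters,
            "class_fractions": fractions,
            "misregistration": {
                "rotation_z_deg": cfg.misreg_rotation_z_deg,
                "translation_nm": list(cfg.misreg_translation_nm),
            },
            "bounds_nm": bounds.tolist(),
        },
    )
    return {"A": table_a, "B": table_b}, fiducials, truth
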