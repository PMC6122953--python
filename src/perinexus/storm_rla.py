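"""STORM-based relative localization analysis (RLA).

Given two channels of already-localized single-molecule coordinates (for
example connexin43 as the reference channel and Na_V1.5 or β1 as the
partner channel), this module

1. registers the channels with a rigid transform estimated from fiducial
   beads (:class:`ChannelRegistrar`),
2. detects molecule clusters by density-based clustering
   (:class:`ClusterDetector`),
3. measures cluster volumes by voxelized occupancy (:func:`voxelize`),
4. computes pairwise overlap fractions and signed closest edge-to-edge
   distances between partner and reference clusters, and
5. classifies every partner cluster as *overlapping* (signed distance < 0),
   *adjacent* (within the perinexal adjacency threshold, default 200 nm
   from the reference cluster edge) or *distant*
   (:class:`RelativeLocalizationClassifier`).

Sign convention: a positive signed distance is the minimum distance between
the surface voxels of two disjoint clusters; a negative signed distance is
minus the maximum depth of any partner voxel inside the reference
occupancy, computed by a Euclidean distance transform. Distances are always
edge-to-edge, never centroid-to-centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

__all__ = [
    "LocalizationTable",
    "RigidTransform",
    "Cluster",
    "ClusterSet",
    "VoxelOccupancy",
    "RelativeLocalizationSummary",
    "ChannelRegistrar",
    "ClusterDetector",
    "RelativeLocalizationClassifier",
    "register_channels",
    "detect_clusters",
    "voxelize",
    "hull_volume",
    "overlap_fraction",
    "signed_closest_distance",
    "classify_relative_localization",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LocalizationTable:
    """One channel's 3D localized molecules with per-point precision.

    ``points`` is a DataFrame with columns ``x_nm, y_nm, z_nm, frame,
    precision_nm``; ``bounds_nm`` is a ``(3, 2)`` min/max box.
    """

    points: pd.DataFrame
    channel: str = ""
    bounds_nm: Optional[Sequence[Sequence[float]]] = None

    def __post_init__(self):
        required = {"x_nm", "y_nm", "z_nm"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"localization table missing columns: {sorted(missing)}")
        if "precision_nm" in self.points.columns and len(self.points):
            if not (self.points["precision_nm"] > 0).all():
                raise ValueError("every localization precision must be > 0")
        if self.bounds_nm is not None and len(self.points):
            b = np.asarray(self.bounds_nm, dtype=float)
            xyz = self.coords
            if (xyz < b[:, 0] - 1e-6).any() or (xyz > b[:, 1] + 1e-6).any():
                raise ValueError("localizations fall outside the stated bounds")

    @property
    def coords(self) -> np.ndarray:
        return self.points[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RigidTransform:
    """Rigid (rotation + translation) mapping of channel B onto channel A."""

    rotation: np.ndarray
    translation_nm: np.ndarray
    residual_rms_nm: float
    n_pairs: int = 0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_nm = np.asarray(self.translation_nm, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if self.residual_rms_nm < 0:
            raise ValueError("residual must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation_nm


@dataclass
class VoxelOccupancy:
    """Voxelized occupancy of a cluster on a world-anchored grid.

    The grid is anchored at the world origin (voxel index ``floor(x / v)``),
    so occupancies of different clusters voxelized at the same voxel size
    live on a common grid and can be intersected directly.
    """

    origin_idx: np.ndarray  # (3,) integer index of dense[0,0,0]
    dense: np.ndarray  # bool (nx, ny, nz)
    voxel_nm: float
    dilation_nm: float = 0.0

    @property
    def occupied_indices(self) -> np.ndarray:
        idx = np.argwhere(self.dense)
        return idx + self.origin_idx

    @property
    def surface_indices(self) -> np.ndarray:
        interior = ndimage.binary_erosion(self.dense, structure=_FACE_STRUCT, border_value=0)
        idx = np.argwhere(self.dense & ~interior)
        return idx + self.origin_idx

    @property
    def n_occupied(self) -> int:
        return int(self.dense.sum())

    @property
    def volume_nm3(self) -> float:
        return self.n_occupied * self.voxel_nm**3

    def centers(self, indices: np.ndarray) -> np.ndarray:
        return (indices + 0.5) * self.voxel_nm


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class Cluster:
    """A detected molecule cluster."""

    id: int
    point_indices: np.ndarray
    points_nm: np.ndarray
    precision_nm: Optional[np.ndarray] = None
    occupancy: Optional[VoxelOccupancy] = None

    @property
    def n_points(self) -> int:
        return len(self.point_indices)

    @property
    def centroid_nm(self) -> np.ndarray:
        return self.points_nm.mean(axis=0)

    @property
    def volume_nm3(self) -> float:
        if self.occupancy is None:
            raise ValueError("cluster not voxelized yet; call voxelize() first")
        return self.occupancy.volume_nm3


@dataclass
class ClusterSet:
    """Clusters detected in one channel, plus the noise labelling."""

    clusters: List[Cluster] = field(default_factory=list)
    labels: Optional[np.ndarray] = None  # per input point, -1 = noise
    channel: str = ""

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i) -> Cluster:
        return self.clusters[i]


@dataclass
class RelativeLocalizationSummary:
    """Per-partner-cluster classes plus population statistics."""

    table: pd.DataFrame  # cluster_id, class, signed_distance_nm, overlap_fraction, ...
    fractions: dict
    adjacency_nm: float
    histogram_counts: np.ndarray
    histogram_edges_nm: np.ndarray
    overlap_degrees: np.ndarray  # overlap fractions among overlapping clusters

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.table.shape[0] and abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


# ---------------------------------------------------------------------------
# channel registration
# ---------------------------------------------------------------------------


class ChannelRegistrar(BaseEstimator):
    """Least-squares rigid alignment of channel B onto channel A.

    Fiducial beads visible in both channels are paired by mutual nearest
    neighbour within ``gate_nm``; the optimal rotation + translation is the
    Kabsch/SVD solution. ``fit`` estimates the transform, ``transform``
    applies it to arbitrary channel-B points.

    Attributes
    ----------
    rotation_ : (3, 3) ndarray
    translation_nm_ : (3,) ndarray
    residual_rms_nm_ : float
    n_pairs_ : int
    """

    def __init__(self, gate_nm: float = 500.0):
        self.gate_nm = gate_nm

    @staticmethod
    def _as_xyz(points) -> np.ndarray:
        if isinstance(points, LocalizationTable):
            return points.coords
        if isinstance(points, pd.DataFrame):
            return points[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        return np.asarray(points, dtype=float)

    def fit(self, fiducials_a, fiducials_b):
        a = self._as_xyz(fiducials_a)
        b = self._as_xyz(fiducials_b)
        if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
            raise ValueError("fiducials must be (n, 3) coordinate arrays")

        tree_a, tree_b = cKDTree(a), cKDTree(b)
        _, nn_ab = tree_b.query(a)  # nearest B for each A
        d_ba, nn_ba = tree_a.query(b)  # nearest A for each B
        pairs = [
            (nn_ba[j], j)
            for j in range(len(b))
            if d_ba[j] <= self.gate_nm and nn_ab[nn_ba[j]] == j
        ]
        if len(pairs) < 3:
            raise ValueError(
                f"only {len(pairs)} usable fiducial pairs within the "
                f"{self.gate_nm} nm gate; >=3 required"
            )
        ia, ib = map(np.array, zip(*pairs))
        pa, pb = a[ia], b[ib]

        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        qa, qb = pa - ca, pb - cb
        s = np.linalg.svd(qb, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError(
                "fiducials are collinear: the rotation about their common "
                "axis is unconstrained; add beads off the line"
            )
        h = qb.T @ qa
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        trans = ca - rot @ cb
        resid = pa - (pb @ rot.T + trans)
        self.rotation_ = rot
        self.translation_nm_ = trans
        self.residual_rms_nm_ = float(np.sqrt((resid**2).sum(axis=1).mean()))
        self.n_pairs_ = len(pairs)
        return self

    def transform(self, points_b) -> np.ndarray:
        if not hasattr(self, "rotation_"):
            raise ValueError("ChannelRegistrar is not fitted yet")
        return self._as_xyz(points_b) @ self.rotation_.T + self.translation_nm_

    @property
    def transform_(self) -> RigidTransform:
        return RigidTransform(
            rotation=self.rotation_,
            translation_nm=self.translation_nm_,
            residual_rms_nm=self.residual_rms_nm_,
            n_pairs=self.n_pairs_,
        )


def register_channels(
    fiducials_a, fiducials_b, points_b, gate_nm: float = 500.0
) -> Tuple[np.ndarray, RigidTransform]:
    """Align channel B onto channel A using fiducial beads.

    Returns the transformed channel-B points and the fitted
    :class:`RigidTransform`.
    """
    reg = ChannelRegistrar(gate_nm=gate_nm).fit(fiducials_a, fiducials_b)
    moved = reg.transform(points_b)
    if isinstance(points_b, LocalizationTable):
        out = points_b.points.copy()
        out[["x_nm", "y_nm", "z_nm"]] = moved
        moved = LocalizationTable(points=out, channel=points_b.channel, bounds_nm=None)
    return moved, reg.transform_


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------


class ClusterDetector(BaseEstimator, ClusterMixin):
    """Density-based molecule-cluster detection.

    A point is a core point if it has at least ``min_points`` neighbours
    (counting itself) within ``radius_nm``; clusters are connected
    components of core points plus their border points (DBSCAN). Components
    with fewer than ``min_cluster_size`` members are discarded as
    background; unclustered points are labelled ``-1`` (noise).

    Defaults (30 nm radius, 5 points, 10-member minimum) sit near three
    times the nominal 10 nm localization precision.
    """

    def __init__(
        self,
        radius_nm: float = 30.0,
        min_points: int = 5,
        min_cluster_size: int = 10,
    ):
        self.radius_nm = radius_nm
        self.min_points = min_points
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")

        precision = None
        channel = ""
        if isinstance(X, LocalizationTable):
            precision = (
                X.points["precision_nm"].to_numpy(dtype=float)
                if "precision_nm" in X.points.columns
                else None
            )
            channel = X.channel
            X = X.coords
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            self.labels_ = np.empty(0, dtype=int)
            self.cluster_set_ = ClusterSet(clusters=[], labels=self.labels_, channel=channel)
            return self

        raw = DBSCAN(eps=self.radius_nm, min_samples=self.min_points).fit_predict(X)
        labels = np.full(len(X), -1, dtype=int)
        next_id = 0
        for lab in np.unique(raw):
            if lab == -1:
                continue
            members = np.flatnonzero(raw == lab)
            if len(members) < self.min_cluster_size:
                continue
            labels[members] = next_id
            next_id += 1

        clusters = [
            Cluster(
                id=cid,
                point_indices=np.flatnonzero(labels == cid),
                points_nm=X[labels == cid],
                precision_nm=None if precision is None else precision[labels == cid],
            )
            for cid in range(next_id)
        ]
        self.labels_ = labels
        self.cluster_set_ = ClusterSet(clusters=clusters, labels=labels, channel=channel)
        return self


def detect_clusters(
    table,
    radius_nm: float = 30.0,
    min_points: int = 5,
    min_cluster_size: int = 10,
) -> ClusterSet:
    """Detect molecule clusters in one channel; empty input yields an empty set."""
    det = ClusterDetector(
        radius_nm=radius_nm, min_points=min_points, min_cluster_size=min_cluster_size
    ).fit(table)
    return det.cluster_set_


# ---------------------------------------------------------------------------
# voxelization and pairwise measures
# ---------------------------------------------------------------------------


def voxelize(
    cluster: Cluster, voxel_nm: float = 20.0, dilation_nm: Optional[float] = None
) -> VoxelOccupancy:
    """Voxelize a cluster on the world-anchored grid.

    A voxel is occupied if it contains a member point or if its centre lies
    within ``dilation_nm`` of one. The default dilation is the median
    localization precision of the member points (or 0 if unavailable), so
    each molecule marks roughly the volume its position uncertainty covers.
    The occupancy is stored on the cluster and returned.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel_nm must be > 0")
    if dilation_nm is None:
        dilation_nm = (
            float(np.median(cluster.precision_nm))
            if cluster.precision_nm is not None and len(cluster.precision_nm)
            else 0.0
        )

    pts = cluster.points_nm
    lo = np.floor((pts.min(axis=0) - dilation_nm) / voxel_nm).astype(int)
    hi = np.floor((pts.max(axis=0) + dilation_nm) / voxel_nm).astype(int)
    shape = hi - lo + 1
    dense = np.zeros(shape, dtype=bool)

    # voxels containing a point are always occupied
    pt_idx = np.floor(pts / voxel_nm).astype(int) - lo
    dense[tuple(pt_idx.T)] = True

    if dilation_nm > 0:
        axes = [
            (np.arange(lo[k], hi[k] + 1) + 0.5) * voxel_nm for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dist, _ = cKDTree(pts).query(centers, k=1)
        dense |= (dist <= dilation_nm).reshape(shape)

    occ = VoxelOccupancy(origin_idx=lo, dense=dense, voxel_nm=voxel_nm, dilation_nm=dilation_nm)
    cluster.occupancy = occ
    return occ


def hull_volume(cluster: Cluster) -> float:
    """Convex-hull volume (nm³), available for comparison with voxel volume."""
    from scipy.spatial import ConvexHull

    return float(ConvexHull(cluster.points_nm).volume)


def _occupied_keyset(occ: VoxelOccupancy) -> set:
    return set(map(tuple, occ.occupied_indices))


def _require_occupancy(cluster: Cluster, what: str) -> VoxelOccupancy:
    if cluster.occupancy is None:
        raise ValueError(f"{what} cluster must be voxelized first")
    return cluster.occupancy


def overlap_fraction(partner: Cluster, reference: Cluster) -> float:
    """Fraction of the partner cluster's voxel volume shared with the reference."""
    occ_p = _require_occupancy(partner, "partner")
    occ_r = _require_occupancy(reference, "reference")
    if occ_p.voxel_nm != occ_r.voxel_nm:
        raise ValueError("clusters voxelized at different voxel sizes")
    if occ_p.n_occupied == 0:
        raise ValueError("zero-volume partner cluster")
    shared = _occupied_keyset(occ_p) & _occupied_keyset(occ_r)
    return len(shared) / occ_p.n_occupied


def signed_closest_distance(partner: Cluster, reference: Cluster) -> float:
    """Signed closest edge-to-edge distance (nm) between two clusters.

    Positive (disjoint occupancies): minimum distance between the dilated
    cluster surfaces, located via the surface voxels and refined to
    sub-voxel precision with the member points near the closest approach
    (minimum pairwise point distance minus twice the dilation radius).
    Negative (shared voxels): minus the maximum depth (Euclidean distance
    transform) of any shared voxel inside the reference occupancy.
    """
    occ_p = _require_occupancy(partner, "partner")
    occ_r = _require_occupancy(reference, "reference")
    if occ_p.voxel_nm != occ_r.voxel_nm:
        raise ValueError("clusters voxelized at different voxel sizes")
    v = occ_p.voxel_nm

    keys_p = _occupied_keyset(occ_p)
    keys_r = _occupied_keyset(occ_r)
    shared = keys_p & keys_r
    if not shared:
        sp = occ_p.centers(occ_p.surface_indices)
        sr = occ_r.centers(occ_r.surface_indices)
        dists, nearest = cKDTree(sr).query(sp, k=1)
        i = int(dists.argmin())
        d_vox = float(dists[i])
        # sub-voxel refinement: exact point-pair minimum minus the dilation
        # applied to each surface; restricted to the closest-approach
        # neighbourhood only when the clusters are large
        dil_p = occ_p.dilation_nm
        dil_r = occ_r.dilation_nm
        near_p, near_r = partner.points_nm, reference.points_nm
        if len(near_p) * len(near_r) > 4_000_000:
            radius = d_vox + 4.0 * v + dil_p + dil_r
            near_p = near_p[np.linalg.norm(near_p - sr[int(nearest[i])], axis=1) <= radius]
            near_r = near_r[np.linalg.norm(near_r - sp[i], axis=1) <= radius]
        if len(near_p) and len(near_r):
            d_pt, _ = cKDTree(near_r).query(near_p, k=1)
            refined = float(d_pt.min()) - dil_p - dil_r
            return max(refined, 0.0)
        return d_vox

    # penetration depth inside the reference, in nm
    padded = np.pad(occ_r.dense, 1, constant_values=False)
    depth = ndimage.distance_transform_edt(padded, sampling=v)[1:-1, 1:-1, 1:-1]
    local = np.array(sorted(shared)) - occ_r.origin_idx
    return float(-depth[tuple(local.T)].max())


# ---------------------------------------------------------------------------
# relative-localization classification
# ---------------------------------------------------------------------------


class RelativeLocalizationClassifier(BaseEstimator):
    """Classify partner clusters relative to reference clusters.

    For every partner cluster the nearest reference cluster by signed
    edge-to-edge distance is found (ties broken by lower reference id) and
    the partner is classed *overlapping* (distance < 0), *adjacent*
    (0 ≤ distance ≤ ``adjacency_nm``) or *distant*. Population fractions, a
    signed-distance histogram and the distribution of overlap degree among
    overlapping clusters are assembled into the fitted ``summary_``.

    ``candidate_k`` reference clusters (by centroid proximity) are screened
    per partner; the exact signed distance is computed for each candidate.
    """

    def __init__(
        self,
        adjacency_nm: float = 200.0,
        voxel_nm: float = 20.0,
        dilation_nm: Optional[float] = None,
        candidate_k: int = 3,
        histogram_bin_nm: float = 25.0,
    ):
        self.adjacency_nm = adjacency_nm
        self.voxel_nm = voxel_nm
        self.dilation_nm = dilation_nm
        self.candidate_k = candidate_k
        self.histogram_bin_nm = histogram_bin_nm

    def fit(self, partner_set: ClusterSet, reference_set: ClusterSet):
        for cl in list(partner_set) + list(reference_set):
            if cl.occupancy is None or cl.occupancy.voxel_nm != self.voxel_nm:
                voxelize(cl, voxel_nm=self.voxel_nm, dilation_nm=self.dilation_nm)

        rows = []
        if len(reference_set) == 0:
            for cl in partner_set:
                rows.append(
                    {
                        "cluster_id": cl.id,
                        "class": "distant",
                        "signed_distance_nm": np.inf,
                        "overlap_fraction": 0.0,
                        "overlap_fraction_ref": 0.0,
                        "nearest_reference": -1,
                        "volume_nm3": cl.volume_nm3,
                    }
                )
        else:
            ref_centroids = np.array([c.centroid_nm for c in reference_set])
            tree = cKDTree(ref_centroids)
            k = min(self.candidate_k, len(reference_set))
            for cl in partner_set:
                _, cand = tree.query(cl.centroid_nm, k=k)
                cand = np.atleast_1d(cand)
                best = None
                for ref_idx in sorted(cand, key=lambda i: reference_set[i].id):
                    ref = reference_set[int(ref_idx)]
                    d = signed_closest_distance(cl, ref)
                    if best is None or d < best[0] - 1e-12:
                        best = (d, ref)
                d, ref = best
                if d < 0:
                    frac = overlap_fraction(cl, ref)
                    frac_ref = (
                        overlap_fraction(ref, cl) if ref.occupancy.n_occupied else 0.0
                    )
                    cls = "overlapping"
                else:
                    frac = 0.0
                    frac_ref = 0.0
                    cls = "adjacent" if d <= self.adjacency_nm else "distant"
                rows.append(
                    {
                        "cluster_id": cl.id,
                        "class": cls,
                        "signed_distance_nm": d,
                        "overlap_fraction": frac,
                        "overlap_fraction_ref": frac_ref,
                        "nearest_reference": ref.id,
                        "volume_nm3": cl.volume_nm3,
                    }
                )

        table = pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "class",
                "signed_distance_nm",
                "overlap_fraction",
                "overlap_fraction_ref",
                "nearest_reference",
                "volume_nm3",
            ],
        )
        n = len(table)
        fractions = {
            cls: (float((table["class"] == cls).sum()) / n if n else 0.0)
            for cls in ("overlapping", "adjacent", "distant")
        }
        finite = table["signed_distance_nm"].replace(np.inf, np.nan).dropna()
        if len(finite):
            lo = np.floor(finite.min() / self.histogram_bin_nm) * self.histogram_bin_nm
            hi = np.ceil(finite.max() / self.histogram_bin_nm) * self.histogram_bin_nm
            hi = max(hi, lo + self.histogram_bin_nm)
            edges = np.arange(lo, hi + self.histogram_bin_nm / 2, self.histogram_bin_nm)
            counts, edges = np.histogram(finite, bins=edges)
        else:
            counts, edges = np.array([], dtype=int), np.array([0.0, self.histogram_bin_nm])
        overlap_degrees = table.loc[table["class"] == "overlapping", "overlap_fraction"].to_numpy()

        self.summary_ = RelativeLocalizationSummary(
            table=table,
            fractions=fractions,
            adjacency_nm=self.adjacency_nm,
            histogram_counts=counts,
            histogram_edges_nm=edges,
            overlap_degrees=overlap_degrees,
        )
        return self


def classify_relative_localization(
    partner_set: ClusterSet,
    reference_set: ClusterSet,
    adjacency_nm: float = 200.0,
    voxel_nm: float = 20.0,
    dilation_nm: Optional[float] = None,
) -> RelativeLocalizationSummary:
    """Classify partner clusters as overlapping / adjacent / distant."""
    clf = RelativeLocalizationClassifier(
        adjacency_nm=adjacency_nm, voxel_nm=voxel_nm, dilation_nm=dilation_nm
    ).fit(partner_set, reference_set)
    return clf.summary_
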