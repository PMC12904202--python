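"""SMLM nanocluster statistics for active-zone point clouds.

Density-based clustering (DBSCAN) of 3D localization clouds, cluster
size as the radius of gyration r_g (RMS distance of the localizations
from their center of mass), nearest-neighbor and distance-to-cluster-
center distributions between channels, and a 2D pixel-based hotspot
enrichment (z90/z50 of background-normalized intensities).

The DBSCAN here follows the published algorithm (core points have at
least ``min_pts`` neighbors within ``eps``, clusters are density-
connected sets of core points) with a deterministic, input-order-
independent rule for border points: a border point joins the cluster
with the lowest id among its core neighbors, ids being assigned by
ascending smallest member index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LocalizationCloud",
    "ClusterResult",
    "DistanceDistributions",
    "HotspotResult",
    "dbscan",
    "radius_of_gyration",
    "nnd",
    "distance_to_cluster_centers",
    "hotspot_enrichment",
]

NOISE = -1


@dataclass
class LocalizationCloud:
    """3D localizations (nm) of one channel, optionally grouped by AZ."""

    points: np.ndarray            # (N, 3) nm
    channel: str = ""
    az_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size and (self.points.ndim != 2 or self.points.shape[1] != 3):
            raise ValueError("points must be (N, 3)")
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.az_id is not None:
            self.az_id = np.asarray(self.az_id)
            if self.az_id.shape[0] != self.points.shape[0]:
                raise ValueError("az_id must match points")

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class ClusterResult:
    """DBSCAN labels plus per-cluster center of mass and r_g."""

    labels: np.ndarray            # per point; -1 = noise
    centers: np.ndarray           # (n_clusters, 3) nm
    r_g: np.ndarray               # (n_clusters,) nm
    sizes: np.ndarray             # (n_clusters,) point counts

    @property
    def n_clusters(self) -> int:
        return int(self.centers.shape[0])

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))


def dbscan(points: np.ndarray, eps: float = 50.0, min_pts: int = 5) -> ClusterResult:
    """Density-based clustering of a 3D point cloud.

    ``eps`` (nm) is the neighborhood radius and ``min_pts`` the minimum
    neighborhood size (the point itself included) for a core point.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterResult(labels=np.empty(0, int),
                             centers=np.empty((0, 3)), r_g=np.empty(0),
                             sizes=np.empty(0, int))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    n = pts.shape[0]
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, eps)
    core = np.array([len(nb) >= min_pts for nb in neighbors])

    # density-connect core points (union-find)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in np.flatnonzero(core):
        for j in neighbors[i]:
            if core[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    labels = np.full(n, NOISE, int)
    roots = sorted({find(i) for i in np.flatnonzero(core)})
    root_to_id = {r: k for k, r in enumerate(roots)}
    for i in np.flatnonzero(core):
        labels[i] = root_to_id[find(i)]
    # border points: lowest cluster id among core neighbors
    for i in np.flatnonzero(~core):
        ids = [labels[j] for j in neighbors[i] if core[j]]
        if ids:
            labels[i] = min(ids)

    n_clusters = len(roots)
    centers = np.empty((n_clusters, 3))
    rgs = np.empty(n_clusters)
    sizes = np.empty(n_clusters, int)
    for k in range(n_clusters):
        member = pts[labels == k]
        centers[k] = member.mean(axis=0)
        rgs[k] = radius_of_gyration(member)
        sizes[k] = member.shape[0]
    return ClusterResult(labels=labels, centers=centers, r_g=rgs, sizes=sizes)


def radius_of_gyration(points: np.ndarray) -> float:
    """RMS distance of the points from their center of mass (nm)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    center = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))


@dataclass
class DistanceDistributions:
    """Distances from one channel to the other, with eCDF summaries."""

    distances: np.ndarray         # nm, one per source point

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")
        self._sorted = np.sort(self.distances)

    def ecdf(self, x) -> np.ndarray | float:
        """Empirical cumulative probability P(distance <= x)."""
        out = np.searchsorted(self._sorted, np.asarray(x, float), side="right") \
            / self._sorted.size
        return float(out) if np.isscalar(x) else out

    def frac_below(self, threshold: float) -> float:
        """Cumulative probability of distances below ``threshold`` nm."""
        return float(self.ecdf(threshold))

    def epdf(self, bin_width: float = 10.0) -> Tuple[np.ndarray, np.ndarray]:
        """Histogram density estimate: (bin_centers, density)."""
        hi = self._sorted[-1] if self._sorted.size else bin_width
        edges = np.arange(0, hi + 2 * bin_width, bin_width)
        dens, _ = np.histogram(self.distances, bins=edges, density=True)
        return (edges[:-1] + edges[1:]) / 2.0, dens


def nnd(points_a: np.ndarray, points_b: np.ndarray) -> DistanceDistributions:
    """Nearest-neighbor distances from each a-point to the b channel."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both point sets must be nonempty")
    d, _ = cKDTree(b).query(a)
    return DistanceDistributions(distances=np.atleast_1d(d))


def distance_to_cluster_centers(points_a: np.ndarray,
                                centers_b: np.ndarray) -> DistanceDistributions:
    """Distance from each a-point to the nearest b-channel cluster
    center (ties resolved to the common distance)."""
    return nnd(points_a, centers_b)


@dataclass(frozen=True)
class HotspotResult:
    """Background-normalized intensity hotspot statistics of one ROI."""

    mu_bg: float
    sigma_bg: float
    z50: float
    z90: float
    enrichment: Optional[float]


def hotspot_enrichment(roi_pixels: np.ndarray,
                       background_pixels: np.ndarray) -> HotspotResult:
    """Hotspot enrichment z90/z50 of an ROI against local background.

    ROI intensities are z-normalized by the background mean and SD.
    z50 is the median; z90 is the intensity threshold leaving an area
    fraction of 10% of the ROI at or above it, taken as the k-th
    largest z-value with k = max(1, floor(0.1 n)) — on discrete data
    this honors the 10%-area definition exactly.  Enrichment is None
    (flagged) when z50 <= 0.
    """
    roi = np.asarray(roi_pixels, dtype=float).ravel()
    bg = np.asarray(background_pixels, dtype=float).ravel()
    if roi.size == 0:
        raise ValueError("ROI is empty")
    if bg.size < 2:
        raise ValueError("background needs >= 2 pixels")
    mu = float(bg.mean())
    sigma = float(bg.std(ddof=1))
    if sigma == 0:
        raise ValueError("invalid background: zero variance")
    z = (roi - mu) / sigma
    z50 = float(np.median(z))
    k = max(1, int(np.floor(0.1 * z.size)))
    z90 = float(np.sort(z)[-k])
    enrichment = z90 / z50 if z50 > 0 else None
    return HotspotResult(mu_bg=mu, sigma_bg=sigma, z50=z50, z90=z90,
                         enrichment=enrichment)
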