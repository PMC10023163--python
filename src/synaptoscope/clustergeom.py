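"""Cluster geometry for two-color localization data.

The workflow compares the spatial organization of one probe (say a calcium
channel) to another (the dense-projection marker ELKS) within a synapse:

1. compute each probe's cluster *center of mass*;
2. draw the axis through the two centers and assign every localization a
   signed *axial coordinate* along it, with the origin probe's center at 0;
3. summarize each probe's axial distribution as a *binned profile*
   (33 nm bins, matching EM section thickness) and a *diameter* — the
   width of the central 95% interval of the axial coordinates about the
   cluster's own center.

Cord-level organization (cluster spacing along the dorsal nerve cord) is
measured by :func:`detect_cord_clusters`, a 1D gap-linking clustering along
the cord's principal axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BIN_NM",
    "ClusterProfile",
    "CordClusters",
    "center_of_mass",
    "axial_projection",
    "binned_profile",
    "cluster_diameter",
    "fraction_within",
    "detect_cord_clusters",
    "profile_pair",
]

#: Histogram bin width in nm, fixed to match EM section thickness.
BIN_NM = 33.0


@dataclass
class ClusterProfile:
    """Axial summary of one probe's localizations within a synapse."""

    probe: str
    center: tuple[float, float]
    axial: np.ndarray  # signed nm along the inter-center axis
    bin_edges: np.ndarray
    fractions: np.ndarray
    diameter: float
    n: int


def center_of_mass(points: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of a set of (x, y) points in nm."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0 or points.shape[1] != 2:
        raise ValueError("center_of_mass requires a non-empty (n, 2) array")
    return points.mean(axis=0)


def axial_projection(
    origin_cluster: np.ndarray, target_cluster: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project both clusters onto the axis through their centers.

    The axis is the unit vector from the origin cluster's center to the
    target cluster's center.  Each localization's axial coordinate is the
    signed scalar projection of (point - origin center) onto the axis, so
    the origin center maps to 0 and the target center to +|center
    distance|.  Returns ``(origin_axial, target_axial)``.
    """
    origin_cluster = np.asarray(origin_cluster, dtype=float)
    target_cluster = np.asarray(target_cluster, dtype=float)
    c0 = center_of_mass(origin_cluster)
    c1 = center_of_mass(target_cluster)
    delta = c1 - c0
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise ValueError(
            "cluster centers coincide; no inter-center axis is defined "
            "(choose an arbitrary fixed axis explicitly)"
        )
    axis = delta / norm
    return (origin_cluster - c0) @ axis, (target_cluster - c0) @ axis


def binned_profile(
    axial: np.ndarray, bin_nm: float = BIN_NM
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram signed axial coordinates into half-open bins.

    Bins are ``[k*bin, (k+1)*bin)`` with an edge anchored at 0 (the origin
    center).  Returns ``(edges, fractions)``; fractions sum to 1.
    """
    axial = np.asarray(axial, dtype=float)
    if axial.size == 0:
        raise ValueError("binned_profile requires at least one coordinate")
    lo = np.floor(axial.min() / bin_nm)
    hi = np.floor(axial.max() / bin_nm) + 1
    edges = np.arange(lo, hi + 1) * bin_nm
    # np.histogram's last bin is closed; pad one empty bin so every data
    # bin is effectively half-open [lo, hi)
    counts, _ = np.histogram(axial, np.append(edges, edges[-1] + bin_nm))
    counts = counts[:-1]
    return edges, counts / counts.sum()


def cluster_diameter(axial: np.ndarray) -> float:
    """Width of the central 95% interval of signed axial coordinates.

    Computed as the 97.5th minus the 2.5th percentile (linear
    interpolation between order statistics).  This spread measure is the
    operational "diameter" of a cluster.
    """
    axial = np.asarray(axial, dtype=float)
    if axial.size < 2:
        raise ValueError("cluster_diameter requires at least 2 coordinates")
    lo, hi = np.percentile(axial, [2.5, 97.5])
    return float(hi - lo)


def fraction_within(target_axial: np.ndarray, interval: tuple[float, float]) -> float:
    """Fraction of axial coordinates inside a closed interval.

    Typically the interval is another probe's central-95% interval on the
    shared axis, giving the "within a cluster" colocalization fraction.
    """
    lo, hi = interval
    if not lo < hi:
        raise ValueError(f"invalid interval ({lo}, {hi})")
    target_axial = np.asarray(target_axial, dtype=float)
    if target_axial.size == 0:
        raise ValueError("fraction_within requires at least one coordinate")
    return float(np.mean((target_axial >= lo) & (target_axial <= hi)))


def profile_pair(
    origin_points: np.ndarray,
    target_points: np.ndarray,
    origin_probe: str = "origin",
    target_probe: str = "target",
    bin_nm: float = BIN_NM,
) -> tuple[ClusterProfile, ClusterProfile]:
    """Full two-probe geometry: projection, profiles and diameters.

    Diameters are measured about each cluster's own center (axial
    coordinates re-centered per probe); the binned profiles share the
    origin-centered axis.
    """
    origin_ax, target_ax = axial_projection(origin_points, target_points)
    profiles = []
    for probe, pts, ax in (
        (origin_probe, origin_points, origin_ax),
        (target_probe, target_points, target_ax),
    ):
        edges, fr = binned_profile(ax, bin_nm)
        c = center_of_mass(pts)
        profiles.append(
            ClusterProfile(
                probe=probe,
                center=(float(c[0]), float(c[1])),
                axial=ax,
                bin_edges=edges,
                fractions=fr,
                diameter=cluster_diameter(ax - ax.mean()),
                n=len(ax),
            )
        )
    return profiles[0], profiles[1]


@dataclass
class CordClusters:
    """Clusters of one probe ordered along the nerve cord."""

    centers: np.ndarray  # (k, 2) cluster centers, ordered along the cord
    members: list[np.ndarray]  # index arrays into the input
    spacings: np.ndarray  # consecutive center-to-center distances, nm
    clusters_per_um: float  # nan when undefined (single cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def detect_cord_clusters(
    locs,
    probe: str | None = None,
    gap_nm: float = 250.0,
    min_cluster_size: int = 20,
) -> CordClusters:
    """1D gap-linking clustering along the cord's principal axis.

    The cord axis is the first principal component of the localizations.
    Localizations are sorted along it and linked while consecutive gaps
    are below ``gap_nm``; runs with at least ``min_cluster_size`` members
    become clusters.  Returns centers (in the original 2D frame), ordered
    spacings and the cluster density over the spanned cord length.

    ``locs`` may be a :class:`~synaptoscope.loc_io.LocalizationSet` (with
    an optional ``probe`` to select) or a plain (n, 2) array.
    """
    if hasattr(locs, "xy"):
        if probe is not None:
            locs = locs.select_probe(probe)
        pts = locs.xy()
    else:
        pts = np.asarray(locs, dtype=float)
    empty = CordClusters(
        centers=np.empty((0, 2)),
        members=[],
        spacings=np.empty(0),
        clusters_per_um=float("nan"),
    )
    if len(pts) < min_cluster_size:
        warnings.warn("too few localizations for cord clustering")
        return empty

    centered = pts - pts.mean(axis=0)
    # first principal component = leading right-singular vector
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    order = np.argsort(t)
    ts = t[order]
    breaks = np.flatnonzero(np.diff(ts) > gap_nm)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(ts)]])

    members, centers = [], []
    for s, e in zip(starts, ends):
        idx = order[s:e]
        if len(idx) >= min_cluster_size:
            members.append(np.sort(idx))
            centers.append(pts[idx].mean(axis=0))
    if not centers:
        warnings.warn("no clusters met the minimum size")
        return empty

    centers = np.asarray(centers)
    proj = (centers - pts.mean(axis=0)) @ vt[0]
    order_c = np.argsort(proj)
    centers = centers[order_c]
    members = [members[i] for i in order_c]
    spacings = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    if len(centers) >= 2:
        span_um = (proj.max() - proj.min()) / 1000.0
        density = len(centers) / span_um if span_um > 0 else float("nan")
    else:
        warnings.warn("single cluster: spacing and density undefined")
        density = float("nan")
    return CordClusters(
        centers=centers,
        members=members,
        spacings=spacings,
        clusters_per_um=float(density),
    )
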