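"""Channel counting from single-fluorophore blink statistics.

A fluorophore blinks a small random number of times during an imaging
session, so the number of *channels* (molecules) at a synapse must be
inferred from the number of *blinks*.  Three estimators are implemented,
mirroring a spatial-grouping workflow for dispersed channels and a
photophysics workflow for dense clusters:

``blink mean``
    Blinks within ``eps`` (60 nm) of each other are grouped into putative
    channels by DBSCAN (singlet blinks count as channels).  A Poisson mean
    ``m`` is fitted to the grouped blink counts, and each synapse's channel
    count is estimated as total blinks / ``m``.

``photon flux``
    Each synapse's total photon count divided by the pooled mean photons
    emitted per grouped channel.

``blink rate``
    For clusters too dense to group (all localizations overlap), total
    blinks divided by an assumed per-fluorophore blink rate (about six
    blinks per minute for cyanine dyes in oxygen-scavenging buffer).

Geometric capacity bounds for a dense cluster come from circle packing:
how many channel-sized circles fit in a cluster-sized circle
(:func:`packing_bound`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = [
    "BlinkGroup",
    "PhotonStats",
    "CountEstimates",
    "group_blinks",
    "fit_blink_poisson",
    "estimate_by_blink_mean",
    "estimate_by_photon_flux",
    "estimate_by_blink_rate",
    "photon_stats",
    "packing_bound",
    "count_channels",
]


@dataclass
class BlinkGroup:
    """A set of blinks attributed to one physical channel."""

    group_id: int
    members: np.ndarray  # indices into the blink table
    centroid: tuple[float, float]
    blink_count: int
    photon_sum: float
    is_singlet: bool


def group_blinks(locs, eps: float = 60.0, min_pts: int = 2) -> list[BlinkGroup]:
    """Density-group blinks into putative channels.

    DBSCAN with radius ``eps`` and core threshold ``min_pts``; noise
    points (singlet blinks) are promoted to singleton groups, since a
    solitary blink is still evidence of one channel.  ``locs`` is a
    :class:`~synaptoscope.loc_io.LocalizationSet` or an (n, 2) array; the
    optional photons vector is read from the table when available.
    """
    if hasattr(locs, "xy"):
        xy = locs.xy()
        photons = locs.data["photons"].to_numpy(dtype=float)
    else:
        xy = np.asarray(locs, dtype=float)
        photons = np.zeros(len(xy))
    if len(xy) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)
    groups: list[BlinkGroup] = []
    for lab in range(labels.max() + 1):
        idx = np.flatnonzero(labels == lab)
        groups.append(_make_group(len(groups), idx, xy, photons))
    for i in np.flatnonzero(labels == -1):
        groups.append(_make_group(len(groups), np.array([i]), xy, photons))
    return groups


def _make_group(gid, idx, xy, photons) -> BlinkGroup:
    c = xy[idx].mean(axis=0)
    return BlinkGroup(
        group_id=gid,
        members=idx,
        centroid=(float(c[0]), float(c[1])),
        blink_count=len(idx),
        photon_sum=float(photons[idx].sum()),
        is_singlet=len(idx) == 1,
    )


def fit_blink_poisson(blink_counts) -> float:
    """Maximum-likelihood Poisson mean of blinks per grouped channel.

    The MLE on observed counts is the sample mean.  No zero-truncation
    correction is applied: channels that never blinked are unobservable
    and simply absent from the data.
    """
    counts = np.asarray(blink_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no blink groups to fit")
    return float(counts.mean())


def estimate_by_blink_mean(total_blinks: float, m: float) -> float:
    """Channels = total blinks / mean blinks per channel."""
    if m <= 0:
        raise ValueError("blink mean m must be positive")
    return total_blinks / m


def estimate_by_photon_flux(total_photons: float, mean_photons_per_channel: float) -> float:
    """Channels = synapse photon total / pooled mean photons per channel.

    The per-channel mean must be pooled across synapses of a condition;
    computing it per synapse would make the estimate degenerate (always
    the number of groups).
    """
    if mean_photons_per_channel <= 0:
        raise ValueError("pooled mean photons per channel must be positive")
    return total_photons / mean_photons_per_channel


def estimate_by_blink_rate(
    total_blinks: float, rate_per_min: float = 6.0, duration_min: float = 1.0
) -> float:
    """Channels = total blinks / (blink rate x session duration)."""
    if rate_per_min <= 0 or duration_min <= 0:
        raise ValueError("rate and duration must be positive")
    return total_blinks / (rate_per_min * duration_min)


@dataclass
class PhotonStats:
    """Pooled photon statistics per blink and per grouped channel."""

    mode_per_blink: float  # Mo, 50-photon binned mode (bin center)
    mean_per_blink: float  # A-bar
    mode_per_channel: float
    mean_per_channel: float


def _binned_mode(values: np.ndarray, bin_width: float = 50.0) -> float:
    """Center of the most populated histogram bin (bins anchored at 0)."""
    values = np.asarray(values, dtype=float)
    edges = np.arange(0.0, values.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(values, edges)
    k = int(np.argmax(counts))
    return float(edges[k] + bin_width / 2)


def photon_stats(photons, groups: list[BlinkGroup], bin_width: float = 50.0) -> PhotonStats:
    """Photon mode/mean per blink and per grouped channel.

    Modes are computed on a histogram with 50-photon bins; means are
    arithmetic.
    """
    photons = np.asarray(photons, dtype=float)
    if photons.size == 0:
        raise ValueError("no blinks")
    per_channel = np.array([g.photon_sum for g in groups], dtype=float)
    return PhotonStats(
        mode_per_blink=_binned_mode(photons, bin_width),
        mean_per_blink=float(photons.mean()),
        mode_per_channel=_binned_mode(per_channel, bin_width) if per_channel.size else float("nan"),
        mean_per_channel=float(per_channel.mean()) if per_channel.size else float("nan"),
    )


# Published optimal packings of N equal circles in a circle, N <= 20,
# expressed as the minimal container/circle diameter ratio admitting N
# circles (Graham et al.; values as tabulated to 6 decimals).
_OPTIMAL_RATIOS = {
    1: 1.0,
    2: 2.0,
    3: 2.154701,
    4: 2.414214,
    5: 2.701302,
    6: 3.0,
    7: 3.0,
    8: 3.304765,
    9: 3.613126,
    10: 3.813026,
    11: 3.923804,
    12: 4.029602,
    13: 4.236068,
    14: 4.328429,
    15: 4.521357,
    16: 4.615426,
    17: 4.792035,
    18: 4.863703,
    19: 4.863703,
    20: 5.122307,
}


def packing_bound(
    container_diameter: float,
    circle_diameter: float,
    method: str = "optimal_ratio",
) -> int:
    """How many circles of one diameter fit in a larger circle.

    ``optimal_ratio``
        Largest N (<= 20) whose published optimal packing ratio does not
        exceed container/circle; falls back to ``hex_lattice`` when the
        ratio exceeds the tabulated range.
    ``hex_lattice``
        Count hexagonal-lattice points (spacing = circle diameter, one
        lattice point at the container center, fixed orientation) whose
        circles fit fully inside the container.  No offset or rotation
        search: reproducibility over optimality.
    """
    if circle_diameter <= 0 or container_diameter <= 0:
        raise ValueError("diameters must be positive")
    if circle_diameter > container_diameter:
        return 0
    ratio = container_diameter / circle_diameter
    if method == "optimal_ratio":
        if ratio <= _OPTIMAL_RATIOS[20] + 1e-9:
            return max(n for n, r in _OPTIMAL_RATIOS.items() if r <= ratio + 1e-9)
        return packing_bound(container_diameter, circle_diameter, "hex_lattice")
    if method == "hex_lattice":
        d = circle_diameter
        reach = (container_diameter - circle_diameter) / 2.0
        jmax = int(np.floor(reach / (d * np.sqrt(3) / 2))) + 1
        imax = int(np.floor(reach / d)) + 2
        count = 0
        for j in range(-jmax, jmax + 1):
            y = j * d * np.sqrt(3) / 2
            for i in range(-imax, imax + 1):
                x = (i + 0.5 * (j % 2)) * d
                if x * x + y * y <= reach * reach + 1e-9:
                    count += 1
        return count
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CountEstimates:
    """Per-synapse channel-count estimates plus pooled photophysics."""

    per_synapse: pd.DataFrame
    m: float  # pooled Poisson blink mean
    photons: PhotonStats

    @property
    def mean_blink_mean_estimate(self) -> float:
        return float(self.per_synapse["est_blink_mean"].mean())

    @property
    def mean_photon_flux_estimate(self) -> float:
        return float(self.per_synapse["est_photon_flux"].mean())


def count_channels(
    synapses,
    eps: float = 60.0,
    min_pts: int = 2,
    blink_rate_per_min: float = 6.0,
    duration_min: float = 1.0,
) -> CountEstimates:
    """Run the full counting workflow over a collection of synapses.

    ``synapses`` is a sequence of per-synapse blink tables (each a
    :class:`~synaptoscope.loc_io.LocalizationSet` or ``(xy, photons)``
    pair).  Blink grouping and the Poisson fit are pooled across all
    synapses; the three estimators are then evaluated per synapse.
    """
    rows = []
    pooled_counts: list[int] = []
    pooled_photon_sums: list[float] = []
    all_photons: list[np.ndarray] = []
    for i, syn in enumerate(synapses):
        if hasattr(syn, "xy"):
            xy, photons = syn.xy(), syn.data["photons"].to_numpy(dtype=float)
        else:
            xy, photons = np.asarray(syn[0], float), np.asarray(syn[1], float)
        groups = group_blinks(xy, eps=eps, min_pts=min_pts)
        for g in groups:
            g.photon_sum = float(photons[g.members].sum())
        pooled_counts.extend(g.blink_count for g in groups)
        pooled_photon_sums.extend(g.photon_sum for g in groups)
        all_photons.append(photons)
        rows.append(
            {
                "roi_id": i,
                "total_blinks": len(xy),
                "n_groups": len(groups),
                "total_photons": float(photons.sum()),
            }
        )
    if not rows:
        raise ValueError("no synapses")
    m = fit_blink_poisson(pooled_counts)
    mean_ph_per_channel = float(np.mean(pooled_photon_sums))
    df = pd.DataFrame(rows)
    df["est_blink_mean"] = df["total_blinks"] / m
    df["est_photon_flux"] = df["total_photons"] / mean_ph_per_channel
    df["est_blink_rate"] = df["total_blinks"] / (blink_rate_per_min * duration_min)
    stats = photon_stats(np.concatenate(all_photons), [])
    stats.mean_per_channel = mean_ph_per_channel
    stats.mode_per_channel = _binned_mode(np.asarray(pooled_photon_sums))
    return CountEstimates(per_synapse=df, m=m, photons=stats)
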