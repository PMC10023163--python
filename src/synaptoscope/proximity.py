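"""Nearest-neighbor colocalization between probe point sets.

For every localization of a *source* probe, the distance to its closest
*target*-probe localization is computed (first nearest neighbor, 2D
Euclidean).  The headline statistic is the fraction of source
localizations whose nearest target lies within a threshold (100 nm by
default) — e.g. "94% of RyR localizations were within 100 nm of a CaV1
localization".  The measure is asymmetric by design: source->target and
target->source answer different questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NNResult", "nn_distances", "fraction_within_threshold", "nn_analysis"]


@dataclass
class NNResult:
    source: str
    target: str
    distances: np.ndarray  # nm, one per source localization
    threshold: float
    fraction_within: float


def nn_distances(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """First-nearest-neighbor distance from each source point to the target set."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.size == 0:
        raise ValueError("empty source point set")
    if target.size == 0:
        raise ValueError("empty target point set")
    d, _ = cKDTree(target).query(source, k=1)
    return np.asarray(d, dtype=float)


def fraction_within_threshold(distances: np.ndarray, threshold: float = 100.0) -> float:
    """Fraction of distances at or below the threshold (inclusive)."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("no distances")
    return float(np.mean(distances <= threshold))


def nn_analysis(
    rois,
    source: str,
    target: str,
    threshold: float = 100.0,
) -> NNResult:
    """Pooled nearest-neighbor analysis over synapse ROIs.

    Distances are computed within each ROI (a source localization is only
    matched against targets of the same synapse), then pooled across ROIs
    for the headline fraction.  ROIs lacking either probe are skipped.
    """
    pooled = []
    for roi in rois:
        s = roi.probe(source).xy()
        t = roi.probe(target).xy()
        if len(s) == 0 or len(t) == 0:
            continue
        pooled.append(nn_distances(s, t))
    if not pooled:
        raise ValueError(f"no ROI contains both {source!r} and {target!r}")
    distances = np.concatenate(pooled)
    return NNResult(
        source=source,
        target=target,
        distances=distances,
        threshold=threshold,
        fraction_within=fraction_within_threshold(distances, threshold),
    )
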