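"""Quantal decomposition of miniature postsynaptic current amplitudes.

A miniature current ("mini") arises from spontaneous fusion of one or a
few synaptic vesicles; a multi-vesicle fusion produces a summed,
multi-quantal amplitude.  The modal amplitude of the distribution is taken
as the single-quantum size.  The amplitude histogram (1 pA bins) is then
decomposed into ``n`` Gaussian terms whose means are constrained to
integer multiples of the mode: term ``k`` is centered on ``k x mode`` and
allowed to move by ``+-k`` pA.  Amplitudes are free; term widths are by
default tied to the quantal scaling ``sd_k = sd_1 * sqrt(k)`` (the
variance of k independently fusing quanta is k times the single-quantum
variance), which keeps the decomposition identifiable when neighboring
components overlap.  Fully free widths are available via
``tie_widths=False`` but are weakly identified: with overlapping
components the least-squares optimum can trade a widened term against
binning noise, making the recovered fractions unstable.  The area under
each fitted term (trapezoidal integration) gives the fraction of events
carrying ``k`` quanta; everything above one quantum is the multiquantal
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "QuantalFit",
    "amplitude_histogram",
    "modal_amplitude",
    "fit_quantal_gaussians",
    "quantal_fractions",
    "multiquantal_fraction",
]


@dataclass
class QuantalFit:
    """Result of the constrained multi-Gaussian histogram fit."""

    mode: float  # single-quantum amplitude, pA
    n_terms: int
    means: np.ndarray  # pA, term k constrained to [k*(mode-1), k*(mode+1)]
    sds: np.ndarray  # pA, free (> 0)
    amplitudes: np.ndarray  # bin-count units, free (>= 0)
    fractions: np.ndarray  # per-term area fractions, sum to 1
    rss: float  # residual sum of squares
    bin_centers: np.ndarray
    bin_counts: np.ndarray

    def model(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, mu, sd in zip(self.amplitudes, self.means, self.sds):
            out += a * np.exp(-((x - mu) ** 2) / (2 * sd**2))
        return out


def amplitude_histogram(
    amplitudes, bin_pa: float = 1.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram mini amplitudes into half-open bins anchored at 0.

    Non-positive amplitudes are rejected (a mini has a magnitude), and
    their count is returned alongside ``(edges, counts)``.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size == 0:
        raise ValueError("no amplitudes")
    n_rejected = int((amps <= 0).sum())
    amps = amps[amps > 0]
    if amps.size == 0:
        raise ValueError(f"all {n_rejected} amplitudes were non-positive")
    n_bins = int(np.floor(amps.max() / bin_pa)) + 1
    bin_edges = np.arange(n_bins + 1) * bin_pa
    # no amplitude can sit on the final (closed) numpy edge, so the bins
    # behave as half-open [k*bin, (k+1)*bin)
    counts, _ = np.histogram(amps, bin_edges)
    return bin_edges[:-1], counts, n_rejected


def modal_amplitude(edges: np.ndarray, counts: np.ndarray) -> float:
    """Lower edge of the most populated bin (ties break to the lowest bin).

    The lower-edge convention matches integer reporting of modes from
    1 pA bins (a peak in [7, 8) is reported as 7 pA).
    """
    counts = np.asarray(counts)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty histogram")
    return float(np.asarray(edges)[int(np.argmax(counts))])


def fit_quantal_gaussians(
    edges: np.ndarray,
    counts: np.ndarray,
    mode: float,
    n_terms: int = 3,
    tie_widths: bool = True,
) -> QuantalFit:
    """Constrained multi-Gaussian least-squares fit to a 1 pA histogram.

    Nonlinear least squares on (bin center, count) pairs of
    ``sum_k a_k exp(-(x - mu_k)^2 / (2 sd_k^2))`` with box constraints
    ``mu_k in [k*(mode-1), k*(mode+1)]`` and ``a_k >= 0``.  With
    ``tie_widths`` (default) a single free width parameter sets
    ``sd_k = sd_1 * sqrt(k)``; otherwise every width is free (> 0).
    Nine deterministic starts (3 mean offsets x 3 width scales) are run
    and the best residual kept.
    """
    if mode <= 0:
        raise ValueError("mode must be positive")
    edges = np.asarray(edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    width = edges[1] - edges[0] if edges.size > 1 else 1.0
    x = edges + width / 2
    if edges[-1] < n_terms * mode:
        raise ValueError(
            f"histogram support ends at {edges[-1]} pA; cannot place {n_terms} "
            f"terms at multiples of {mode} pA"
        )

    ks = np.arange(1, n_terms + 1)
    if tie_widths:
        # layout: a_1..a_n, mu_1..mu_n, sd_1
        lo = np.concatenate([np.zeros(n_terms), ks * (mode - 1), [1e-6]])
        hi = np.concatenate([np.full(n_terms, np.inf), ks * (mode + 1), [np.inf]])

        def unpack(p):
            return p[:n_terms], p[n_terms : 2 * n_terms], p[-1] * np.sqrt(ks)

    else:
        # layout: a_1, mu_1, sd_1, a_2, mu_2, sd_2, ...
        lo = np.ravel([[0.0, k * (mode - 1), 1e-6] for k in ks])
        hi = np.ravel([[np.inf, k * (mode + 1), np.inf] for k in ks])

        def unpack(p):
            return p[0::3], p[1::3], p[2::3]

    def residual(p):
        amps_, mus_, sds_ = unpack(p)
        model = np.zeros_like(x)
        for a, mu, sd in zip(amps_, mus_, sds_):
            model += a * np.exp(-((x - mu) ** 2) / (2 * sd**2))
        return model - counts

    best = None
    peak = counts.max()
    for sd_scale in (0.5, 1.0, 2.0):
        for mu_off in (-0.5, 0.0, 0.5):
            a0 = peak / ks
            mu0 = ks * mode + mu_off * ks
            if tie_widths:
                p0 = np.concatenate([a0, mu0, [2.0 * sd_scale]])
            else:
                p0 = np.ravel(
                    np.column_stack([a0, mu0, 2.0 * np.sqrt(ks) * sd_scale])
                )
            p0 = np.clip(p0.astype(float), lo, hi)
            try:
                res = least_squares(residual, p0, bounds=(lo, hi))
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError("quantal fit failed to converge from any start")

    amps, means, sds = (np.asarray(v).copy() for v in unpack(best.x))
    fit = QuantalFit(
        mode=float(mode),
        n_terms=n_terms,
        means=means,
        sds=sds,
        amplitudes=amps,
        fractions=np.empty(n_terms),
        rss=float(2 * best.cost),
        bin_centers=x,
        bin_counts=counts,
    )
    fit.fractions = quantal_fractions(fit)
    return fit


def quantal_fractions(fit: QuantalFit, resolution_pa: float = 0.1) -> np.ndarray:
    """Per-term area fractions by trapezoidal integration.

    Each fitted term is integrated over the histogram support at 0.1 pA
    resolution; fractions are the per-term areas normalized to sum to 1.
    """
    xs = np.arange(fit.bin_centers[0], fit.bin_centers[-1] + resolution_pa, resolution_pa)
    areas = np.array(
        [
            np.trapezoid(a * np.exp(-((xs - mu) ** 2) / (2 * sd**2)), xs)
            for a, mu, sd in zip(fit.amplitudes, fit.means, fit.sds)
        ]
    )
    total = areas.sum()
    if total == 0:
        raise ValueError("fit has zero total area")
    return areas / total


def multiquantal_fraction(fractions: np.ndarray) -> float:
    """Fraction of events releasing more than one quantum: 1 - fraction_1."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0 or not np.all(fractions >= 0):
        raise ValueError("invalid fractions")
    return float(1.0 - fractions[0])
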