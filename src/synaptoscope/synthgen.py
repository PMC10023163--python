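"""Synthetic data with ground-truth bookkeeping for every analysis stage.

Each generator emulates the statistical structure its downstream analysis
assumes, and returns a *ledger* recording the hidden truth (which channel
produced each blink, each mini's true quantal class, each worm's true bout
boundaries), so estimators can be validated by parameter recovery.

Blinking model
    Observable blink counts per channel follow a zero-truncated Poisson:
    a channel that never blinks is invisible, so the generator draws from
    the truncated law parameterized by its *observed* mean (default 2.7
    blinks/channel).  The underlying rate solves ``lam / (1 - exp(-lam))
    = mean``.

Photon model
    Log-normal, the minimal right-skewed two-parameter law matching the
    observed per-blink mode (575 photons) and mean (765 photons).

Precision model
    Localization error falls with photon count as ``sigma = c / sqrt(N)``
    with ``c = 500 nm*photons^0.5``, mapping the photon mode to ~21 nm —
    inside the 15-29 nm range of typical blinks.

Channel placement
    ``dense_cluster``: uniform in a disc (CaV2-like, ~250-300 nm).
    ``dispersed``: a hard-core point process (uniform proposals, minimum
    pairwise separation, default 100 nm) over a varicosity-scale disc.
    The hard core makes channels individually resolvable at the 60 nm
    grouping criterion, the regime in which grouped blink counts reflect
    single-fluorophore statistics (observed mean ~2.7 blinks/channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .loc_io import LocalizationSet
from .locomotion import Track

__all__ = [
    "SynapseSimConfig",
    "QuantalSimConfig",
    "CAV1_PRESET",
    "CAV2_PRESET",
    "RYR_PRESET",
    "NEMADIPINE_PRESET",
    "DANTROLENE_NEMADIPINE_PRESET",
    "ztp_rate",
    "sample_ztp",
    "lognormal_params",
    "simulate_synapse",
    "simulate_minis",
    "simulate_vesicle_profiles",
    "simulate_tracks",
    "simulate_cord",
    "DEFAULT_DOCKED_PROFILE",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# blink / photon / precision models


def ztp_rate(observed_mean: float) -> float:
    """Underlying Poisson rate of a zero-truncated Poisson with this mean.

    Solves ``lam / (1 - exp(-lam)) = observed_mean``; e.g. an observed
    mean of 2.7 corresponds to a rate of ~2.47.
    """
    if observed_mean <= 1.0:
        raise ValueError(
            f"observed blink mean must exceed 1 (got {observed_mean}); the "
            "zero-truncated Poisson mean is always > 1"
        )
    return float(brentq(lambda lam: lam / (1 - np.exp(-lam)) - observed_mean, 1e-9, 1e3))


def sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse-CDF on (P(0), 1]."""
    if size == 0:
        return np.zeros(0, dtype=int)
    u = rng.uniform(np.exp(-lam), 1.0, size)
    return stats.poisson.ppf(u, lam).astype(int)


def lognormal_params(mode: float, mean: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mode and mean."""
    if not 0 < mode < mean:
        raise ValueError("need 0 < mode < mean for a right-skewed log-normal")
    sigma2 = (2.0 / 3.0) * np.log(mean / mode)
    return float(np.log(mode) + sigma2), float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# SMLM synapse simulation


@dataclass(frozen=True)
class SynapseSimConfig:
    """Study conditions for one probe's blink simulation.

    ``placement`` is ``("dense_cluster", diameter_nm)`` or
    ``("dispersed", extent_nm, min_separation_nm)`` where *extent* is the
    diameter of the residence disc.
    """

    name: str
    probe: str
    channels_per_synapse: int
    placement: tuple
    blink_mean: float = 2.7  # observed blinks per channel
    photon_mode: float = 575.0
    photon_mean: float = 765.0
    precision_coeff: float = 500.0  # nm * photons^0.5
    duration_s: float = 60.0
    fps: float = 50.0
    background_blinks: float = 0.0  # expected spurious blinks per synapse
    dark_fraction: float = 0.0  # channels that never blink (unlabeled)

    def __post_init__(self) -> None:
        if self.channels_per_synapse < 0:
            raise ValueError("channels_per_synapse must be >= 0")
        if self.blink_mean <= 1.0:
            raise ValueError("observed blink mean must exceed 1")
        if self.placement[0] not in ("dense_cluster", "dispersed"):
            raise ValueError(f"unknown placement model {self.placement[0]!r}")
        if any(v <= 0 for v in self.placement[1:]):
            raise ValueError("placement dimensions must be positive")
        if not 0 <= self.dark_fraction < 1:
            raise ValueError("dark_fraction must be in [0, 1)")


#: CaV1: dispersed over the synaptic varicosity, ~79 channels.
CAV1_PRESET = SynapseSimConfig(
    name="CaV1",
    probe="CaV1",
    channels_per_synapse=79,
    placement=("dispersed", 1400.0, 100.0),
)

#: RyR: dispersed, lateral, ~29 channels over a ~870 nm extent.
RYR_PRESET = SynapseSimConfig(
    name="RyR",
    probe="RyR",
    channels_per_synapse=29,
    placement=("dispersed", 869.0, 100.0),
)

#: CaV2: ~101 channels packed into a ~275 nm dense-projection cluster.
CAV2_PRESET = SynapseSimConfig(
    name="CaV2",
    probe="CaV2",
    channels_per_synapse=101,
    placement=("dense_cluster", 275.0),
)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _hardcore_disc(
    rng: np.random.Generator, n: int, radius: float, min_sep: float, max_tries: int = 500_000
) -> np.ndarray:
    """Random sequential placement with a minimum pairwise separation."""
    pts = np.empty((n, 2))
    k = 0
    tries = 0
    d2 = min_sep * min_sep
    while k < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} channels with {min_sep} nm separation in a "
                f"{2 * radius:.0f} nm disc (placed {k}); the configuration is too dense"
            )
        p = _uniform_disc(rng, 1, radius)[0]
        tries += 1
        if k == 0 or (((pts[:k] - p) ** 2).sum(axis=1) >= d2).all():
            pts[k] = p
            k += 1
    return pts


def simulate_synapse(
    cfg: SynapseSimConfig, seed
) -> tuple[LocalizationSet, dict]:
    """Simulate one synapse's blink table.

    Returns ``(localizations, ledger)``.  The ledger maps every blink to
    its source channel (``blink_channel``, index into
    ``channel_positions``; -1 marks background) and records the true
    channel count, including dark channels that produced no blinks.
    """
    rng = _rng(seed)
    n_ch = cfg.channels_per_synapse
    if cfg.placement[0] == "dense_cluster":
        positions = _uniform_disc(rng, n_ch, cfg.placement[1] / 2.0)
    else:
        positions = _hardcore_disc(rng, n_ch, cfg.placement[1] / 2.0, cfg.placement[2])

    dark = rng.uniform(0, 1, n_ch) < cfg.dark_fraction
    lam = ztp_rate(cfg.blink_mean)
    blinks = np.where(dark, 0, sample_ztp(rng, lam, n_ch))
    blink_channel = np.repeat(np.arange(n_ch), blinks)

    origins = positions[blink_channel] if len(blink_channel) else np.empty((0, 2))
    n_bg = rng.poisson(cfg.background_blinks) if cfg.background_blinks > 0 else 0
    if n_bg:
        bg = _uniform_disc(rng, n_bg, cfg.placement[1] / 2.0)
        origins = np.vstack([origins, bg])
        blink_channel = np.concatenate([blink_channel, np.full(n_bg, -1)])

    n = len(blink_channel)
    mu, sigma = lognormal_params(cfg.photon_mode, cfg.photon_mean)
    photons = rng.lognormal(mu, sigma, n)
    precision = cfg.precision_coeff / np.sqrt(photons)
    xy = origins + rng.normal(0, precision[:, None], (n, 2))
    frames = rng.integers(0, int(cfg.duration_s * cfg.fps), n)

    df = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "photons": photons,
            "frame": frames,
            "precision_nm": precision,
            "probe": cfg.probe,
        }
    )
    ledger = {
        "preset": cfg.name,
        "n_channels": n_ch,
        "n_dark": int(dark.sum()),
        "channel_positions": positions,
        "blinks_per_channel": blinks,
        "blink_channel": blink_channel,
        "n_background": int(n_bg),
    }
    return LocalizationSet(df), ledger


# ---------------------------------------------------------------------------
# mini-amplitude mixtures


@dataclass(frozen=True)
class QuantalSimConfig:
    """Three-component quantal mixture of mini amplitudes.

    Component ``k`` (k = 1, 2, 3 quanta) has mean ``k * mode`` and
    standard deviation ``sigma1 * sqrt(k)`` (independent quanta sum their
    variances); amplitudes are truncated positive.
    """

    name: str
    mode: float  # single-quantum amplitude, pA
    weights: tuple[float, float, float]
    sigma1: float = 2.0  # pA
    noise_sd: float = 0.0  # additive baseline noise, pA

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.mode <= 0 or self.sigma1 < 0:
            raise ValueError("mode must be positive and sigma1 non-negative")


NEMADIPINE_PRESET = QuantalSimConfig(
    name="nemadipine", mode=7.0, weights=(0.67, 0.18, 0.15)
)
DANTROLENE_NEMADIPINE_PRESET = QuantalSimConfig(
    name="dantrolene_nemadipine", mode=6.0, weights=(0.75, 0.15, 0.10)
)


def simulate_minis(
    cfg: QuantalSimConfig, n_events: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw mini amplitudes from the quantal mixture.

    Returns ``(amplitudes_pa, true_class)`` where class is the number of
    quanta (1-3) behind each event.  Non-positive draws are resampled
    within their class (truncation at 0).
    """
    rng = _rng(seed)
    classes = rng.choice([1, 2, 3], size=n_events, p=cfg.weights)
    amps = rng.normal(classes * cfg.mode, cfg.sigma1 * np.sqrt(classes))
    if cfg.noise_sd > 0:
        amps = amps + rng.normal(0, cfg.noise_sd, n_events)
    while (amps <= 0).any():
        bad = amps <= 0
        amps[bad] = rng.normal(
            classes[bad] * cfg.mode, cfg.sigma1 * np.sqrt(classes[bad])
        )
        if cfg.noise_sd > 0:
            amps[bad] += rng.normal(0, cfg.noise_sd, int(bad.sum()))
    return amps, classes


# ---------------------------------------------------------------------------
# docked-vesicle tables

#: Default per-bin mean docked vesicles per synapse (33 nm bins from the
#: dense projection out to 594 nm): enriched near the dense projection
#: with a long lateral tail.
DEFAULT_DOCKED_PROFILE = np.array(
    [1.8, 1.3, 1.0, 0.85, 0.75, 0.65, 0.6, 0.55, 0.5, 0.45,
     0.4, 0.38, 0.35, 0.32, 0.3, 0.28, 0.26, 0.24]
)


def simulate_vesicle_profiles(
    n_synapses: int,
    profile: np.ndarray = DEFAULT_DOCKED_PROFILE,
    depletion: np.ndarray | float = 0.5,
    seed=0,
    genotype: str = "synthetic",
    bin_nm: float = 33.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired unstimulated/stimulated docked-vesicle distance tables.

    Per synapse and 33 nm bin, docked counts are Poisson around
    ``profile``; the stimulated cohort is an independent set of synapses
    in which each vesicle fuses (is removed) with its bin's depletion
    probability.  Distances are uniform within their bin.  Returns
    ``(no_stim, stim)`` tables with columns ``synapse_id, genotype,
    condition, distance_nm``.
    """
    rng = _rng(seed)
    profile = np.asarray(profile, dtype=float)
    depletion = np.broadcast_to(np.asarray(depletion, dtype=float), profile.shape)
    if ((depletion < 0) | (depletion > 1)).any():
        raise ValueError("depletion fractions must lie in [0, 1]")

    def cohort(condition: str, thin: bool) -> pd.DataFrame:
        rows = []
        for s in range(n_synapses):
            counts = rng.poisson(profile)
            if thin:
                counts = rng.binomial(counts, 1.0 - depletion)
            for b, c in enumerate(counts):
                for d in rng.uniform(b * bin_nm, (b + 1) * bin_nm, c):
                    rows.append((f"{condition}_{s}", genotype, condition, d))
            if counts.sum() == 0:  # keep empty synapses visible
                rows.append((f"{condition}_{s}", genotype, condition, np.nan))
        df = pd.DataFrame(
            rows, columns=["synapse_id", "genotype", "condition", "distance_nm"]
        )
        return df

    return cohort("no_stim", False), cohort("stim", True)


# ---------------------------------------------------------------------------
# worm tracks


def simulate_tracks(
    n_worms: int,
    fps: float = 8.0,
    duration_s: float = 300.0,
    forward_speed_um_s: float = 300.0,
    speed_sd_um_s: float = 40.0,
    forward_bout_mean_s: float = 30.0,
    backward_bout_mean_s: float = 2.2,
    pause_bout_mean_s: float = 1.5,
    pause_prob: float = 0.2,
    seed=0,
) -> tuple[list[Track], list[list[tuple[str, int, int]]]]:
    """Semi-Markov bout model of worm crawling.

    Worms alternate forward bouts with reversals (and occasional pauses),
    with exponential bout durations.  Heading diffuses slowly; backward
    frames move against the heading.  Returns the tracks and, per worm,
    the true bout list as ``(state, start_frame, end_frame_inclusive)``.

    Setting ``backward_bout_mean_s = 0`` disables reversals entirely.
    """
    rng = _rng(seed)
    n_frames = int(round(duration_s * fps))
    dt = 1.0 / fps
    tracks: list[Track] = []
    ledgers: list[list[tuple[str, int, int]]] = []
    for w in range(n_worms):
        states: list[str] = []
        bouts: list[tuple[str, int, int]] = []
        frame = 0
        state = "forward"
        while frame < n_frames:
            if state == "forward":
                mean = forward_bout_mean_s
            elif state == "backward":
                mean = backward_bout_mean_s
            else:
                mean = pause_bout_mean_s
            length = max(1, int(round(rng.exponential(mean) * fps))) if mean > 0 else 0
            if length == 0:
                state = "forward"
                continue
            length = min(length, n_frames - frame)
            states.extend([state] * length)
            bouts.append((state, frame, frame + length - 1))
            frame += length
            if state == "forward":
                if backward_bout_mean_s > 0 and rng.uniform() > pause_prob:
                    state = "backward"
                elif pause_bout_mean_s > 0:
                    state = "pause"
            else:
                state = "forward"

        direction = np.array(states, dtype=object)
        heading = rng.uniform(0, 2 * np.pi)
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        x[0] = y[0] = 0.0
        for i in range(1, n_frames):
            heading += rng.normal(0, 0.08)
            st = states[i - 1]
            if st == "pause":
                speed = abs(rng.normal(0, 5.0))
            else:
                speed = max(25.0, rng.normal(forward_speed_um_s, speed_sd_um_s))
            sign = -1.0 if st == "backward" else 1.0
            x[i] = x[i - 1] + sign * speed * dt * np.cos(heading)
            y[i] = y[i - 1] + sign * speed * dt * np.sin(heading)
        tracks.append(
            Track(
                worm_id=f"worm_{w}",
                t_s=np.arange(n_frames) * dt,
                x_um=x,
                y_um=y,
                direction=direction,
            )
        )
        ledgers.append(bouts)
    return tracks, ledgers


# ---------------------------------------------------------------------------
# nerve-cord fields of view


def simulate_cord(
    n_synapses: int = 10,
    spacing_um: float = 1.10,
    spacing_sd_um: float = 0.16,
    fiducial: str = "ELKS",
    fiducial_n: int = 200,
    fiducial_sigma_nm: float = 75.0,
    targets: dict | None = None,
    seed=0,
) -> tuple[LocalizationSet, dict]:
    """A stretch of nerve cord with regularly spaced synaptic clusters.

    Fiducial (dense-projection marker) clusters are laid out along a
    line with Gaussian inter-cluster spacing; each target probe adds a
    cluster at a per-probe radial offset from the fiducial center.
    ``targets`` maps probe label -> ``(n_locs, sigma_nm, offset_nm)``.
    The ledger records true cluster centers and per-probe counts.
    """
    rng = _rng(seed)
    targets = targets or {}
    gaps = rng.normal(spacing_um * 1000.0, spacing_sd_um * 1000.0, n_synapses - 1)
    centers_1d = np.concatenate([[0.0], np.cumsum(gaps)])
    angle = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(angle), np.sin(angle)])
    centers = centers_1d[:, None] * axis[None, :]

    frames_total = 3000
    rows = []
    per_synapse_counts: list[dict] = []
    for c in centers:
        counts = {}
        pts = c + rng.normal(0, fiducial_sigma_nm, (fiducial_n, 2))
        rows.append(_probe_frame(rng, pts, fiducial, frames_total))
        counts[fiducial] = fiducial_n
        for probe, (n_locs, sigma, offset) in targets.items():
            th = rng.uniform(0, 2 * np.pi)
            off = offset * np.array([np.cos(th), np.sin(th)])
            pts = c + off + rng.normal(0, sigma, (n_locs, 2))
            rows.append(_probe_frame(rng, pts, probe, frames_total))
            counts[probe] = n_locs
        per_synapse_counts.append(counts)

    df = pd.concat(rows, ignore_index=True)
    ledger = {
        "centers": centers,
        "spacings_nm": np.linalg.norm(np.diff(centers, axis=0), axis=1),
        "per_synapse_counts": per_synapse_counts,
    }
    return LocalizationSet(df), ledger


def _probe_frame(rng, pts, probe, frames_total) -> pd.DataFrame:
    n = len(pts)
    mu, sigma = lognormal_params(575.0, 765.0)
    photons = rng.lognormal(mu, sigma, n)
    return pd.DataFrame(
        {
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
            "photons": photons,
            "frame": rng.integers(0, frames_total, n),
            "precision_nm": 500.0 / np.sqrt(photons),
            "probe": probe,
        }
    )
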