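# Methods

This note documents the models behind each analysis, the tunable
parameters and their defaults, what the synthetic generators do and do
not emulate, and the numerical choices made where the design was open.

## Localization tables and ROIs

A localization record is one blink: `x_nm, y_nm, (z_nm), photons, frame,
precision_nm, probe`. Coordinates are absolute nanometers in the camera
frame; vendor exports in other units or column names are mapped through
a `Dialect`. z is discarded before analysis (`flatten_z`): multi-color
axial registration is unreliable due to chromatic aberration, and all
geometry here is 2D, assuming synapses imaged en face.

Standard filtering keeps blinks localized to 80 nm or better
(Cramér–Rao lower bound), inclusive at the boundary — the choice of
inclusive vs exclusive only moves records sitting exactly on the
threshold.

A synapse ROI is the set of localizations (all probes) within 700 nm of
a fiducial cluster center, the fiducial being a dense-projection marker
such as ELKS. Dorsal-cord synapses average ~580 nm across, so a 700 nm
window captures a synapse with margin while excluding neighbors at the
~1 µm cluster spacing. Fiducial clusters are found by 1D gap-linking
along the cord's principal component (split at gaps > 250 nm, keep runs
of ≥ 20 localizations; both thresholds are configurable — the gap must
sit well above intra-cluster spacing and below inter-synapse spacing).
Ambiguous localizations go to the nearest center, ties to the lower ROI
id. The 700 nm window applies to every probe, not only the fiducial.

## Cluster geometry

For an origin and a target probe in one ROI, the analysis axis is the
unit vector between the two cluster centers of mass; every localization
gets a signed scalar projection onto it, with the origin center at 0.
Profiles use half-open 33 nm bins with an edge anchored at 0, matching
the electron-microscopy section thickness so optical and EM profiles
are directly comparable.

"Diameter" is the width of the central 95% interval of a probe's axial
coordinates about its own center (97.5th − 2.5th percentile, linear
interpolation). This is a spread measure: for a Gaussian cluster it
equals 3.92 σ. The alternative — 95% interval of radial distances —
was rejected because radial distances cannot be negative and would
halve apparent widths relative to the axial convention.

The overlap statistic (`fraction_within`) is the fraction of one
probe's axial coordinates inside another probe's central-95% interval,
pooled across synapses by default (per-synapse averaging is available
by calling it per ROI).

## Nearest-neighbor colocalization

First nearest neighbor only (k = 1), 2D Euclidean, inclusive threshold
(default 100 nm), computed within each synapse ROI and pooled across
ROIs. The measure is directional: RyR→CaV1 asks whether every RyR sits
near some CaV1; the reverse asks the opposite question, and the two
fractions generally differ.

## Channel counting

SMLM observes blinks, not molecules. Three estimators convert blink
counts to channel counts:

1. **Blink mean.** Blinks within 60 nm are grouped by DBSCAN
   (`eps = 60`, `min_pts = 2`); noise points are promoted to singleton
   groups, since a solitary blink still marks one channel. The 60 nm
   radius sits above the achievable resolution (~40 nm) and below
   typical channel spacing for dispersed channels. The Poisson mean of
   grouped blink counts is the sample mean (its MLE); no
   zero-truncation correction is applied in the estimator — invisible
   channels are simply absent — while the generator draws from the
   truncated law so that the observable mean matches. Channel count =
   total blinks / m, with m pooled across the cohort.
2. **Photon flux.** Synapse photon total / pooled mean photons per
   grouped channel. The pooled mean must come from the whole cohort:
   computed per synapse the estimator degenerates to the group count.
3. **Blink rate.** Total blinks / (rate × duration), default 6
   blinks/min per fluorophore — for dense clusters where grouping is
   impossible because localizations overlap.

When per-synapse estimates from (1) and (2) are averaged over the same
cohort that supplied the pooled denominators, both reduce algebraically
to (total groups)/(n synapses) and coincide exactly. On real data from
multiple sessions the two differ, because photophysics varies across
sessions while the pooled denominators do not.

**Packing bounds.** Capacity of a circular cluster for circular
channels: for container/channel diameter ratios within the published
optimal packings (N ≤ 20) the table answer is exact; beyond it, a
hexagonal lattice with spacing equal to the channel diameter, one
lattice point at the container center and fixed orientation, is
enumerated. No offset/rotation search is attempted: the lattice count
is reproducible and within one circle of the area-density estimate
(e.g. 20 nm circles in a 250 nm cluster: 121 by lattice enumeration,
~119–120 by density).

## Quantal decomposition

Mini amplitudes are binned at 1 pA (half-open bins anchored at 0; the
mode is reported as the lower edge of the peak bin, ties to the lowest
bin). The histogram is fit by nonlinear least squares with a sum of
`n_terms` Gaussians. Term k's mean is box-constrained to
`[k(mode−1), k(mode+1)]` — the single-quantum amplitude sets the comb,
with ±k pA slack at term k. Amplitude coefficients are free and
non-negative.

Widths are tied by default to the quantal scaling `σ_k = σ₁√k` with σ₁
free: the amplitude of a k-quantum event is the sum of k independent
single-quantum amplitudes, so its variance is k times the
single-quantum variance. This tie is not merely cosmetic. With fully
free widths the binned least-squares problem is weakly identified when
neighboring components overlap: the optimizer can widen one term into
its neighbor's support and trade that against counting noise in the
high-count peak bins, and the resulting first-component fraction is
bimodal across random samples (spread ~12 percentage points at
n = 20,000 events with σ₁ = 2 pA). With tied widths the recovered
fractions are stable to better than 1 percentage point at the same
sample size, and unbiased on generator mixtures. The fully free fit
remains available (`tie_widths=False`) for comparison with legacy
analyses; Poisson-weighted least squares was also evaluated and does
not rescue the free-width fit.

The fit runs nine deterministic starts (three mean offsets × three
width scales) and keeps the best residual. Per-term area fractions come
from trapezoidal integration of each fitted term over the histogram
support at 0.1 pA resolution; the multiquantal fraction is
`1 − fraction₁`. Fractions are invariant to uniform rescaling of the
histogram, so fitting counts vs normalized frequencies is immaterial.

## Docked-vesicle fusion profiles

The synapse is the statistical unit: per-synapse 33 nm histograms of
docked-vesicle distance from the dense projection are averaged within
condition, and the fusion profile is the per-bin difference of means
(unstimulated − stimulated). Negative differences (apparent docking
increase) are reported, never clipped. Zones are 0–33, 33–165 and
165–594 nm; zone release probability is (lost vesicles)/(baseline
vesicles) on zone totals and is flagged undefined where the baseline is
empty. Distances are consumed as annotated; no re-projection of the
micrograph geometry is attempted.

## Locomotion

Tracks are centroid positions at 8 frames/s for a nominal 5 min.
Exclusion rules: leaving the field of view before 180 s, or
pause-excluded mean speed below 100 µm/s. A reversal is a maximal run
of backward frames lasting strictly more than 4 frames (> 500 ms at
8 fps). Pause frames are those below 20 µm/s — the assay excludes
pauses from speed but states no threshold, so 20 µm/s (well below
crawling speeds, above tracker jitter) is the documented, configurable
default. Direction labels come from the tracker or generator; head–tail
inference is out of scope.

## Synthetic generators

All generators take a seed (or `numpy` Generator) and return a
ground-truth ledger; identical seeds give identical outputs.

**Blinking.** Observable blinks per channel are zero-truncated Poisson
parameterized by the observed mean (default 2.7): a channel with zero
blinks is unobservable, so the generator is self-consistent with the
estimator that fits plain-Poisson to observed groups. The underlying
rate solves λ/(1−e^{−λ}) = 2.7, giving λ ≈ 2.472. A dark-channel
fraction (default 0) supports labeling-efficiency bias studies.

**Photons and precision.** Photons per blink are log-normal — the
minimal right-skewed two-parameter law matching the observed mode (575)
and mean (765): σ² = ⅔·ln(mean/mode), μ = ln(mode) + σ². Precision is
c/√photons with c = 500 nm·photons^½, mapping the photon mode to
~21 nm and typical blinks to 15–30 nm, all comfortably inside the 80 nm
filter. Blink times are uniform over the 60 s session; no
photobleaching decay is modeled.

**Channel placement.** The dense-cluster model is uniform in a disc
(CaV2 preset: 101 channels, 275 nm). The dispersed model is a hard-core
point process: uniform proposals in a disc, rejected within 100 nm of
an accepted channel (CaV1 preset: 79 channels over a 1400 nm
varicosity-scale disc; RyR preset: 29 channels over 869 nm). The hard
core encodes the working assumption behind blink grouping — that
dispersed channels are individually resolvable at the 60 nm criterion.
This is a deliberate idealization: real dispersed channels also form
small subclusters, and in that regime grouping merges neighbors and
the blink-mean estimator undercounts. Passing recovery tests on this
generator therefore shows the estimators are correct in the resolvable
regime, not that real data is free of merging bias. (Placements dense
enough to defeat the 60 nm criterion — e.g. 79 channels confined to an
869 nm disc — are inconsistent with a fitted blink mean of ~2.7, which
matches single-fluorophore statistics only when grouped objects are
single channels.)

**Minis.** Each event draws a quantal class k ∈ {1, 2, 3} with preset
weights, then an amplitude from N(k·mode, σ₁√k), truncated positive by
in-class resampling. Presets: mode 7 pA with weights (0.67, 0.18, 0.15)
and mode 6 pA with weights (0.75, 0.15, 0.10). σ₁ = 2 pA is a generator
default (no measured value is available), and at mode 6 it makes
neighboring components overlap substantially — deliberately a hard case
for the decomposition.

**Docked vesicles.** Per-synapse, per-bin counts are Poisson around a
mean profile (default: enriched near the dense projection, long lateral
tail, ~10 docked vesicles per synapse); the stimulated cohort is an
independent set of synapses with each vesicle removed with its bin's
depletion probability (binomial thinning), so planted depletion is the
recoverable release probability.

**Tracks.** A semi-Markov bout model alternates forward bouts
(exponential, mean 30 s), reversals (mean 2.2 s) and pauses (mean
1.5 s), with slowly diffusing heading and Gaussian speed (default
300 ± 40 µm/s). The ledger records exact bout boundaries. Not modeled:
body posture, omega turns, track noise from skeletonization.

**Cord fields.** Fiducial clusters (Gaussian, σ = 75 nm) are laid along
a line with Gaussian spacing (default 1.10 ± 0.16 µm); target probes
add clusters at per-probe radial offsets. Nearby synapse pairs drawn
closer than the gap-linking threshold merge in detection — a real
ambiguity the tests tolerate by comparing against the ledger.

## Problem sizes and tolerances

End-to-end recovery checks run 1000 synapses for the counting presets
(estimator means land within ~2 channels of truth), 10,000 channels for
the Poisson fit (SE ≈ 0.014), and 20,000 events for the quantal fits
(first-component fraction stable to < 1 pp with tied widths). Property
tests use exact oracles (O(n²) nearest neighbors, lattice enumeration,
closed-form track metrics) or 3-SEM statistical bands.

## Known limitations

- Grouping-based counting assumes resolvable channels; dense clusters
  must use the blink-rate route, which inherits the uncertainty of the
  assumed per-fluorophore blink rate.
- The quantal fit with free widths is weakly identified (see above);
  with tied widths it assumes quantal variance additivity.
- The hex-lattice packing bound is a fixed-orientation construction,
  not a certified optimum, for counts beyond the published N ≤ 20
  table.
- Localization tables are trusted as given: no drift correction,
  chromatic registration, or raw-frame fitting.
- EM distances are in-section annotations; 3D reconstruction is out of
  scope.
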