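"""Decompose a miniature-current amplitude distribution into quantal components.

Draws 20,000 mini amplitudes from a three-component mixture (single,
double and triple vesicle fusions at 7 / 14 / 21 pA), then recovers the
per-component fractions with the constrained three-Gaussian histogram fit.
"""

import numpy as np

from synaptoscope import synthgen
from synaptoscope.quantal import (
    amplitude_histogram,
    fit_quantal_gaussians,
    modal_amplitude,
    multiquantal_fraction,
)

cfg = synthgen.NEMADIPINE_PRESET  # mode 7 pA, weights 67/18/15 %
amps, _ = synthgen.simulate_minis(cfg, 20_000, seed=2)

edges, counts, _ = amplitude_histogram(amps)
print(f"histogram mode: {modal_amplitude(edges, counts):.0f} pA (planted {cfg.mode:.0f} pA)")

fit = fit_quantal_gaussians(edges, counts, cfg.mode)
print(f"component means: {np.round(fit.means, 1).tolist()} pA (expected ~7, 14, 21)")
print(f"area fractions:  {np.round(100 * fit.fractions, 1).tolist()} % "
      f"(planted {[100 * w for w in cfg.weights]})")
print(f"multiquantal fraction: {100 * multiquantal_fraction(fit.fractions):.0f} % "
      "— the share of events releasing more than one vesicle")
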