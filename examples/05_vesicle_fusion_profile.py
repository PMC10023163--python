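"""Spatial fusion profile of docked vesicles from stimulated vs unstimulated synapses.

Simulates docked-vesicle distance tables for two cohorts where only
vesicles beyond 165 nm of the dense projection fuse (a lateral-release
pattern), then recovers the per-zone release probabilities.
"""

import numpy as np

from synaptoscope import synthgen
from synaptoscope.emprofile import bin_docked, fusion_profile, zone_summary

depletion = np.zeros(18)        # 18 x 33 nm bins out to 594 nm
depletion[5:] = 0.45            # fusion restricted beyond 165 nm

no_stim, stim = synthgen.simulate_vesicle_profiles(
    300, depletion=depletion, seed=5
)
profile = fusion_profile(bin_docked(no_stim), bin_docked(stim))
zones = zone_summary(profile)

print(zones[["zone", "docked_no_stim", "docked_stim", "release_probability"]]
      .to_string(index=False))
print("release probability ~0 near the dense projection and ~0.45 laterally "
      "reproduces the planted lateral-release pattern")
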