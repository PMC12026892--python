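"""Classify hub-locus interaction durations with a Gaussian mixture.

Samples 2,000 dwell times from the *snail* nc14 reference mixture (short /
mid / long-lived hub contacts), fits the three-component mixture, and prints
the recovered component means alongside the generating values, plus the
survival curve at a few durations.
"""

import numpy as np

from hubburst import fit_dwell_mixture, sample_dwell_times, survival_curve
from hubburst.conditions import DWELL_NC14

mix = DWELL_NC14["sna"]
durations = sample_dwell_times(mix, 2000, seed=1)
fit = fit_dwell_mixture(durations, seed=1)

print("snail nc14 dwell-time mixture (minutes)")
for name, got, want, w in zip(
    ("short", "mid", "long"), fit.means_min, mix.means_min, fit.weights
):
    print(f"  {name:5s}: recovered {got:6.3f}  generating {want:6.2f}  weight {w:.2f}")
print(f"  class boundaries at {np.round(fit.class_boundaries_min, 2)} min")

grid, surv = survival_curve(durations)
for t in (0.5, 2.0, 10.0):
    s = surv[np.searchsorted(grid, t, side="right") - 1]
    print(f"  fraction of contacts lasting >= {t:4.1f} min: {s:.3f}")

# The long-lived component mean near 10 minutes is what distinguishes a
# strongly hub-retaining target gene from transient non-target contacts
# (~3 minutes); the survival curve shows the same tail directly.
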