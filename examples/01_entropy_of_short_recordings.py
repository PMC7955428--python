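"""Distribution entropy of short RR-interval series.

Builds three ~2-minute heartbeat recordings of increasing complexity and
computes DistEn (m=3, tau=1, B=256) for each.  DistEn lies in [0, 1]:
a perfectly regular series scores 0, and richer beat-to-beat structure
pushes the value toward 1.  Unlike sample/approximate entropy it needs no
distance threshold, so ~120 beats are enough for a stable estimate.
"""

import numpy as np

from disten import distribution_entropy, generate_rri
from disten.synth import rri_params_for_complexity

constant = np.full(120, 850.0)
low = generate_rri(rri_params_for_complexity(0.1, mean_rri=850, n_beats=120, seed=1))
high = generate_rri(rri_params_for_complexity(0.9, mean_rri=850, n_beats=120, seed=1))

for name, series in [("constant", constant), ("low complexity", low), ("high complexity", high)]:
    result = distribution_entropy(series)
    print(f"{name:16s} DistEn = {result.value:.3f}  ({result.n_beats_used} beats)")

print()
print("A constant rhythm has zero entropy; the low-complexity record's slow")
print("set-point shifts concentrate its distance histogram, while the noisy,")
print("respiration-modulated record spreads it toward the uniform limit.")
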