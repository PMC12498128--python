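"""Cluster-based permutation t test on an electrode x frequency grid.

A +1 SD effect is planted on a frontal patch of one group; the test forms
clusters of bins with uncorrected p < 0.001 over the montage's spatial and
+-1 Hz spectral adjacency and compares each cluster's summed t (Tsum)
against the permutation distribution of the largest |Tsum|.
"""

import numpy as np

from assrshift.calibration import smoothed_null_data
from assrshift.cluster import permutation_p
from assrshift.montage import CHANNELS, spatio_spectral_adjacency

n_freqs = 30  # e.g. 4-33 Hz at 1 Hz bins
graph = spatio_spectral_adjacency(n_freqs)
rng = np.random.default_rng(0)

values = smoothed_null_data(rng, 60, graph)  # 30 + 30 subjects
patch = [CHANNELS.index(c) * n_freqs + f
         for c in ("F3", "Fz", "F4") for f in range(5, 15)]
values[:30, patch] += 1.0
labels = np.arange(60) < 30

result = permutation_p(values, "unpaired", graph, labels,
                       n_permutations=500, seed=0)
for c in result.significant(0.05):
    chans = sorted({CHANNELS[m // n_freqs] for m in c.members})
    freqs = [m % n_freqs + 4 for m in c.members]
    print(f"significant cluster: p = {c.p:.3f}, Tsum = {c.tsum:.1f}, "
          f"{len(c.members)} bins over {chans}, {min(freqs)}-{max(freqs)} Hz")
# p is the fraction of random group relabelings whose largest cluster
# statistic beats this cluster's; members should recover the planted patch.
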