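"""Derive stability classes from a 7-bin FACS stability table.

Simulates a small GPSP-style table with three planted groups, clusters the
normalized bin distributions (complete linkage, Euclidean distance), cuts
the tree into three groups and labels the extremes. Prints the class sizes
and per-class mean PSI — the bin-weighted stability index in [1, 7], which
should rise monotonically from the unstable to the stable class.
"""

import numpy as np

from stabnet.simulate import FixtureConfig, simulate_gpsp
from stabnet.stability_classes import assign_classes, cluster_distributions

config = FixtureConfig(gpsp_counts=(40, 120, 40))
records, planted = simulate_gpsp(config, seed=0)

dendrogram = cluster_distributions(records)
assignments = assign_classes(dendrogram, records, k=3)

print(f"{len(records)} proteins clustered into 3 groups\n")
for label in ("unstable", "non_assigned", "stable"):
    psi = [a.psi for a in assignments if a.label == label]
    print(f"  {label:>13}: n = {len(psi):3d}   mean PSI = {np.mean(psi):.2f}")

correct = sum(a.label == p for a, p in zip(assignments, planted))
print(f"\nagreement with the planted grouping: {correct}/{len(records)}")
print("mean PSI must increase from unstable to stable — PSI is a weighted")
print("mean over bins R1..R7, and stable proteins concentrate in R5-R7.")
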