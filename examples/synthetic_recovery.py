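"""Validate the pipeline end to end on synthetic data with known truth.

Simulates paired population/stroma profiles (200 genes, 3 replicate arrays)
with 20 planted receptor-ligand pairs and 20 unmatchable decoys, then runs
the differential-expression gate (Welch t, p < 0.01) and the matcher, and
scores recall and false-discovery proportion against the planted truth.
"""

import numpy as np

from ligrec import SimulationConfig, recover_planted_pairs, simulate

recalls, fdps = [], []
for seed in range(10):
    sim = simulate(SimulationConfig(seed=seed))
    recall, fdp = recover_planted_pairs(sim, alpha=0.01)
    recalls.append(recall)
    fdps.append(fdp)
    print(f"seed {seed}: recall {recall:.2f}, FDP {fdp:.2f}")

print(
    f"\nmean recall {np.mean(recalls):.3f}, mean FDP {np.mean(fdps):.3f} "
    "(planted 32-fold boosts are unmissable at these noise levels; decoys are"
    " blocked by their absent partner)"
)
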