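"""Genetic-algorithm descriptor selection against decoy descriptors.

Plants the generating descriptor among 50 random per-donor decoys and lets
the seeded GA pick one descriptor (beyond the forced lnP and T columns) by
leave-one-out Q2.  The planted descriptor should win, and the run is fully
reproducible from its seed.
"""

import numpy as np

from desqspr import (
    GAConfig,
    SynthSpec,
    build_design,
    ga_select,
    reference_eeig02d,
    synth_generate,
)

seed = 7
rng = np.random.default_rng(seed + 1000)
dataset = synth_generate(SynthSpec(sigma=0.05, seed=seed))
lookup = reference_eeig02d()
X, y = build_design(dataset, lookup)
donors = [r.hbd for r in dataset.records]
for k in range(50):
    per_donor = {h: rng.normal() for h in lookup}
    X[f"decoy{k:02d}"] = [per_donor[h] for h in donors]

result = ga_select(X, y, forced=("lnP", "T"), cfg=GAConfig(seed=seed))
print(f"candidates: {X.shape[1] - 2} (1 planted + 50 decoys)")
print(f"selected:   {result.selected}  (fitness Q2_LOO = {result.fitness:.4f})")
print(f"fit R2 = {result.fit.r2:.4f}; generations to best: "
      f"{result.history.index(max(result.history))}")
print("\nThe GA recovers the planted structural descriptor because no random")
print("per-donor decoy explains the cross-donor solubility differences as well.")
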