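"""Replicate quality control and smoothing for FTIR-style spectra tables.

Each sample is measured in triplicate; a group is kept only when every
replicate pair correlates at rho >= 0.95, survivors are averaged and
smoothed with a length-15 Savitzky-Golay filter, and the water-vapour
absorption windows (2200-2270, 3200-3700 1/cm) are masked out.
"""

import numpy as np

from brierscoremf import ReplicateGroup, preprocess_replicates

rng = np.random.default_rng(0)
wn = np.linspace(900, 3900, 200)
base = np.exp(-((wn - 1650) / 80.0) ** 2) + 0.6 * np.exp(-((wn - 2900) / 150.0) ** 2)

groups = []
for i in range(5):
    sample = base * rng.uniform(0.8, 1.2)  # concentration varies per sample
    reps = sample + rng.normal(scale=0.002, size=(3, wn.size))
    groups.append(ReplicateGroup(f"patient{i}", reps, wavenumbers=wn))
# one corrupted acquisition: a replicate that lost its spectral shape
bad = np.vstack([base, base, rng.permutation(base)])
groups.append(ReplicateGroup("patient5", bad, wavenumbers=wn))

X, qc = preprocess_replicates(groups, rho_min=0.95, window=15, polyorder=3,
                              water_regions=[(2200, 2270), (3200, 3700)])
for res in qc:
    state = "kept" if res.passed else f"rejected ({res.reason})"
    print(f"{res.sample_id}: {state}")
print(f"\nprocessed table: {X.n_samples} samples x {X.n_channels} channels "
      f"(of {wn.size} raw channels; the rest fell in water windows)")
# each surviving row is the smoothed replicate average, ready for training
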