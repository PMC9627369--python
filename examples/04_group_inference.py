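"""Voxelwise PD-vs-HC contrast with FDR and cluster-extent control.

Simulates a small cohort with reduced PD connectivity in compact target
clusters, fits the voxelwise GLM with nuisance covariates, and shows the
surviving significance network and its cluster table.
"""

import numpy as np

from nacfc import SimulationSpec, assign_targets, generate_atlas, generate_bold, generate_cohort, qc_filter
from nacfc.fc import seed_fc_maps
from nacfc.glm import significance_network, voxelwise_group_contrast

spec = SimulationSpec(n_pd=40, n_hc=40, n_timepoints=150, seed=1)
atlas = generate_atlas(seed=1)
targets = assign_targets(atlas, spec)
cohort, _ = qc_filter(generate_cohort(spec), flag_col=None,
                      fd_threshold=float("inf"))

maps = []
for _, row in cohort.iterrows():
    bold = generate_bold(row, atlas, targets, spec)
    maps.append(seed_fc_maps(bold, atlas, seeds=["core_L"])["core_L"])

res = voxelwise_group_contrast(maps, cohort,
                               covariates=("sex", "age", "education", "mean_fd"))
sig = significance_network(res, q=0.05, k_min=20)

tgt = targets["core_L"]
dice = 2 * np.sum(sig.mask & tgt) / (sig.mask.sum() + tgt.sum())
print(f"seed core_L: {sig.n_voxels} voxels survive FDR q=0.05, extent >= 20")
print(f"median t inside the recovered network: "
      f"{np.median(res.t_map[sig.mask]):.2f} (PD - HC)")
print(f"Dice overlap with the planted target set: {dice:.2f}\n")
print(sig.cluster_table(res.t_map).to_string(index=False))
print("\nNegative peak t values: PD connectivity is reduced, as planted.")
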