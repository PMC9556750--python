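"""Simulate a paired two-region single-cell study with planted truth.

Generates a small version of the emulated design — 3 patients, one
atherosclerotic-core (AC) and one proximal-adjacent (PA) sample each,
six cell types with exclusive markers — spikes in 5% cross-type
doublets, and writes the 10x-style triplet plus the ground-truth tables.
"""

from pathlib import Path

import scpcnet as s

cfg = s.SimConfig(
    cells_per_sample={"AC": 300, "PA": 120},
    n_genes=300,
    seed=0,
)
adata, truth = s.generate_cells(cfg)
adata, truth = s.spike_doublets(adata, truth, rate=0.05)

out = Path("scratch/example_dataset")
s.write_matrix(adata, out)
s.synthetic.write_truth(truth, out / "truth")

print(f"cells: {adata.n_obs}  genes: {adata.n_vars}")
print(f"samples: {sorted(adata.obs['sample'].unique())}")
print(f"spiked doublets: {int(truth.is_doublet.sum())}")
print(f"cell types: {truth.cell_types.value_counts().to_dict()}")
# Each count is a negative-binomial UMI draw; cell types differ by
# marker programs, and the doublets are sums of two cross-type cells.
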