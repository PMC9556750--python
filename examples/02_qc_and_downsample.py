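"""Quality control and per-sample equalizing downsampling.

Cells with >10% mitochondrial UMIs, or with <200 or >4000 detected
genes, are removed (boundaries retained); then every sample is
downsampled to the same quota so cell-type discovery is not dominated
by the larger AC samples.
"""

import scpcnet as s

cfg = s.SimConfig(
    cells_per_sample={"AC": 400, "PA": 150}, n_genes=2000, seed=1
)
adata, _ = s.generate_cells(cfg)

filtered, report = s.qc_filter(adata, mito_max=0.10, min_genes=200,
                               max_genes=4000)
print(f"cells in: {report.cells_in}  out: {report.cells_out}")
print(f"removed  mito: {report.removed_mito}  low-genes: "
      f"{report.removed_low_genes}  high-genes: {report.removed_high_genes}")

down = s.downsample_equal(filtered, total_cells=600, seed=0)
print(down.obs["sample"].value_counts().to_dict())
# Every sample now contributes exactly 100 cells, mirroring the study's
# downsampling of 6 samples to 17,100 cells (2,850 per sample).
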