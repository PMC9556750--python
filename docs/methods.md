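# Methods

This note records the models, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## Pipeline model

The analysis contrasts two anatomic regions (atherosclerotic core, AC, and
proximal-adjacent artery, PA) sampled pairwise from each patient:

1. **QC** removes cells with a mitochondrial UMI fraction above 10%, or
   fewer than 200 or more than 4,000 detected genes. All three boundaries
   are *retained* — removal uses strict inequalities — and a failing cell is
   accounted once, under the first failing rule in the order
   mito → too-few → too-many. Detected means UMI ≥ 1; the mito fraction is
   computed on raw UMIs before any normalization.
2. **Equal downsampling** draws the same quota per sample (e.g., six samples
   to 17,100 cells = 2,850 each), so unsupervised cell-type discovery is not
   dominated by the larger AC samples. A sample below quota keeps all of its
   cells with a warning; the shortfall is never re-allocated to other
   samples.
3. **Partitioning** clusters cells by modularity (Leiden optimization of the
   modularity objective) on a k-nearest-neighbor graph built in PC space of
   log1p depth-normalized expression. Graph partitioning was chosen over
   clustering in a 2-D embedding because it is deterministic given a seed
   and directly testable; low-dimensional visual embeddings are out of
   scope. Partition markers are genes expressed (UMI ≥ 1) in >80% of the
   partition's cells at mean raw count >2 (strict); partitions are labeled
   by majority vote of a user-supplied reference marker table, ties and
   no-hit partitions becoming "unassigned". Partitions below 50 cells are
   too small for differential expression and are dropped.
4. **Doublet filtering** is marker exclusion: a gene expressed in >90% of
   one partition and <10% of every other is an exclusion marker of that
   partition; a cell expressing ≥2 exclusion markers of *foreign* partitions
   is tagged for removal. Flags are validated by the upward shift of total
   UMI in flagged cells (one-sided rank-sum). Sub-threshold partitions are
   excluded from both sides of the marker scan: they are frequently doublet
   clusters themselves, and counting them in the rarity scan lets a doublet
   cluster veto its parents' markers.
5. **Differential expression** fits, per gene, an OLS of standardized
   log-normalized expression on the region contrast plus patient dummies.
   The coefficient is the *normalized effect* (NE), PA-positive. A linear
   model on standardized values was chosen over a count GLM because the
   defining property of the approach is that the coefficient *is* the
   effect size on a commensurate scale. Genes expressed in <1% of cells are
   not tested (reported NE = 0, p = 1, q = NaN); zero-variance genes report
   NE = 0, p = 1. BH correction runs across tested genes.
6. **Networks** are reconstructed per cell type from the same normalized
   expression: correlation shrunk toward the identity with the analytic
   intensity λ* = Σ Var(r_ij) / Σ r_ij² (clamped to [0, 1]),
   pseudo-inverted, rescaled to partial correlations. Fisher z uses the
   effective sample size n − (p − 2) − 3, floored at 3, since each partial
   correlation conditions on p − 2 genes. The FDR analysis fits only the
   *scale* of the null to the central 90% of the z distribution — the null
   is taken symmetric about zero, so both the empirical and the theoretical
   (BH) modes rank edges identically by |z| and agree on the top ranks. The
   top 20,000 edges (configurable) are retained even past FDR 0.05; module
   detection treats |pcor| as the edge weight (affinity mode). The literal
   reading of "reciprocal" distance weights (1/|pcor|) is available behind
   `weight_mode="reciprocal"`, but modularity treats weights as connection
   strength, so affinities are the default.
7. **Drivers.** Modules whose genes are over-represented among significant
   DE genes (one-tailed Fisher over the network universe, p < 0.05) are
   selected; an optional |NE| floor on the DE set guards against weak
   global compositional shifts counting as hits (see limitations). Within a
   module, the subnetwork keeps the top 15% of genes by strength — computed
   on the module's induced subgraph by default; `strength_scope="global"`
   ranks by whole-network strength — plus all module DE genes. Key-driver
   flags are strict: q < 0.05 AND |NE| > 0.5 AND strength > 0.3. The 0.3
   cut applies to node strength (sum of |pcor|), consistent with ranking
   genes by connectivity; a per-edge reading would make "strength of
   connections" a property of single links rather than of genes.
8. **Subpopulations.** Expression on a gene panel is binarized at raw count
   ≥ 2; both axes are clustered with the asymmetric binary distance
   d = discordant / (discordant + both-on) — joint absences excluded, an
   all-off pair defined as distance 0 with a warning — under complete
   linkage. Subpopulations come from nested cuts of the cell dendrogram
   (cuts of one tree are nested by construction); each gets its fraction of
   AC cells, and a per-gene regression of normalized expression on that
   fraction ranks genes along the PA → AC axis for pre-ranked enrichment.
   No cut count is hard-coded; k values are configuration.

**Enrichment machinery.** Pre-ranked GSEA uses the weighted KS running sum
(hit steps ∝ |score|^w, w = 1 by default; miss steps uniform), a gene-label
permutation null (the only available null when a single ranked list exists;
1,000 permutations by default), NES = ES divided by the mean |null ES| of
matching sign, and the sign-matched pooled-null FDR rule. The leading edge
is the members at or before the running-sum extremum (after it, for
negative ES). Gene-set collections are user-supplied GMT files; bundled
tests use synthetic sets only.

## Synthetic data generator

The generator emulates the motivating study's design: 3 patients × 2 regions
(defaults: 13,000 AC and 5,000 PA cells per patient — tests and the
acceptance script run scaled-down versions and say so below), six cell
types, ~2,000 genes (the order of robustly expressed genes, not a full
annotation), ~1% mitochondrial genes, negative-binomial margins
(dispersion θ = 2, a typical droplet value), and gene-wise log-normal
patient factors (sd 0.15, a mild batch effect) shared by both regions of a
patient — mirroring patient-as-covariate adjustment.

*Cell types* get 10 exclusive markers each (NB mean 6 in the own type,
0.005 elsewhere — bright canonical markers that clear the 90%/10%
ubiquity/rarity criteria) plus mild lognormal modulation (sd 0.3) of the
shared baseline, which is drawn log-normally (median ≈ 0.6 counts/cell).

*Partial-correlation modules* are planted through a Gaussian copula: a
sparse symmetric positive-definite precision matrix per module (ring plus
random chords at average degree ~3, or a star for hub experiments; signs
random; magnitudes rescaled toward the range floor until the smallest
eigenvalue clears 0.05), inverted to a latent correlation, sampled as
multivariate normal, and pushed through each gene's NB quantile function.
Diagonal rescaling leaves partial correlations invariant, so the planted
`pcor` values are exact at the latent level. A star with k spokes requires
Σ pcor² < 1 to stay positive definite — a hub with ten partners cannot
exceed |pcor| ≈ 0.31, which bounds what hub-recovery experiments can plant.

*Differential expression* is planted as a latent mean shift computed so
that the *recovered* normalized effect equals the requested δ: with margin
slope c = E[g(z)·z] and sd s of g(z) = log1p(quantile(Φ(z))) (computed by
Gauss–Hermite quadrature), batch sd τ, and up-region fraction f
(v = f(1−f)), the shift is Δ = δ·sqrt(s² + τ²) / (c·sqrt(1 − δ²v)). The
calibration is first-order: exact for balanced regions and most accurate
for well-expressed genes; |δ| must stay below 1/sqrt(v) (2, when balanced)
because a standardized two-group contrast is bounded.

*Doublets* are appended (never replacing singlets, so singlet truth stays
intact for recall): each is the elementwise count sum of two cells of
different types from the same sample, at round(rate × n) barcodes.

**What the generator does not emulate** — ambient RNA, empty droplets, UMI
saturation, read-level structure, cell-cycle or continuous lineage
variation, and realistic per-cell-type library-size distributions (none are
published for this design; defaults are configurable, not calibrated).
Passing tests therefore demonstrate recovery under the planted model, not
robustness to every artifact of real droplet data.

## Numerical choices and known limitations

- **Composition effects.** Depth normalization makes strong planted shifts
  on high-mean genes bleed weakly into all other genes (their normalized
  expression moves the other way). With many cells this produces
  statistically significant but small spurious NEs; the |NE| > 0.5
  selection rule downstream is insensitive to them, and driver experiments
  gate the Fisher DE set at |NE| > 0.5 for the same reason.
- **Discretized margins.** Genes with near-zero counts carry almost no
  copula information; estimated partial correlations on such genes
  attenuate and, for weak conditional links, can flip sign. Recovery
  experiments therefore plant structure on expressed genes (base mean ≥ 1).
- **Determinism.** All sampling uses a single seeded generator; Louvain
  runs under an explicitly seeded igraph RNG; Leiden partitioning passes
  its seed through; hierarchical clustering uses SciPy's agglomeration,
  which is deterministic given input order (equal-height merges resolve by
  SciPy's cluster indexing).
- **Degenerate inputs.** All-identical cells partition into a single
  cluster; constant genes are excluded from the correlation stage with a
  warning; zero-total cells fall to the low-genes QC rule with a warning;
  empty retained-edge sets yield empty module sets.
- **Problem sizes.** The test-suite and acceptance-script experiments use
  scaled versions of the study design chosen for statistical adequacy:
  module recovery at 300 genes × 2,000 cells (5 seeds), DE calibration at
  1,000 null genes × 600 cells and 50 replicates of 500 cells/region for
  effect recovery, the doublet filter at ~1,900 cells × 300 genes with 5%
  spiked doublets, driver recovery at 200 genes × 1,000 cells over 50
  replicates. The generator's own defaults remain at the full design scale.
- **Open count reports.** Module counts in the motivating workflow depend
  on the retained-edge budget and are not treated as ground truth anywhere;
  no particular module count is asserted.
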