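"""Synthetic single-cell UMI data with planted, recoverable structure.

Generates 10x-style count matrices that mimic a paired two-region vascular
single-cell study (three patients, an atherosclerotic-core and a
proximal-adjacent sample each) while planting known ground truth:

* discrete cell types with bright, type-exclusive marker genes,
* region differential expression with a prescribed *normalized effect*
  (the coefficient a standardized linear contrast should recover),
* gene modules with a prescribed sparse partial-correlation structure
  (a Gaussian copula with a block precision matrix, mapped to
  negative-binomial count margins),
* multiplicative per-patient batch factors,
* optional cross-type doublets built by summing two real cells.

The accompanying :class:`SyntheticTruth` records everything that was
planted so every downstream stage (QC, partitioning, doublet filtering,
DE, network reconstruction, driver selection) can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "DEEffect",
    "ModuleSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_cells",
    "spike_doublets",
    "write_truth",
]


@dataclass(frozen=True)
class DEEffect:
    """A planted region effect for one gene in one cell type.

    ``effect`` is the target normalized effect magnitude (standardized
    scale); ``region`` names the region in which the gene is elevated.
    The recorded truth follows the PA-positive sign convention.
    """

    gene: str
    cell_type: str
    region: str
    effect: float


@dataclass(frozen=True)
class ModuleSpec:
    """A planted partial-correlation module: a gene list and the
    magnitude range for within-module partial correlations.

    ``topology="random"`` plants a connected sparse graph (ring plus
    chords, average degree ~3); ``topology="hub"`` plants a star with
    the first gene as hub. A hub with k spokes needs the sum of squared
    partial correlations below 1 to stay positive definite, so high-|pcor|
    hubs are only feasible with moderate magnitudes."""

    genes: tuple[str, ...]
    pcor_range: tuple[float, float] = (0.25, 0.4)
    topology: str = "random"


@dataclass
class SimConfig:
    """Study design and noise parameters for the generator.

    Defaults mirror the emulated study: 3 patients, paired AC/PA samples,
    ~13,000 AC and ~5,000 PA cells per patient, six major cell types.
    ``n_genes`` defaults to 2,000 (the order of robustly expressed genes
    retained for network work, not the full annotation).
    """

    n_patients: int = 3
    regions: tuple[str, str] = ("AC", "PA")
    cells_per_sample: int | Mapping[str, int] = field(
        default_factory=lambda: {"AC": 13000, "PA": 5000}
    )
    n_genes: int = 2000
    n_cell_types: int = 6
    markers_per_type: int = 10
    mito_gene_fraction: float = 0.01
    nb_dispersion: float = 2.0
    patient_effect_sd: float = 0.15
    type_dev_sd: float = 0.3
    type_marker_mean: float = 6.0
    marker_background_mean: float = 0.005
    base_log_mean: float = -0.5
    base_log_sd: float = 1.0
    base_mean: Mapping[str, float] | None = None
    de_spec: Sequence[DEEffect] = ()
    ggm_spec: Sequence[ModuleSpec] = ()
    doublet_rate: float = 0.05
    seed: int = 0

    # -- derived layout -------------------------------------------------
    @property
    def n_mito_genes(self) -> int:
        return int(round(self.n_genes * self.mito_gene_fraction))

    @property
    def gene_names(self) -> list[str]:
        n_mt = self.n_mito_genes
        body = [f"G{i:04d}" for i in range(1, self.n_genes - n_mt + 1)]
        mito = [f"MT-{j}" for j in range(1, n_mt + 1)]
        return body + mito

    @property
    def cell_type_names(self) -> list[str]:
        return [f"CT{i}" for i in range(1, self.n_cell_types + 1)]

    def cells_for(self, region: str) -> int:
        if isinstance(self.cells_per_sample, Mapping):
            return int(self.cells_per_sample[region])
        return int(self.cells_per_sample)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.regions) != 2:
            raise ValueError("exactly two regions are required")
        for r in self.regions:
            if self.cells_for(r) < 1:
                raise ValueError("cells_per_sample must be >= 1")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must lie in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be nonnegative")
        names = set(self.gene_names)
        seen: set[str] = set()
        for m in self.ggm_spec:
            gs = set(m.genes)
            if not gs <= names:
                missing = sorted(gs - names)
                raise ValueError(f"module genes not in gene set: {missing}")
            if gs & seen:
                raise ValueError("module gene lists must be disjoint")
            if len(m.genes) < 3:
                raise ValueError("modules need at least 3 genes")
            lo, hi = m.pcor_range
            if not (0 < lo <= hi < 1):
                raise ValueError("pcor_range must satisfy 0 < lo <= hi < 1")
            if m.topology not in ("random", "hub"):
                raise ValueError(f"unknown module topology {m.topology!r}")
            if m.topology == "hub" and hi**2 * (len(m.genes) - 1) >= 1:
                raise ValueError(
                    "hub module infeasible: sum of squared partial "
                    "correlations must stay below 1"
                )
            seen |= gs
        types = set(self.cell_type_names)
        for d in self.de_spec:
            if d.gene not in names:
                raise ValueError(f"de_spec gene {d.gene!r} not in gene set")
            if d.cell_type not in types:
                raise ValueError(f"de_spec cell type {d.cell_type!r} unknown")
            if d.region not in self.regions:
                raise ValueError(f"de_spec region {d.region!r} unknown")
            if not np.isfinite(d.effect) or d.effect <= 0:
                raise ValueError("de_spec effects must be finite and > 0")


@dataclass
class SyntheticTruth:
    """Ground truth record for a generated dataset."""

    cell_types: pd.Series
    is_doublet: pd.Series
    doublets: pd.DataFrame
    de_table: pd.DataFrame
    module_membership: pd.Series
    module_precisions: dict[str, pd.DataFrame]
    planted_edges: pd.DataFrame
    patient_factors: pd.DataFrame
    config: SimConfig
    type_markers: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------
# negative-binomial copula margins


def _nb_cdf_table(mu: float, theta: float) -> np.ndarray:
    """CDF lookup table for a NB(mu, theta) margin (mean/dispersion form)."""
    if mu <= 0:
        return np.array([1.0])
    p = theta / (theta + mu)
    kmax = int(stats.nbinom.ppf(1.0 - 1e-10, theta, p)) + 1
    return stats.nbinom.cdf(np.arange(kmax + 1), theta, p)


def _nb_cdf_matrix(mus: np.ndarray, theta: float) -> np.ndarray:
    """Row-wise NB CDF tables for a vector of means (shared dispersion).

    Equivalent to stacking :func:`_nb_cdf_table` per gene but computed in
    one vectorized log-pmf evaluation; the support is truncated far in
    the tail (mean + 15 sd + 50) and the last entry forced to 1."""
    from scipy.special import gammaln

    mus = np.maximum(np.asarray(mus, dtype=float), 1e-12)
    sd = np.sqrt(mus + mus**2 / theta)
    K = int(np.ceil(np.max(mus + 15 * sd + 50)))
    ks = np.arange(K + 1, dtype=float)
    logpmf = (
        gammaln(ks[None, :] + theta)
        - gammaln(theta)
        - gammaln(ks[None, :] + 1.0)
        + theta * np.log(theta / (theta + mus))[:, None]
        + ks[None, :] * np.log(mus / (theta + mus))[:, None]
    )
    cdf = np.cumsum(np.exp(logpmf), axis=1)
    cdf[:, -1] = 1.0
    return cdf


def _nb_quantile(u: np.ndarray, cdf: np.ndarray) -> np.ndarray:
    """Quantile transform via a precomputed CDF table (min k: F(k) >= u)."""
    return np.searchsorted(cdf, u, side="left").astype(np.int64)


def _margin_moments(mu: float, theta: float) -> tuple[float, float]:
    """Linear (Hermite) slope and sd of log1p(NB quantile(Phi(z))), z~N(0,1).

    Used to translate a target normalized effect into the latent-mean
    shift that produces it after count sampling and standardization.
    """
    z, w = np.polynomial.hermite_e.hermegauss(201)
    w = w / w.sum()
    cdf = _nb_cdf_table(mu, theta)
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    y = np.log1p(_nb_quantile(u, cdf).astype(float))
    m = float(np.sum(w * y))
    sd = float(np.sqrt(np.sum(w * (y - m) ** 2)))
    slope = float(np.sum(w * y * z))
    return slope, sd


def _latent_shift(delta: float, mu: float, theta: float, tau: float,
                  f_up: float) -> float:
    """Latent Gaussian mean shift producing normalized effect ``delta``.

    First-order calibration: with margin slope c and sd s, batch sd tau and
    up-region fraction f (variance v = f(1-f)), the standardized contrast of
    a latent shift D is c*D / sqrt(s^2 + c^2 D^2 v + tau^2); solve for D.
    """
    c, s = _margin_moments(mu, theta)
    if c <= 0:
        raise ValueError("gene margin is degenerate; cannot plant an effect")
    v = f_up * (1.0 - f_up)
    denom = 1.0 - delta**2 * v
    if denom <= 0:
        raise ValueError(
            f"planted effect {delta} is unattainable on the standardized "
            f"scale with up-region fraction {f_up:.3f} (needs |delta| < "
            f"{1.0 / np.sqrt(v):.2f})"
        )
    return delta * np.sqrt(s**2 + tau**2) / (c * np.sqrt(denom))


# ---------------------------------------------------------------------
# planted precision matrices


def _module_precision(m: int, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix with unit
    diagonal whose implied partial correlations have magnitudes in
    [lo, hi].

    A ring guarantees connectivity; random chords raise the average
    degree to ~3 so modularity clustering sees each module as one dense
    community. Magnitudes are scaled toward ``lo`` (and chords dropped as
    a last resort) until the matrix is comfortably positive definite.
    """
    edges = [(i, (i + 1) % m) for i in range(m)]
    perm = rng.permutation(m)
    chords = [
        (int(perm[2 * j]), int(perm[2 * j + 1])) for j in range(m // 2)
    ]
    chords = [e for e in chords if abs(e[0] - e[1]) not in (1, m - 1)]
    edges = edges + chords
    mags = rng.uniform(lo, hi, size=len(edges))
    signs = rng.choice([-1.0, 1.0], size=len(edges))

    def build(mags_: np.ndarray, edges_: list, signs_: np.ndarray):
        omega = np.eye(m)
        for (i, j), mag, sgn in zip(edges_, mags_, signs_):
            omega[i, j] = omega[j, i] = -mag * sgn
        return omega

    for _ in range(60):
        omega = build(mags, edges, signs)
        if np.linalg.eigvalsh(omega)[0] > 0.05:
            return omega
        if np.all(mags <= lo + 1e-12) and len(edges) > m:
            # drop the weakest chord
            k = m + int(np.argmin(mags[m:]))
            edges = edges[:k] + edges[k + 1:]
            mags = np.delete(mags, k)
            signs = np.delete(signs, k)
        else:
            mags = np.maximum(lo, lo + (mags - lo) * 0.5)
    raise ValueError("could not construct a positive-definite module precision")


def _hub_precision(m: int, lo: float, hi: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Star-shaped precision: gene 0 is the hub, connected to all other
    genes with partial correlations of magnitude in [lo, hi]."""
    mags = rng.uniform(lo, hi, size=m - 1)
    signs = rng.choice([-1.0, 1.0], size=m - 1)
    while (mags**2).sum() >= 0.95:
        mags *= 0.98
    omega = np.eye(m)
    omega[0, 1:] = omega[1:, 0] = -mags * signs
    return omega


def _precision_to_pcor(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


# ---------------------------------------------------------------------
# main generator


def generate_cells(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate singlet cells for every (patient, region) sample.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts in
    ``X``, ``obs`` columns ``sample``/``patient``/``region``, ``var``
    columns ``symbol``/``is_mito``) plus the :class:`SyntheticTruth`.
    Identical configs (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    theta = config.nb_dispersion
    types = config.cell_type_names
    patients = [f"P{i}" for i in range(1, config.n_patients + 1)]

    # baseline means
    base = np.exp(rng.normal(config.base_log_mean, config.base_log_sd,
                             size=n_genes))
    if config.base_mean:
        for g, mu in config.base_mean.items():
            base[gene_idx[g]] = float(mu)

    # type deviations (log-normal modulation of non-marker genes)
    type_dev = np.exp(rng.normal(0.0, config.type_dev_sd,
                                 size=(len(types), n_genes)))

    # marker genes: exclusive to one type, drawn from genes not used for
    # modules, DE effects or mitochondria
    reserved = {gene_idx[g] for m in config.ggm_spec for g in m.genes}
    reserved |= {gene_idx[d.gene] for d in config.de_spec}
    reserved |= {i for i, g in enumerate(genes) if g.startswith("MT-")}
    pool = np.array([i for i in range(n_genes) if i not in reserved])
    need = config.markers_per_type * len(types)
    if len(pool) < need:
        raise ValueError("not enough free genes for type markers")
    marker_idx = rng.choice(pool, size=need, replace=False).reshape(
        len(types), config.markers_per_type
    )
    mu_type = base[None, :] * type_dev  # (types, genes)
    for t in range(len(types)):
        mu_type[:, marker_idx[t]] = config.marker_background_mean
        mu_type[t, marker_idx[t]] = config.type_marker_mean

    # patient batch factors
    tau = config.patient_effect_sd if config.n_patients > 1 else 0.0
    pf = np.exp(rng.normal(0.0, config.patient_effect_sd,
                           size=(config.n_patients, n_genes)))
    if config.n_patients == 1:
        pf[:] = 1.0

    # planted modules: per-module precision and the latent correlation
    module_membership: dict[str, str] = {}
    module_precisions: dict[str, pd.DataFrame] = {}
    module_chols: list[tuple[np.ndarray, np.ndarray]] = []
    edge_rows = []
    for k, mspec in enumerate(config.ggm_spec, start=1):
        mid = f"M{k}"
        idx = np.array([gene_idx[g] for g in mspec.genes])
        if mspec.topology == "hub":
            omega = _hub_precision(len(idx), *mspec.pcor_range, rng=rng)
        else:
            omega = _module_precision(len(idx), *mspec.pcor_range, rng=rng)
        if np.linalg.eigvalsh(omega)[0] <= 0:
            raise ValueError("planted precision matrix is not positive definite")
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        module_chols.append((idx, np.linalg.cholesky(corr)))
        pcor = _precision_to_pcor(omega)
        glist = list(mspec.genes)
        module_precisions[mid] = pd.DataFrame(omega, index=glist, columns=glist)
        for g in glist:
            module_membership[g] = mid
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if omega[a, b] != 0.0:
                    edge_rows.append((glist[a], glist[b], pcor[a, b], mid))
    planted_edges = pd.DataFrame(
        edge_rows, columns=["gene_i", "gene_j", "pcor", "module"]
    )

    # planted DE: latent shifts per (type, gene)
    n_up = {r: config.cells_for(r) for r in config.regions}
    total = sum(n_up.values())
    de_rows = []
    shift_map: dict[tuple[int, int], tuple[float, str]] = {}
    for d_ in config.de_spec:
        t = types.index(d_.cell_type)
        gi = gene_idx[d_.gene]
        f_up = n_up[d_.region] / total
        mu = mu_type[t, gi]
        shift = _latent_shift(d_.effect, mu, theta, tau, f_up)
        shift_map[(t, gi)] = (shift, d_.region)
        planted_ne = d_.effect if d_.region == "PA" else -d_.effect
        de_rows.append((d_.gene, d_.cell_type, d_.region, planted_ne, shift))
    de_table = pd.DataFrame(
        de_rows,
        columns=["gene", "cell_type", "up_region", "planted_ne", "latent_shift"],
    )

    # sample cells
    blocks, barcodes, obs_rows, truth_types = [], [], [], []
    corr_cols = sorted({int(i) for idx, _ in module_chols for i in idx}
                       | {gi for (_, gi) in shift_map})
    corr_pos = {gi: j for j, gi in enumerate(corr_cols)}
    for p_i, patient in enumerate(patients):
        for region in config.regions:
            sample = f"{patient}-{region}"
            n_cells = config.cells_for(region)
            # near-equal deterministic type allocation
            counts_per_type = np.full(len(types), n_cells // len(types))
            counts_per_type[: n_cells % len(types)] += 1
            for t, n_tc in enumerate(counts_per_type):
                if n_tc == 0:
                    continue
                u = rng.random((n_tc, n_genes))
                if corr_cols:
                    z = rng.standard_normal((n_tc, len(corr_cols)))
                    for idx, chol in module_chols:
                        cols = [corr_pos[int(i)] for i in idx]
                        z[:, cols] = (
                            rng.standard_normal((n_tc, len(idx))) @ chol.T
                        )
                    for (tt, gi), (shift, up_region) in shift_map.items():
                        if tt != t:
                            continue
                        f_up = n_up[up_region] / total
                        ind = 1.0 if region == up_region else 0.0
                        z[:, corr_pos[gi]] += shift * (ind - f_up)
                    u[:, corr_cols] = np.clip(
                        ndtr(z), 1e-12, 1 - 1e-12
                    )
                block = np.empty((n_tc, n_genes), dtype=np.int32)
                mus = mu_type[t] * pf[p_i]
                cdfs = _nb_cdf_matrix(mus, theta)
                for gi in range(n_genes):
                    block[:, gi] = _nb_quantile(u[:, gi], cdfs[gi])
                blocks.append(sp.csr_matrix(block))
                for c in range(n_tc):
                    barcodes.append(f"{sample}-{types[t]}-{c:05d}")
                    obs_rows.append((sample, patient, region))
                    truth_types.append(types[t])
    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["sample", "patient", "region"],
                       index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(
        {
            "symbol": genes,
            "is_mito": [g.startswith("MT-") for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = SyntheticTruth(
        cell_types=pd.Series(truth_types, index=obs.index, name="cell_type"),
        is_doublet=pd.Series(False, index=obs.index, name="is_doublet"),
        doublets=pd.DataFrame(
            columns=["barcode", "parent1", "parent2", "type1", "type2"]
        ),
        de_table=de_table,
        module_membership=pd.Series(module_membership, name="module",
                                    dtype=object),
        module_precisions=module_precisions,
        planted_edges=planted_edges,
        patient_factors=pd.DataFrame(pf, index=patients, columns=genes),
        config=config,
        type_markers={
            types[t]: [genes[i] for i in marker_idx[t]]
            for t in range(len(types))
        },
    )
    return adata, truth


def spike_doublets(
    adata: ad.AnnData,
    truth: SyntheticTruth,
    rate: float | None = None,
    seed: int | None = None,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Append synthetic cross-type doublets.

    Each doublet is the elementwise count sum of two cells of *different*
    cell types drawn from the same sample; ``round(rate * n_cells)``
    barcodes are appended and recorded in the truth tables. The input
    singlets are left untouched so singlet-level recall stays well
    defined.
    """
    if rate is None:
        rate = truth.config.doublet_rate
    if not 0 <= rate < 0.5:
        raise ValueError("doublet rate must lie in [0, 0.5)")
    if truth.cell_types.nunique() < 2:
        raise ValueError("need at least 2 cell types to form doublets")
    rng = np.random.default_rng(
        truth.config.seed + 1 if seed is None else seed
    )
    n_d = int(round(rate * adata.n_obs))
    if n_d == 0:
        return adata, truth
    samples = adata.obs["sample"].to_numpy()
    ctype = truth.cell_types.to_numpy()
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    rows, meta, bcs, trows = [], [], [], []
    sample_ids = np.unique(samples)
    made = 0
    while made < n_d:
        s = sample_ids[int(rng.integers(len(sample_ids)))]
        cand = np.flatnonzero(samples == s)
        i, j = rng.choice(cand, size=2, replace=False)
        if ctype[i] == ctype[j]:
            continue
        rows.append(X[i] + X[j])
        bc = f"{s}-DBL{made:05d}"
        bcs.append(bc)
        meta.append(tuple(adata.obs.iloc[i][["sample", "patient", "region"]]))
        trows.append((bc, adata.obs_names[i], adata.obs_names[j],
                      ctype[i], ctype[j]))
        made += 1
    Xd = sp.vstack(rows, format="csr")
    obs_d = pd.DataFrame(meta, columns=["sample", "patient", "region"],
                         index=pd.Index(bcs, name="barcode"))
    out = ad.AnnData(
        X=sp.vstack([X, Xd], format="csr"),
        obs=pd.concat([adata.obs, obs_d]),
        var=adata.var.copy(),
    )
    dbl = pd.DataFrame(trows,
                       columns=["barcode", "parent1", "parent2",
                                "type1", "type2"])
    new_truth = SyntheticTruth(
        cell_types=pd.concat(
            [truth.cell_types,
             pd.Series("doublet", index=obs_d.index, name="cell_type")]
        ),
        is_doublet=pd.concat(
            [truth.is_doublet,
             pd.Series(True, index=obs_d.index, name="is_doublet")]
        ),
        doublets=pd.concat([truth.doublets, dbl], ignore_index=True),
        de_table=truth.de_table,
        module_membership=truth.module_membership,
        module_precisions=truth.module_precisions,
        planted_edges=truth.planted_edges,
        patient_factors=truth.patient_factors,
        config=truth.config,
        type_markers=truth.type_markers,
    )
    return out, new_truth


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write the truth tables as TSV and the config as JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.cell_types.to_frame().assign(
        is_doublet=truth.is_doublet
    ).to_csv(out / "cell_truth.tsv", sep="\t")
    truth.doublets.to_csv(out / "doublets.tsv", sep="\t", index=False)
    truth.de_table.to_csv(out / "de_truth.tsv", sep="\t", index=False)
    truth.module_membership.rename_axis("gene").to_frame().to_csv(
        out / "module_truth.tsv", sep="\t"
    )
    truth.planted_edges.to_csv(out / "edge_truth.tsv", sep="\t", index=False)
    truth.patient_factors.to_csv(out / "patient_factors.tsv", sep="\t")
    cfg = asdict(truth.config)
    cfg["de_spec"] = [asdict(d) for d in truth.config.de_spec]
    cfg["ggm_spec"] = [asdict(m) for m in truth.config.ggm_spec]
    if isinstance(cfg["cells_per_sample"], Mapping):
        cfg["cells_per_sample"] = dict(cfg["cells_per_sample"])
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=2))
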