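"""Cell partitioning, marker discovery, cell-type labels, doublet filter.

Cells are partitioned by modularity community detection on a
k-nearest-neighbor graph built in PC space of log-normalized expression
(deterministic given a seed). Partition markers follow the ubiquity
criteria: expressed in >80% of the partition's cells at a mean raw count
>2. Doublets are flagged by marker exclusion: a gene that is
ubiquitously expressed (>90%) in one partition and rare (<10%) in every
other is an exclusion marker; any cell expressing two or more exclusion
markers of *foreign* partitions is tagged for removal, and the flagged
set is validated by its upward shift in total read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Partitioning",
    "partition_cells",
    "find_partition_markers",
    "assign_cell_types",
    "discover_exclusion_markers",
    "flag_doublets",
    "validate_doublets_readcount",
    "small_partitions",
]


@dataclass
class Partitioning:
    """Cell -> partition assignment plus optional cell-type labels."""

    labels: pd.Series                      # cell -> partition id (int)
    type_labels: dict[int, str] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def partitions(self) -> list[int]:
        return sorted(self.labels.unique())

    def label_of(self, partition: int) -> str:
        return self.type_labels.get(partition, "unassigned")


def partition_cells(
    adata: ad.AnnData,
    n_pcs: int = 30,
    k_neighbors: int = 15,
    seed: int = 0,
) -> Partitioning:
    """Modularity communities of the kNN graph in PC space.

    log1p of library-size-normalized counts -> top ``n_pcs`` principal
    components -> ``k_neighbors`` nearest-neighbor graph -> Leiden
    optimization of modularity. Deterministic given ``seed``.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells")
    if n_pcs >= min(adata.n_obs, adata.n_vars):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(n_cells, n_genes)="
            f"{min(adata.n_obs, adata.n_vars)}"
        )
    X0 = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    colmax = X0.max(axis=0).toarray().ravel()
    colmin = X0.min(axis=0).toarray().ravel()
    identical = bool(np.all(colmax == colmin))
    if identical:
        # degenerate input: all cells identical -> a single partition
        return Partitioning(
            labels=pd.Series(0, index=adata.obs_names, name="partition")
        )
    work = adata.copy()
    sc.pp.normalize_total(work)
    sc.pp.log1p(work)
    sc.pp.pca(work, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(work, n_neighbors=k_neighbors, random_state=seed)
    conn = sp.triu(sp.coo_matrix(work.obsp["connectivities"]))
    g = ig.Graph(
        n=adata.n_obs, edges=list(zip(conn.row, conn.col))
    )
    part = la.find_partition(
        g,
        la.ModularityVertexPartition,
        weights=list(conn.data),
        seed=seed,
        n_iterations=2,
    )
    labels = pd.Series(part.membership, index=adata.obs_names,
                       name="partition")
    return Partitioning(labels=labels)


def _fraction_and_mean(adata: ad.AnnData, labels: pd.Series):
    """Per-partition fraction of expressing cells (UMI >= 1) and mean raw
    count, as (partitions x genes) DataFrames."""
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    parts = sorted(labels.unique())
    frac = np.zeros((len(parts), adata.n_vars))
    mean = np.zeros((len(parts), adata.n_vars))
    lab = labels.loc[adata.obs_names].to_numpy()
    for i, p in enumerate(parts):
        rows = np.flatnonzero(lab == p)
        if len(rows) == 0:
            logger.warning("partition %s is empty; skipped", p)
            continue
        sub = X[rows]
        # integer accumulation so boundary fractions (e.g. exactly 80%)
        # compare exactly against their thresholds
        n_on = np.asarray((sub > 0).sum(axis=0)).ravel().astype(np.int64)
        tot = np.asarray(sub.sum(axis=0)).ravel().astype(np.int64)
        frac[i] = n_on / len(rows)
        mean[i] = tot / len(rows)
    cols = adata.var_names
    return (pd.DataFrame(frac, index=parts, columns=cols),
            pd.DataFrame(mean, index=parts, columns=cols))


def find_partition_markers(
    adata: ad.AnnData,
    partitioning: Partitioning,
    min_fraction: float = 0.8,
    min_mean: float = 2.0,
) -> pd.DataFrame:
    """Genes expressed in more than ``min_fraction`` of a partition's
    cells with mean raw count above ``min_mean`` (strict inequalities),
    ranked by fraction then mean."""
    frac, mean = _fraction_and_mean(adata, partitioning.labels)
    rows = []
    for p in frac.index:
        hit = (frac.loc[p] > min_fraction) & (mean.loc[p] > min_mean)
        for g in frac.columns[hit]:
            rows.append((g, p, frac.at[p, g], mean.at[p, g]))
    out = pd.DataFrame(
        rows, columns=["gene", "partition", "fraction_expressing",
                       "mean_count"]
    )
    return out.sort_values(
        ["partition", "fraction_expressing", "mean_count"],
        ascending=[True, False, False],
    ).reset_index(drop=True)


def assign_cell_types(
    markers: pd.DataFrame,
    reference: dict[str, str],
) -> dict[int, str]:
    """Label each partition with the cell type whose reference markers
    dominate its marker list (majority vote; ties or no hits ->
    "unassigned")."""
    if not reference:
        logger.warning("empty reference table: all partitions unassigned")
        return {int(p): "unassigned" for p in markers["partition"].unique()}
    out: dict[int, str] = {}
    for p, sub in markers.groupby("partition"):
        votes = (
            sub["gene"].map(reference).dropna().value_counts()
        )
        if votes.empty:
            out[int(p)] = "unassigned"
        elif len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            out[int(p)] = "unassigned"
        else:
            out[int(p)] = str(votes.index[0])
    return out


def discover_exclusion_markers(
    adata: ad.AnnData,
    partitioning: Partitioning,
    ubiquity: float = 0.9,
    rarity: float = 0.1,
    min_partition_cells: int = 50,
) -> dict[int, list[str]]:
    """Exclusion markers per partition: genes expressed in more than
    ``ubiquity`` of one partition's cells and in less than ``rarity`` of
    every other partition's cells (both strict).

    Partitions below ``min_partition_cells`` (too small for downstream
    DE; frequently doublet clusters) are excluded from both the ubiquity
    candidacy and the rarity scan — their cells are dropped from the
    analysis anyway, and counting them in the rarity scan would let
    doublet clusters veto their parents' markers."""
    if len(partitioning.partitions) < 2:
        raise ValueError("need at least 2 partitions")
    sizes = partitioning.sizes
    big = [int(p) for p in sizes.index[sizes >= min_partition_cells]]
    if len(big) < 2:
        big = partitioning.partitions
    mask = partitioning.labels.isin(big)
    cells = partitioning.labels.index[mask]
    adata = adata[adata.obs_names.isin(set(cells))]
    frac, _ = _fraction_and_mean(
        adata, partitioning.labels.loc[adata.obs_names]
    )
    out: dict[int, list[str]] = {int(p): [] for p in frac.index}
    F = frac.to_numpy()
    for j, g in enumerate(frac.columns):
        col = F[:, j]
        own = int(np.argmax(col))
        if col[own] > ubiquity and np.all(np.delete(col, own) < rarity):
            out[int(frac.index[own])].append(g)
    return out


def flag_doublets(
    adata: ad.AnnData,
    partitioning: Partitioning,
    exclusion_sets: dict[int, list[str]],
    min_markers: int = 2,
) -> pd.DataFrame:
    """Flag cells expressing >= ``min_markers`` exclusion markers of
    partitions other than their own.

    Returns a per-cell DataFrame (n_inappropriate, inappropriate_markers,
    total_umi, flagged).
    """
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel().astype(int)
    lab = partitioning.labels.loc[adata.obs_names].to_numpy()
    gene_pos = {g: i for i, g in enumerate(adata.var_names)}
    owner: dict[str, int] = {}
    for p, genes in exclusion_sets.items():
        for g in genes:
            owner[g] = p
    marker_genes = sorted(owner)
    cols = np.array([gene_pos[g] for g in marker_genes], dtype=int)
    n_inap = np.zeros(adata.n_obs, dtype=int)
    inap_lists: list[list[str]] = [[] for _ in range(adata.n_obs)]
    if len(cols):
        expressed = (X[:, cols] > 0).toarray()
        owners = np.array([owner[g] for g in marker_genes])
        foreign = expressed & (owners[None, :] != lab[:, None])
        n_inap = foreign.sum(axis=1)
        for i in np.flatnonzero(n_inap):
            inap_lists[i] = [marker_genes[j]
                             for j in np.flatnonzero(foreign[i])]
    return pd.DataFrame(
        {
            "partition": lab,
            "n_inappropriate": n_inap,
            "inappropriate_markers": inap_lists,
            "total_umi": total,
            "flagged": n_inap >= min_markers,
        },
        index=adata.obs_names,
    )


@dataclass
class ReadCountShift:
    n_flagged: int
    n_unflagged: int
    mean_flagged: float
    mean_unflagged: float
    median_flagged: float
    median_unflagged: float
    p_value: float
    passed: bool


def validate_doublets_readcount(flags: pd.DataFrame, adata=None) -> ReadCountShift:
    """Validate flagged doublets by their upward total-UMI shift.

    One-sided Wilcoxon rank-sum of flagged vs unflagged total UMI;
    validation passes iff the flagged mean exceeds the unflagged mean.
    """
    flagged = flags.loc[flags["flagged"], "total_umi"].to_numpy()
    unflagged = flags.loc[~flags["flagged"], "total_umi"].to_numpy()
    if len(flagged) == 0:
        logger.warning("no doublets flagged; nothing to validate")
        return ReadCountShift(0, len(unflagged), np.nan,
                              float(np.mean(unflagged)), np.nan,
                              float(np.median(unflagged)), np.nan, False)
    p = float(
        stats.mannwhitneyu(flagged, unflagged, alternative="greater")[1]
    )
    mf, mu = float(np.mean(flagged)), float(np.mean(unflagged))
    return ReadCountShift(
        n_flagged=len(flagged),
        n_unflagged=len(unflagged),
        mean_flagged=mf,
        mean_unflagged=mu,
        median_flagged=float(np.median(flagged)),
        median_unflagged=float(np.median(unflagged)),
        p_value=p,
        passed=mf > mu,
    )


def small_partitions(partitioning: Partitioning, min_cells: int = 50) -> list[int]:
    """Partitions below the size needed for downstream DE (to be dropped)."""
    sizes = partitioning.sizes
    return [int(p) for p in sizes.index[sizes < min_cells]]
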