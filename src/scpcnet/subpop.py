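"""Binarized biclustering of cells by module genes and subpopulation
analysis.

Expression is binarized at a raw count of two or more, both axes are
clustered with the asymmetric binary (Jaccard) distance — discordant /
(discordant + both-on), joint absences excluded — under complete
linkage, subpopulations are defined by nested cuts of the cell
dendrogram, and a per-gene continuous model on the subpopulation AC
fraction yields a ranked list for enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .diff_expr import normalize_expression

logger = logging.getLogger(__name__)

__all__ = [
    "BiclusterResult",
    "binarize",
    "bicluster",
    "cut_subpopulations",
    "ac_fraction",
    "continuous_expression_model",
    "balanced_downsample",
    "linkage_to_newick",
]


def binarize(adata, genes: list[str], threshold: int = 2) -> pd.DataFrame:
    """Cells x genes on/off matrix: on iff raw UMI >= ``threshold``."""
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    sub = adata[:, genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    return pd.DataFrame(X >= threshold, index=adata.obs_names, columns=genes)


def _binary_distance(B: np.ndarray) -> np.ndarray:
    """Condensed pairwise asymmetric binary distance.

    d = discordant / (discordant + both-on); pairs with no positive
    coordinate in either vector get distance 0 (with a warning)."""
    allzero = ~B.any(axis=1)
    if allzero.any():
        logger.warning("%d all-off vectors; their pairwise distances are 0",
                       int(allzero.sum()))
    with np.errstate(invalid="ignore"):
        d = pdist(B.astype(bool), metric="jaccard")
    return np.nan_to_num(d, nan=0.0)


@dataclass
class BiclusterResult:
    binary: pd.DataFrame
    gene_linkage: np.ndarray | None
    cell_linkage: np.ndarray | None


def bicluster(binary: pd.DataFrame) -> BiclusterResult:
    """Complete-linkage hierarchical clustering of both axes under the
    binary distance. Deterministic given input order (SciPy's
    agglomeration resolves equal-height merges by cluster index)."""
    if binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    B = binary.to_numpy(dtype=bool)
    cell_link = linkage(_binary_distance(B), method="complete")
    gene_link = linkage(_binary_distance(B.T), method="complete")
    return BiclusterResult(binary=binary, gene_linkage=gene_link,
                           cell_linkage=cell_link)


def cut_subpopulations(
    result: BiclusterResult, ks: int | list[int]
) -> pd.DataFrame:
    """Nested dendrogram cuts of the cell axis.

    ``ks`` is one k or a list of k values; each cell gets a label per
    cut (column ``k{K}``) plus ``subpop`` from the finest cut. Cuts of
    one tree are nested: every finer cluster sits inside one coarser
    cluster.
    """
    if isinstance(ks, int):
        ks = [ks]
    n = result.binary.shape[0]
    out = {}
    for k in sorted(ks):
        if k > n:
            raise ValueError(f"k={k} exceeds the number of cells ({n})")
        out[f"k{k}"] = fcluster(result.cell_linkage, t=k,
                                criterion="maxclust")
    df = pd.DataFrame(out, index=result.binary.index)
    df["subpop"] = df[f"k{max(ks)}"]
    return df


def ac_fraction(subpops: pd.Series, regions: pd.Series) -> pd.Series:
    """Fraction of AC cells per subpopulation."""
    regions = regions.loc[subpops.index]
    return (
        (regions == "AC").groupby(subpops).mean().rename("ac_fraction")
    )


def continuous_expression_model(
    adata,
    subpops: pd.Series,
    normalized: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-gene slope of normalized expression on the cell's
    subpopulation AC fraction; the resulting coefficients rank genes for
    pre-ranked enrichment."""
    fracs = ac_fraction(subpops, adata.obs["region"])
    if fracs.nunique() < 2:
        raise ValueError(
            "need at least 2 distinct AC-fraction values across "
            "subpopulations"
        )
    x = subpops.map(fracs).to_numpy(dtype=float)
    if normalized is None:
        normalized = normalize_expression(adata)
    Y = normalized.loc[subpops.index].to_numpy()
    xc = x - x.mean()
    denom = float((xc**2).sum())
    coef = (xc @ (Y - Y.mean(axis=0))) / denom
    return pd.Series(coef, index=normalized.columns, name="coefficient")


def balanced_downsample(
    adata, per_group: int, by: list[str], seed: int = 0
):
    """Draw exactly ``per_group`` cells from every combination of ``by``
    columns (e.g. 448 per cell type x region for heatmaps)."""
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    groups = adata.obs.groupby(by, observed=True).indices
    for key in sorted(groups, key=str):
        idx = np.asarray(groups[key])
        if len(idx) < per_group:
            raise ValueError(
                f"group {key} has {len(idx)} cells (< {per_group})"
            )
        keep.append(rng.choice(idx, size=per_group, replace=False))
    return adata[np.sort(np.concatenate(keep))].copy()


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string."""
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = link[i - n]
        return f"({node(int(a))},{node(int(b))}):{h:.6g}"

    return node(2 * n - 2) + ";"
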