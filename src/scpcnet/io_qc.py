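"""Reading/writing 10x-style matrix triplets and per-cell quality control.

QC follows the standard single-cell recipe for this kind of study: drop
cells with a mitochondrial UMI fraction above 10%, or with fewer than 200
or more than 4,000 detected genes (boundaries are retained — removal uses
strict inequalities), then downsample so every sample contributes the same
number of cells to unsupervised cell-type discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "read_matrix", "write_matrix", "qc_filter",
           "downsample_equal"]

REQUIRED_META = ("sample", "patient", "region")


def read_matrix(path, mito_prefix: str = "MT-") -> ad.AnnData:
    """Read a genes x cells MatrixMarket triplet plus cell metadata.

    Expects ``matrix.mtx`` (integer coordinate, genes x cells),
    ``features.tsv`` (gene symbols), ``barcodes.tsv`` and ``metadata.tsv``
    (columns barcode, sample, patient, region) in ``path``. Returns a
    cells x genes :class:`~anndata.AnnData` with ``is_mito`` flagged for
    symbols starting with ``mito_prefix``.
    """
    path = Path(path)
    mtx = mmread(path / "matrix.mtx")
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    symbols = features[0].astype(str).tolist()
    bcs = barcodes[0].astype(str).tolist()
    n_genes, n_cells = mtx.shape
    if len(symbols) != n_genes:
        raise ValueError(
            f"features.tsv lists {len(symbols)} genes but matrix.mtx has "
            f"{n_genes} rows"
        )
    if len(bcs) != n_cells:
        raise ValueError(
            f"barcodes.tsv lists {len(bcs)} barcodes but matrix.mtx has "
            f"{n_cells} columns"
        )
    data = mtx.tocsr().data
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("matrix.mtx contains non-integer entries")
    meta_path = path / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("barcode",) + REQUIRED_META:
        if col not in meta.columns:
            raise ValueError(f"metadata.tsv lacks required column {col!r}")
    meta = meta.set_index("barcode")
    missing = [b for b in bcs if b not in meta.index]
    if missing:
        raise ValueError(
            f"metadata.tsv has no rows for {len(missing)} barcodes "
            f"(first: {missing[0]!r})"
        )
    obs = meta.loc[bcs, list(REQUIRED_META)].copy()
    obs.index.name = "barcode"
    if obs[list(REQUIRED_META)].isna().any().any():
        raise ValueError("metadata.tsv has missing sample/patient/region values")
    if obs.index.to_frame().assign(sample=obs["sample"]).duplicated().any():
        raise ValueError("duplicate barcodes within a sample")
    X = sp.csr_matrix(mtx.T).astype(np.int64)
    var = pd.DataFrame(
        {"symbol": symbols,
         "is_mito": [s.startswith(mito_prefix) for s in symbols]},
        index=pd.Index(symbols, name="gene"),
    )
    return ad.AnnData(X=X, obs=obs, var=var)


def write_matrix(adata: ad.AnnData, path) -> None:
    """Write the genes x cells triplet (matrix.mtx, features.tsv,
    barcodes.tsv) plus metadata.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(path / "matrix.mtx", sp.coo_matrix(X.T).astype(np.int64))
    pd.Series(adata.var_names).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs[list(REQUIRED_META)].rename_axis("barcode").to_csv(
        path / "metadata.tsv", sep="\t"
    )


@dataclass
class QCReport:
    """Removal accounting for :func:`qc_filter`.

    A failing cell is counted once, under its first failing rule in the
    priority order mito -> too-few-genes -> too-many-genes.
    """

    cells_in: int
    removed_mito: int
    removed_low_genes: int
    removed_high_genes: int
    cells_out: int
    per_sample: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample


def qc_filter(
    adata: ad.AnnData,
    mito_max: float = 0.10,
    min_genes: int = 200,
    max_genes: int = 4000,
) -> tuple[ad.AnnData, QCReport]:
    """Remove cells with >``mito_max`` mitochondrial fraction or with
    <``min_genes`` or >``max_genes`` detected genes (UMI >= 1).

    Cells exactly at a boundary are retained.
    """
    if "is_mito" not in adata.var:
        raise ValueError("gene annotation lacks the is_mito flag")
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_cols = adata.var["is_mito"].to_numpy()
    mito = np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    if np.any(total == 0):
        logger.warning(
            "%d zero-total cells removed under the low-genes rule",
            int((total == 0).sum()),
        )
    fail_mito = mito_frac > mito_max
    fail_low = genes_detected < min_genes
    fail_high = genes_detected > max_genes
    first_fail = np.full(adata.n_obs, "", dtype=object)
    first_fail[fail_high] = "high"
    first_fail[fail_low] = "low"
    first_fail[fail_mito] = "mito"
    keep = first_fail == ""
    per_sample = (
        pd.DataFrame(
            {"sample": adata.obs["sample"].to_numpy(), "rule": first_fail}
        )
        .groupby("sample")["rule"]
        .value_counts()
        .unstack(fill_value=0)
        .rename(columns={"": "kept", "mito": "removed_mito",
                         "low": "removed_low_genes",
                         "high": "removed_high_genes"})
    )
    report = QCReport(
        cells_in=adata.n_obs,
        removed_mito=int(fail_mito.sum()),
        removed_low_genes=int((fail_low & ~fail_mito).sum()),
        removed_high_genes=int((fail_high & ~fail_low & ~fail_mito).sum()),
        cells_out=int(keep.sum()),
        per_sample=per_sample,
    )
    assert report.cells_out == (
        report.cells_in - report.removed_mito - report.removed_low_genes
        - report.removed_high_genes
    )
    return adata[keep].copy(), report


def downsample_equal(
    adata: ad.AnnData, total_cells: int, seed: int
) -> ad.AnnData:
    """Draw an equal quota of cells per sample, uniformly without
    replacement, so every sample contributes the same number of cells.

    A sample smaller than its quota keeps all of its cells, with a
    warning; the achieved total is then smaller than requested (no silent
    re-allocation to other samples).
    """
    samples = adata.obs["sample"].to_numpy()
    sample_ids = sorted(pd.unique(samples))
    n_samples = len(sample_ids)
    if total_cells % n_samples != 0:
        raise ValueError(
            f"total_cells={total_cells} is not divisible by the "
            f"{n_samples} samples"
        )
    quota = total_cells // n_samples
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for s in sample_ids:
        idx = np.flatnonzero(samples == s)
        if len(idx) < quota:
            logger.warning(
                "sample %s has %d cells (< quota %d); keeping all",
                s, len(idx), quota,
            )
            keep_idx.append(idx)
        else:
            keep_idx.append(rng.choice(idx, size=quota, replace=False))
    keep = np.sort(np.concatenate(keep_idx))
    out = adata[keep].copy()
    if out.n_obs < total_cells:
        logger.warning("achieved total %d < requested %d", out.n_obs,
                       total_cells)
    return out
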