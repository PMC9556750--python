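"""Normalized-effect differential expression.

Each gene's expression is library-size normalized, log1p transformed and
standardized to zero mean / unit variance across cells; an ordinary linear
model of the standardized values on the region contrast (plus patient
dummies as confounder adjustment) then yields a coefficient that is
directly interpretable as that gene's effect size — the *normalized
effect* (NE). The sign convention is PA-positive: NE > 0 means higher in
proximal-adjacent tissue, NE < 0 higher in the atherosclerotic core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["normalize_expression", "fit_de", "bh_adjust"]


def normalize_expression(adata) -> pd.DataFrame:
    """Standardized log-normalized expression (cells x genes).

    Counts are scaled per cell to the median library size, log1p
    transformed, then each gene is standardized to mean 0 / variance 1
    across cells. Zero-variance genes are left at all-zero (their DE
    results are reported as NE = 0, p = 1).
    """
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    X = X.astype(float)
    depth = X.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("cells with zero library size; run QC first")
    scale = np.median(depth) / depth
    Y = np.log1p(X * scale[:, None])
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (Y - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(Z, index=adata.obs_names, columns=adata.var_names)


def _design(obs: pd.DataFrame, contrast: str, covariates: list[str],
            positive_level: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(obs[contrast].unique())
    if len(levels) != 2:
        raise ValueError(f"contrast {contrast!r} must have exactly 2 levels")
    if positive_level not in levels:
        raise ValueError(
            f"positive level {positive_level!r} absent from {contrast!r}"
        )
    x = (obs[contrast] == positive_level).to_numpy(float)
    cols = [np.ones(len(obs)), x]
    names = ["intercept", contrast]
    for cov in covariates:
        vals = sorted(obs[cov].unique())
        for v in vals[1:]:
            cols.append((obs[cov] == v).to_numpy(float))
            names.append(f"{cov}[{v}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"confounded design: {contrast!r} is collinear with covariates "
            f"{covariates} (e.g. every patient observed in a single region)"
        )
    return X, names


def fit_de(
    adata,
    contrast: str = "region",
    covariates: list[str] | None = None,
    positive_level: str = "PA",
    min_expressing_frac: float = 0.01,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene normalized-effect model ``z_g ~ contrast + covariates``.

    Returns a DataFrame indexed by gene with columns ``ne`` (the contrast
    coefficient; PA-positive by default), ``p`` (two-sided coefficient
    test) and ``q`` (Benjamini-Hochberg across tested genes). Genes
    expressed in fewer than ``min_expressing_frac`` of cells are not
    tested (reported with NE = 0, p = 1, q = NaN); zero-variance genes
    are reported with NE = 0, p = 1.

    ``normalized`` lets callers reuse (or manipulate) the output of
    :func:`normalize_expression`; the fit is then exactly the OLS on
    those values.
    """
    covariates = list(covariates) if covariates else []
    if normalized is None:
        normalized = normalize_expression(adata)
    Y = normalized.to_numpy()
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 cells")
    for lvl in pd.unique(adata.obs[contrast]):
        if (adata.obs[contrast] == lvl).sum() < 2:
            raise ValueError(f"contrast level {lvl!r} has fewer than 2 cells")
    X, _ = _design(adata.obs, contrast, covariates, positive_level)
    raw = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    expressing = (raw > 0).mean(axis=0)
    variable = Y.std(axis=0) > 0
    tested = (expressing >= min_expressing_frac) & variable

    ne = np.zeros(Y.shape[1])
    pvals = np.ones(Y.shape[1])
    if tested.any():
        Yt = Y[:, tested]
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ (X.T @ Yt)
        resid = Yt - X @ beta
        dof = n - np.linalg.matrix_rank(X)
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
        tstat = beta[1] / se
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        ne[tested] = beta[1]
        pvals[tested] = p
    q = np.full(Y.shape[1], np.nan)
    if tested.any():
        q[tested] = bh_adjust(pvals[tested])
    return pd.DataFrame(
        {"ne": ne, "p": pvals, "q": q, "tested": tested},
        index=normalized.columns,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values propagate as NaN and are excluded from the ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and np.nanmin(p) < 0 or p.size and np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
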