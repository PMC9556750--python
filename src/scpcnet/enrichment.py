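"""Pre-ranked gene-set enrichment and Fisher overlap machinery.

`preranked_gsea` implements the weighted Kolmogorov-Smirnov enrichment
statistic on a list of genes ranked by normalized effect, with a
gene-label permutation null, sign-matched NES normalization and the
pooled-null FDR rule. `fisher_one_tailed` is the hypergeometric
upper-tail test used for module / DE-gene and hallmark / module overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt
from scipy import stats

__all__ = ["GseaResult", "read_gmt", "preranked_gsea", "fisher_one_tailed"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets = _read_gmt(str(path))
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return {k: list(v) for k, v in sets.items()}


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list[str]


def _running_es(
    order_scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """Enrichment score of one set against a ranked list.

    Hit steps are proportional to |score|^weight (uniform at weight 0);
    miss steps are a uniform decrement. Returns (ES, extremum index).
    """
    n = len(order_scores)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0, 0
    w = np.abs(order_scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = n_hit
    steps = hit_w / denom - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def preranked_gsea(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over ``sets`` for a gene -> score Series.

    The null is built from ``n_perm`` random same-size gene sets drawn
    from the ranked list (gene-label permutation). NES = ES divided by
    the mean |null ES| of matching sign; the nominal p is the matching
    sign tail; FDR pools null NES values across sets, sign-matched.
    Returns a DataFrame sorted by NES with a ``leading_edge`` column.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p/FDR will be coarse")
    order = np.argsort(-ranked.to_numpy(), kind="stable")
    genes = ranked.index.to_numpy()[order]
    scores = ranked.to_numpy()[order]
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n = len(genes)

    rows = []
    null_by_set: list[np.ndarray] = []
    for name, members in sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if len(idx) == 0:
            continue
        if len(idx) < min_size:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, i_ext = _running_es(scores, mask, weight)
        if es >= 0:
            le = [g for g in genes[: i_ext + 1] if g in set(members)]
        else:
            le = [g for g in genes[i_ext:] if g in set(members)]
        null = np.empty(n_perm)
        k = len(idx)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _running_es(scores, pmask, weight)
        same = null >= 0 if es >= 0 else null < 0
        n_same = max(int(same.sum()), 1)
        p = (np.sum(np.abs(null[same]) >= abs(es)) + 1) / (n_same + 1)
        mean_same = np.abs(null[same]).mean() if same.any() else np.nan
        nes = es / mean_same if mean_same and mean_same > 0 else 0.0
        null_nes = np.where(
            null >= 0,
            null / max(np.abs(null[null >= 0]).mean(), 1e-12),
            null / max(np.abs(null[null < 0]).mean(), 1e-12)
            if (null < 0).any() else 0.0,
        )
        null_by_set.append(null_nes)
        rows.append([name, es, nes, p, np.nan, k, le])

    if not rows:
        return pd.DataFrame(
            columns=["name", "es", "nes", "p", "fdr", "size", "leading_edge"]
        )
    res = pd.DataFrame(
        rows, columns=["name", "es", "nes", "p", "fdr", "size",
                       "leading_edge"]
    )
    pooled = np.concatenate(null_by_set)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_tail = np.mean(pooled[pooled >= 0] >= nes) if np.any(
                pooled >= 0) else 0.0
            obs_tail = np.mean(obs[obs >= 0] >= nes)
        else:
            null_tail = np.mean(pooled[pooled < 0] <= nes) if np.any(
                pooled < 0) else 0.0
            obs_tail = np.mean(obs[obs < 0] <= nes)
        fdr[i] = min(null_tail / max(obs_tail, 1e-12), 1.0)
    res["fdr"] = fdr
    return res.sort_values("nes", ascending=False).reset_index(drop=True)


def fisher_one_tailed(table) -> float:
    """One-tailed (enrichment) Fisher exact p for a 2x2 table.

    ``table`` is [[overlap, set1_only], [set2_only, neither]]; the
    returned value is the hypergeometric upper tail P(X >= overlap).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be nonnegative")
    return float(stats.fisher_exact(t, alternative="greater")[1])


def overlap_table(hits: set, members: set, universe: set) -> np.ndarray:
    """2x2 contingency table for two gene sets within a universe."""
    hits = hits & universe
    members = members & universe
    a = len(hits & members)
    b = len(members - hits)
    c = len(hits - members)
    d = len(universe) - a - b - c
    return np.array([[a, b], [c, d]])
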