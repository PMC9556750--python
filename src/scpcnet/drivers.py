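"""Module enrichment and key-driver subnetwork extraction.

A module is carried forward when significant DE genes overlap it more
than chance (one-tailed Fisher exact test over the network gene
universe, p < 0.05). Within a selected module, the subnetwork keeps the
top 15% of genes by strength plus every DE gene; a gene is a *key
driver* when it passes all three cuts simultaneously: q < 0.05,
|NE| > 0.5, and strength > 0.3 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .enrichment import fisher_one_tailed, overlap_table
from .network import NetworkModules, node_strength

__all__ = [
    "ModuleEnrichment",
    "DriverSubnetwork",
    "select_enriched_modules",
    "hallmark_module_overlap",
    "extract_driver_subnetwork",
]


@dataclass
class ModuleEnrichment:
    module: str
    table: np.ndarray
    p: float
    selected: bool


@dataclass
class DriverSubnetwork:
    module: str
    nodes: pd.DataFrame          # index gene; ne, q, strength, is_driver
    edges: pd.DataFrame          # retained edges among the nodes

    @property
    def drivers(self) -> list[str]:
        return sorted(self.nodes.index[self.nodes["is_driver"]])


def _significant_de(de: pd.DataFrame, q_cut: float = 0.05,
                    ne_cut: float | None = None) -> set[str]:
    sig = de["q"] < q_cut
    if ne_cut is not None:
        sig &= de["ne"].abs() > ne_cut
    return set(de.index[sig.fillna(False)])


def select_enriched_modules(
    modules: NetworkModules,
    de: pd.DataFrame,
    alpha: float = 0.05,
    de_q: float = 0.05,
    de_ne: float | None = None,
) -> list[ModuleEnrichment]:
    """One-tailed Fisher enrichment of significant DE genes per module.

    The universe is the set of network genes; a module is selected iff
    its upper-tail p is below ``alpha``. ``de_ne`` optionally restricts
    the DE gene set to |NE| above a cut (guards against weak global
    compositional shifts counting as hits). Modules disjoint from the
    universe are skipped.
    """
    universe = set(modules.membership.index) & set(de.index)
    hits = _significant_de(de, de_q, de_ne) & universe
    out = []
    for mid, genes in modules.modules.items():
        members = set(genes) & universe
        if not members:
            continue
        table = overlap_table(hits, members, universe)
        p = fisher_one_tailed(table)
        out.append(ModuleEnrichment(module=mid, table=table, p=p,
                                    selected=p < alpha))
    return out


def hallmark_module_overlap(
    modules: NetworkModules,
    leading_edges: dict[str, list[str]],
    de: pd.DataFrame | None = None,
    alpha: float = 0.05,
    de_q: float = 0.05,
) -> pd.DataFrame:
    """Fisher overlap of each hallmark's leading edge with each module.

    When ``de`` is given, the leading edge is restricted to significant
    DE genes first. A hallmark is flagged ``specific`` when exactly one
    module passes ``alpha``. Returns a (hallmark, module, p, passed,
    specific) DataFrame; hallmarks with an empty effective leading edge
    are skipped.
    """
    universe = set(modules.membership.index)
    sig = _significant_de(de, de_q) if de is not None else None
    rows = []
    for name, le in leading_edges.items():
        hits = set(le) & universe
        if sig is not None:
            hits &= sig
        if not hits:
            continue
        passes = []
        for mid, genes in modules.modules.items():
            p = fisher_one_tailed(overlap_table(hits, set(genes), universe))
            passes.append((mid, p, p < alpha))
        n_pass = sum(1 for _, _, ok in passes if ok)
        for mid, p, ok in passes:
            rows.append((name, mid, p, ok, n_pass == 1 and ok))
    return pd.DataFrame(
        rows, columns=["hallmark", "module", "p", "passed", "specific"]
    )


def extract_driver_subnetwork(
    module_genes: list[str],
    edges: pd.DataFrame,
    de: pd.DataFrame,
    top_frac: float = 0.15,
    strength_cut: float = 0.3,
    ne_cut: float = 0.5,
    q_cut: float = 0.05,
    module: str = "",
    strength_scope: str = "module",
) -> DriverSubnetwork:
    """Filter a module to its driver subnetwork.

    The node set is the union of the module's top ``top_frac`` genes by
    strength and all of the module's DE genes (q < ``q_cut`` and
    |NE| > ``ne_cut``). Strength is computed on the module's induced
    subgraph by default (``strength_scope="module"``); pass ``"global"``
    to rank by whole-network strength instead. Driver flags are strict:
    q < q_cut AND strength > strength_cut AND |NE| > ne_cut.
    """
    if len(module_genes) < 3:
        raise ValueError("module must have at least 3 genes")
    mset = set(module_genes)
    kept = edges[edges["retained"]]
    sub_edges = kept[
        kept["gene_i"].isin(mset) & kept["gene_j"].isin(mset)
    ].copy()
    if strength_scope == "module":
        strength = node_strength(
            sub_edges.assign(retained=True)
        ).reindex(sorted(mset)).fillna(0.0)
    elif strength_scope == "global":
        strength = node_strength(kept.assign(retained=True)).reindex(
            sorted(mset)
        ).fillna(0.0)
    else:
        raise ValueError(f"unknown strength_scope {strength_scope!r}")
    n_top = ceil(top_frac * len(module_genes))
    top = set(strength.sort_values(ascending=False).index[:n_top])
    de_m = de.reindex(sorted(mset))
    de_genes = set(
        de_m.index[(de_m["q"] < q_cut) & (de_m["ne"].abs() > ne_cut)]
    )
    node_set = sorted(top | de_genes)
    nodes = pd.DataFrame(
        {
            "ne": de_m["ne"].reindex(node_set),
            "q": de_m["q"].reindex(node_set),
            "strength": strength.reindex(node_set),
        }
    )
    nodes["is_driver"] = (
        (nodes["q"] < q_cut)
        & (nodes["strength"] > strength_cut)
        & (nodes["ne"].abs() > ne_cut)
    ).fillna(False)
    nodes["direction"] = np.where(
        nodes["q"] >= q_cut, "ns",
        np.where(nodes["ne"] > 0, "PA-up", "AC-up"),
    )
    sub = sub_edges[
        sub_edges["gene_i"].isin(node_set) & sub_edges["gene_j"].isin(node_set)
    ].reset_index(drop=True)
    return DriverSubnetwork(module=module, nodes=nodes, edges=sub)
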