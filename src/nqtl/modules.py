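"""Hot-edge filtering and network-signature mining.

After association mapping, attention narrows to the "hot" part of the
bipartite SNP-edge association graph: SNPs and edges carrying far more
significant links than background. The hot edges' association profiles over
hot SNPs form a dense matrix; hierarchically clustering its rows groups
edges with similar genotype-association patterns into nQTL modules (network
signatures), each summarized by its member genes and anchor SNPs.

Default hot-filter settings follow the real-data case studies: keep the
top 1,000 edges by SNP-connection count, with a dataset-specific minimum
count (330 and 2,000 in the published analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .edges import split_edge_id
from .mapping import AssociationTable

logger = logging.getLogger("nqtl")

__all__ = [
    "AssociationProfileMatrix",
    "ModuleSet",
    "count_links",
    "hot_select",
    "build_profile",
    "cluster_modules",
    "module_report",
]


@dataclass
class AssociationProfileMatrix:
    """Hot edges x hot SNPs association strengths.

    Values are capped -log10 p (``neglog`` mode) or 0/1 at a p threshold
    (``binary`` mode); unreported tests count as non-significant (0).
    """

    edge_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.edge_ids), len(self.snp_ids)):
            raise ValueError("profile shape does not match ids")


@dataclass
class ModuleSet:
    """A partition of clustered edges into modules (1-based contiguous)."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        found = sorted(set(self.labels.values()))
        if found != list(range(1, self.k + 1)):
            raise ValueError(f"module indices must be 1..{self.k}, got {found}")

    def members(self, module: int) -> list[str]:
        return [e for e, m in self.labels.items() if m == module]


def count_links(assoc: AssociationTable, axis: str = "edge",
                p_threshold: float = 1e-5) -> dict[str, int]:
    """Significant-link count per SNP or per trait (edge) at a p threshold."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    col = {"snp": "snp", "edge": "trait", "trait": "trait"}.get(axis)
    if col is None:
        raise ValueError("axis must be 'snp' or 'edge'")
    recs = assoc.records
    hit = recs[recs["p"] <= p_threshold]
    return hit.groupby(col, sort=False).size().to_dict()


def hot_select(counts: dict[str, int], top_k: int | None = 1000,
               min_count: int | None = None) -> list[str]:
    """Ids passing the hot filter: count >= min_count, then top_k by count.

    Boundary ties break lexicographically by id so the selection is
    deterministic. Either criterion may be None (unused); an empty result is
    returned with a warning, not an error.
    """
    if top_k is None and min_count is None:
        raise ValueError("at least one of top_k, min_count must be set")
    items = [(i, c) for i, c in counts.items() if min_count is None or c >= min_count]
    items.sort(key=lambda ic: (-ic[1], ic[0]))
    if top_k is not None:
        items = items[:top_k]
    if not items:
        logger.warning("hot filter selected nothing (min_count=%s, top_k=%s)",
                       min_count, top_k)
    return [i for i, _ in items]


def build_profile(assoc: AssociationTable, hot_edges, hot_snps,
                  mode: str = "neglog", p_threshold: float = 1e-5,
                  cap: float = 16.0) -> AssociationProfileMatrix:
    """Association profile of hot edges over hot SNPs.

    ``neglog``: -log10 p capped at ``cap``; ``binary``: 1 where
    p <= p_threshold. Tests missing from the record table fill as 0.
    """
    hot_edges, hot_snps = list(hot_edges), list(hot_snps)
    if not hot_edges or not hot_snps:
        raise ValueError("hot edge and SNP sets must be non-empty")
    if mode not in ("neglog", "binary"):
        raise ValueError(f"unknown profile mode {mode!r}")
    e_pos = {e: i for i, e in enumerate(hot_edges)}
    s_pos = {s: i for i, s in enumerate(hot_snps)}
    out = np.zeros((len(hot_edges), len(hot_snps)))
    recs = assoc.records
    sel = recs[recs["trait"].isin(e_pos) & recs["snp"].isin(s_pos)]
    rows = sel["trait"].map(e_pos).to_numpy()
    cols = sel["snp"].map(s_pos).to_numpy()
    p = sel["p"].to_numpy(dtype=float)
    if mode == "neglog":
        vals = np.minimum(-np.log10(np.maximum(p, 10.0 ** -cap)), cap)
    else:
        vals = (p <= p_threshold).astype(float)
    # keep the strongest value if a (snp, edge) appears more than once
    np.maximum.at(out, (rows, cols), vals)
    return AssociationProfileMatrix(hot_edges, hot_snps, out, mode)


def cluster_modules(profile: AssociationProfileMatrix, k: int = 10,
                    distance: str | None = None) -> ModuleSet:
    """Average-linkage hierarchical clustering of edge profiles into k modules.

    Distance defaults to 1 - Pearson correlation of profiles in ``neglog``
    mode and Jaccard distance in ``binary`` mode. Rows that are constant
    (distance undefined under correlation) become singleton modules appended
    after the k clustered ones, with a warning. Deterministic given row
    order.
    """
    n = len(profile.edge_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    if distance is None:
        distance = "correlation" if profile.mode == "neglog" else "jaccard"
    vals = profile.values
    if distance == "correlation":
        const = vals.std(axis=1) == 0
    else:
        const = np.zeros(n, dtype=bool)
    cluster_idx = np.flatnonzero(~const)
    singleton_idx = np.flatnonzero(const)
    if singleton_idx.size:
        logger.warning("%d constant profile rows moved to singleton modules",
                       singleton_idx.size)
    labels: dict[str, int] = {}
    k_eff = min(k, cluster_idx.size)
    if cluster_idx.size:
        sub = vals[cluster_idx]
        if distance == "jaccard":
            dmat = pdist(sub.astype(bool), metric="jaccard")
        else:
            dmat = pdist(sub, metric="correlation")
        dmat = np.nan_to_num(dmat, nan=1.0)
        if k_eff == cluster_idx.size:
            assign = np.arange(1, k_eff + 1)
        else:
            Z = linkage(dmat, method="average")
            assign = fcluster(Z, t=k_eff, criterion="maxclust")
        # renumber modules contiguously in order of first appearance
        remap: dict[int, int] = {}
        for a in assign:
            if a not in remap:
                remap[a] = len(remap) + 1
        for i, a in zip(cluster_idx, assign):
            labels[profile.edge_ids[i]] = remap[a]
    n_clusters = len(set(labels.values()))
    for j, i in enumerate(singleton_idx, start=1):
        labels[profile.edge_ids[i]] = n_clusters + j
    return ModuleSet(labels=labels, k=n_clusters + singleton_idx.size)


def module_report(modules: ModuleSet, assoc: AssociationTable,
                  p_threshold: float = 1e-5, top_snps: int = 5) -> pd.DataFrame:
    """Per-module summary: size, member genes, top anchor SNPs by link count."""
    if not modules.labels:
        raise ValueError("empty module set")
    recs = assoc.records
    hit = recs[recs["p"] <= p_threshold]
    rows = []
    for m in range(1, modules.k + 1):
        edges = sorted(modules.members(m))
        genes = sorted({g for e in edges for g in split_edge_id(e)})
        sub = hit[hit["trait"].isin(edges)]
        counts = sub.groupby("snp", sort=False).size()
        anchors = sorted(counts.items(), key=lambda sc: (-sc[1], sc[0]))[:top_snps]
        rows.append({
            "module": m,
            "n_edges": len(edges),
            "n_genes": len(genes),
            "genes": ",".join(genes),
            "anchor_snps": ",".join(s for s, _ in anchors),
        })
    return pd.DataFrame(rows)
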