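"""Ground-truthed synthetic datasets and AUC benchmarking.

Two generators mirror the simulation design used to benchmark edge-trait
detection against conventional eQTL mapping. Both share a common population
signal ``pop = pop_scale * N(0,1)`` added to every variable and ramped
per-trait genetic effects
``effect_scale * (rank/n_traits)^effect_exponent``, so that planted links
range from undetectably weak to strong within one dataset. The defaults
(exponent 9, scale 1/2) follow the R expression ``((1:n)/n)^9/2`` of the
reference simulation, where ``^`` binds tighter than ``/``:

* expression-trait scenario — every gene receives one uniformly chosen SNP
  plus its ramped effect on top of independent Gaussian noise and ``pop``;
* edge-trait scenario — gene expression stays pure noise, the baseline edge
  matrix is the per-sample co-expression of those genes, and the ramped SNP
  effects are added to a chosen subset of *edge rows* instead, so the signal
  exists only at the network level.

Genotypes are continuous Gaussian scores (SNP row = N(0,1) + pop), matching
the linear model used for mapping. Detection performance is summarized by
the rank-based AUC: the probability that a planted link outranks a
non-planted one under a method's association score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .edges import GenePairList, build_edge_matrix, enumerate_pairs
from .mapping import linear_stats
from .matrixio import EdgeMatrix, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("nqtl")

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_expression_trait_dataset",
    "gen_edge_trait_dataset",
    "evaluate_auc",
    "rank_auc",
    "compare_methods",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give the desk-scale profile (100 samples, 100 genes, 500 SNPs,
    200 causal edges); the full-scale settings from the benchmarking study
    (100 samples, 2,000-5,000 genes, 2,000-200,000 SNPs, all-pairs edges)
    are reachable by configuration but need cluster-class resources.
    """

    n: int = 100
    ngs: int = 100
    nss: int = 500
    pop_scale: float = 0.2
    effect_exponent: float = 9.0
    effect_scale: float = 0.5
    n_causal_edges: int = 200
    n_pairs: int | None = None  # None = all gene pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 samples")
        if self.ngs < 2:
            raise ValueError("need at least 2 genes")
        if self.nss < 1:
            raise ValueError("need at least 1 SNP")
        max_pairs = self.ngs * (self.ngs - 1) // 2
        n_pairs = max_pairs if self.n_pairs is None else self.n_pairs
        if n_pairs > max_pairs:
            raise ValueError(f"n_pairs {n_pairs} exceeds {max_pairs} possible pairs")
        if self.n_causal_edges > n_pairs:
            raise ValueError("n_causal_edges exceeds the number of edges")


@dataclass
class SimTruth:
    """Planted (SNP, trait) links with effect sizes.

    ``links`` has columns snp, trait, effect, snp_idx, trait_idx where the
    index columns refer to row positions in the generated matrices.
    """

    links: pd.DataFrame
    scenario: str

    def __post_init__(self) -> None:
        if (self.links["effect"] <= 0).any():
            raise ValueError("planted effects must be positive")

    def mask(self, n_snps: int, n_traits: int) -> np.ndarray:
        """Boolean SNPs x traits matrix marking the planted links."""
        m = np.zeros((n_snps, n_traits), dtype=bool)
        m[self.links["snp_idx"].to_numpy(), self.links["trait_idx"].to_numpy()] = True
        return m


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(count)]


def _gen_snps(rng: np.random.Generator, cfg: SimConfig, pop: np.ndarray) -> np.ndarray:
    return rng.standard_normal((cfg.nss, cfg.n)) + pop


def gen_expression_trait_dataset(cfg: SimConfig):
    """Simulate genes carrying ramped single-SNP effects (expression traits).

    Per gene g (1-based), one SNP is chosen uniformly without replacement
    (with replacement when there are more genes than SNPs) and added with
    effect ``effect_scale * (g/ngs)^effect_exponent``. Returns genotype
    matrix, expression matrix and the ground truth of all ngs planted links.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = cfg.pop_scale * rng.standard_normal(cfg.n)
    snps = _gen_snps(rng, cfg, pop)
    replace = cfg.ngs > cfg.nss
    chosen = rng.choice(cfg.nss, size=cfg.ngs, replace=replace)
    effects = cfg.effect_scale * ((np.arange(1, cfg.ngs + 1)) / cfg.ngs) ** cfg.effect_exponent
    genes = rng.standard_normal((cfg.ngs, cfg.n)) + pop + effects[:, None] * snps[chosen]
    snp_ids = _ids("snp", cfg.nss)
    gene_ids = _ids("gene", cfg.ngs)
    sample_ids = _ids("s", cfg.n)
    truth = SimTruth(
        links=pd.DataFrame({
            "snp": [snp_ids[c] for c in chosen],
            "trait": gene_ids,
            "effect": effects,
            "snp_idx": chosen,
            "trait_idx": np.arange(cfg.ngs),
        }),
        scenario="expression",
    )
    return (
        GenotypeMatrix(snp_ids, sample_ids, snps),
        ExpressionMatrix(gene_ids, sample_ids, genes),
        truth,
    )


def gen_edge_trait_dataset(cfg: SimConfig):
    """Simulate SNP effects planted on edge rows only (edge traits).

    Gene expression is pure N(0,1); the baseline edge matrix is its
    per-sample co-expression. ``n_causal_edges`` edges are chosen uniformly,
    each is assigned one uniformly chosen SNP, and the r-th chosen edge
    (r = 1..n_causal_edges) receives effect
    ``effect_scale * (r/n_causal_edges)^effect_exponent`` plus the shared
    population signal.
    The unmodified gene matrix is also returned so the conventional
    gene-level mapping can be run on the same data.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = cfg.pop_scale * rng.standard_normal(cfg.n)
    snps = _gen_snps(rng, cfg, pop)
    genes = rng.standard_normal((cfg.ngs, cfg.n))
    snp_ids = _ids("snp", cfg.nss)
    gene_ids = _ids("gene", cfg.ngs)
    sample_ids = _ids("s", cfg.n)
    expr = ExpressionMatrix(gene_ids, sample_ids, genes)
    pairs = enumerate_pairs(expr, mode="all_pairs")
    if cfg.n_pairs is not None and cfg.n_pairs < pairs.n_pairs:
        sel = np.sort(rng.choice(pairs.n_pairs, size=cfg.n_pairs, replace=False))
        pairs = GenePairList(pairs.gene_ids, pairs.idx_a[sel], pairs.idx_b[sel])
    if cfg.n_causal_edges > pairs.n_pairs:
        raise ValueError("pair subset smaller than n_causal_edges")
    cor = build_edge_matrix(expr, pairs)
    values = cor.values + pop  # pop is the common signal in all variables
    causal = rng.choice(pairs.n_pairs, size=cfg.n_causal_edges, replace=False)
    chosen_snps = rng.choice(cfg.nss, size=cfg.n_causal_edges,
                             replace=cfg.n_causal_edges > cfg.nss)
    effects = cfg.effect_scale * ((np.arange(1, cfg.n_causal_edges + 1))
                                  / cfg.n_causal_edges) ** cfg.effect_exponent
    values[causal] += effects[:, None] * snps[chosen_snps]
    edge_mat = EdgeMatrix(list(cor.row_ids), sample_ids, values)
    truth = SimTruth(
        links=pd.DataFrame({
            "snp": [snp_ids[c] for c in chosen_snps],
            "trait": [cor.row_ids[e] for e in causal],
            "effect": effects,
            "snp_idx": chosen_snps,
            "trait_idx": causal,
        }),
        scenario="edge",
    )
    return GenotypeMatrix(snp_ids, sample_ids, snps), expr, edge_mat, truth


def rank_auc(scores: np.ndarray, is_true: np.ndarray) -> float:
    """Rank-based AUC with midranks for ties.

    Probability that a true link's score exceeds a false link's, counting
    ties as half. ``scores`` and ``is_true`` are flat, equally long arrays.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    is_true = np.asarray(is_true, dtype=bool).ravel()
    n_pos = int(is_true.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both true and false links")
    ranks = stats.rankdata(scores)
    return float((ranks[is_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_auc(scores: Mapping[tuple[str, str], float], truth: SimTruth) -> float:
    """AUC of a (snp, trait) -> score map against planted truth.

    Truth links missing from ``scores`` (untested pairs) are placed at a
    floor value below every reported score.
    """
    truth_keys = set(zip(truth.links["snp"], truth.links["trait"]))
    if not truth_keys:
        raise ValueError("truth is empty")
    keys = list(scores.keys())
    vals = np.array([scores[k] for k in keys], dtype=float)
    floor = (vals.min() if vals.size else 0.0) - 1.0
    missing = truth_keys - set(keys)
    if missing:
        keys.extend(sorted(missing))
        vals = np.concatenate([vals, np.full(len(missing), floor)])
    labels = np.array([k in truth_keys for k in keys])
    if labels.all():
        raise ValueError("truth covers all scored pairs; AUC undefined")
    return rank_auc(vals, labels)


def _gene_scores_from_edges(t_edges: np.ndarray, pairs: GenePairList, ngs: int) -> np.ndarray:
    """Score each gene by its best member-edge statistic (SNPs x genes)."""
    out = np.full((t_edges.shape[0], ngs), -np.inf)
    for g in range(ngs):
        member = np.flatnonzero((pairs.idx_a == g) | (pairs.idx_b == g))
        if member.size:
            out[:, g] = t_edges[:, member].max(axis=1)
    return out


def _edge_scores_from_genes(t_genes: np.ndarray, pairs: GenePairList) -> np.ndarray:
    """Score each edge by the better of its two member-gene statistics."""
    return np.maximum(t_genes[:, pairs.idx_a], t_genes[:, pairs.idx_b])


def _abs_t(G, T) -> np.ndarray:
    _beta, t, _p, _df = linear_stats(G, T)
    return np.abs(np.nan_to_num(t, nan=0.0))


def compare_methods(cfg: SimConfig, seeds: Sequence[int]) -> dict:
    """Benchmark edge-level (nQTL) vs gene-level (eQTL) mapping by AUC.

    For each seed both scenarios are generated at the configured scale and
    both mapping arms are scored by |t| against the planted truth:

    * expression scenario — the gene arm maps SNPs x genes directly; the
      edge arm maps SNPs x (edges built from the genes) and scores a gene by
      its best member-edge statistic;
    * edge scenario — the edge arm maps SNPs x edges directly; the gene arm
      maps SNPs x genes and scores an edge by the better of its two member
      genes.

    Returns ``{"per_seed": DataFrame, "wilcoxon": {scenario: p}}`` where the
    signed-rank test compares the paired AUCs across seeds.
    """
    rows = []
    for seed in seeds:
        c = SimConfig(**{**cfg.__dict__, "seed": int(seed)})
        # --- expression-trait scenario
        G, E, truth = gen_expression_trait_dataset(c)
        t_gene = _abs_t(G, E)
        auc_e = rank_auc(t_gene.ravel(), truth.mask(c.nss, c.ngs).ravel())
        pairs = enumerate_pairs(E, mode="all_pairs")
        edges = build_edge_matrix(E, pairs)
        t_edge = _abs_t(G, edges)
        gene_scores = _gene_scores_from_edges(t_edge, pairs, c.ngs)
        auc_n = rank_auc(gene_scores.ravel(), truth.mask(c.nss, c.ngs).ravel())
        rows.append({"scenario": "expression", "seed": seed,
                     "auc_eqtl": auc_e, "auc_nqtl": auc_n})
        # --- edge-trait scenario
        G, E, edge_mat, truth = gen_edge_trait_dataset(c)
        t_edge = _abs_t(G, edge_mat)
        pairs = enumerate_pairs(E, mode="all_pairs")
        if cfg.n_pairs is not None:
            eid_pos = {e: i for i, e in enumerate(pairs.edge_ids())}
            sel = np.array([eid_pos[e] for e in edge_mat.row_ids])
            pairs = GenePairList(pairs.gene_ids, pairs.idx_a[sel], pairs.idx_b[sel])
        mask = truth.mask(c.nss, edge_mat.n_rows)
        auc_n = rank_auc(t_edge.ravel(), mask.ravel())
        t_gene = _abs_t(G, E)
        edge_scores = _edge_scores_from_genes(t_gene, pairs)
        auc_e = rank_auc(edge_scores.ravel(), mask.ravel())
        rows.append({"scenario": "edge", "seed": seed,
                     "auc_eqtl": auc_e, "auc_nqtl": auc_n})
    per_seed = pd.DataFrame(rows)
    wilcoxon = {}
    for scen, grp in per_seed.groupby("scenario"):
        diff = grp["auc_nqtl"] - grp["auc_eqtl"]
        if len(diff) >= 2 and not np.allclose(diff, 0):
            wilcoxon[scen] = float(stats.wilcoxon(diff).pvalue)
        else:
            wilcoxon[scen] = float("nan")
    return {"per_seed": per_seed, "wilcoxon": wilcoxon}
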