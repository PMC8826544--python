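"""Per-sample co-expression edges.

The Pearson correlation of two genes over ``n`` samples decomposes into a sum
of per-sample products of population z-scores::

    PCC(i, j) = (1/n) * sum_k z_ik * z_jk,   z_ik = (x_ik - mu_i) / sigma_i

Each product ``e_ijk = z_ik * z_jk`` is the edge-like correlation of the
gene-pair (i, j) in sample k: a sample-level quantity whose mean over samples
is exactly the population correlation. Stacking these values for a list of
gene-pairs gives an edges x samples matrix that can be association-mapped
against genotypes the same way an expression matrix is.

The z-scores use the population convention (variance divided by n, not n-1);
with the sample convention the mean-equals-PCC identity would not hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .matrixio import EdgeMatrix, ExpressionMatrix

logger = logging.getLogger("nqtl")

__all__ = [
    "GenePairList",
    "standardize_genes",
    "enumerate_pairs",
    "read_ppi_edges",
    "build_edge_matrix",
    "edge_id",
]

EDGE_SEP = "--"


def edge_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{EDGE_SEP}{gene_b}"


def split_edge_id(eid: str) -> tuple[str, str]:
    a, b = eid.split(EDGE_SEP)
    return a, b


@dataclass
class GenePairList:
    """An ordered list of gene-pairs, indexed into an expression matrix.

    Pairs are stored as row-index arrays (``idx_a[k] < idx_b[k]`` in the
    expression matrix's row order); string edge ids ("geneA--geneB") are
    derived on demand so that all-pairs lists over thousands of genes stay
    cheap to hold.
    """

    gene_ids: list[str]
    idx_a: np.ndarray = field(repr=False)
    idx_b: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.idx_a = np.asarray(self.idx_a, dtype=np.int64)
        self.idx_b = np.asarray(self.idx_b, dtype=np.int64)
        if self.idx_a.shape != self.idx_b.shape:
            raise ValueError("idx_a and idx_b must have equal length")
        if np.any(self.idx_a == self.idx_b):
            raise ValueError("self-pairs are not allowed")
        if np.any(self.idx_a > self.idx_b):
            raise ValueError("pairs must be ordered by expression row position")
        key = self.idx_a * len(self.gene_ids) + self.idx_b
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate pairs")

    def __len__(self) -> int:
        return len(self.idx_a)

    @property
    def n_pairs(self) -> int:
        return len(self.idx_a)

    def pairs(self) -> Iterator[tuple[str, str]]:
        for a, b in zip(self.idx_a, self.idx_b):
            yield self.gene_ids[a], self.gene_ids[b]

    def edge_ids(self) -> list[str]:
        return [edge_id(self.gene_ids[a], self.gene_ids[b])
                for a, b in zip(self.idx_a, self.idx_b)]


def standardize_genes(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Population z-score each gene row; drop zero-variance genes.

    Returns the standardized matrix (each row mean 0, population SD 1) and the
    ids of genes removed for having no variance across samples. Missing cells
    must already be resolved (see ``SampleMatrix.impute_row_means``).

    Raises if fewer than 2 samples or if every gene is constant.
    """
    if expr.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    vals = expr.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("expression matrix contains non-finite values; apply a missing-value policy first")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # ddof=0: population convention
    keep = sd[:, 0] > 0
    if not keep.any():
        raise ValueError("all genes have zero variance across samples")
    dropped = [expr.row_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning("dropping %d zero-variance genes: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    z = (vals[keep] - mu[keep]) / sd[keep]
    out = ExpressionMatrix(
        row_ids=[expr.row_ids[i] for i in np.flatnonzero(keep)],
        sample_ids=list(expr.sample_ids),
        values=z,
    )
    return out, dropped


def read_ppi_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style edge list: node, node, integer combined score.

    The header row, if present, is auto-detected (a third column that does not
    parse as a number is taken to be a header).
    """
    first = pd.read_csv(path, sep=r"\s+", nrows=1, header=None)
    has_header = False
    try:
        float(first.iloc[0, 2])
    except (ValueError, TypeError):
        has_header = True
    frame = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None,
                        usecols=[0, 1, 2])
    frame.columns = ["protein1", "protein2", "combined_score"]
    frame["combined_score"] = frame["combined_score"].astype(float)
    return frame


def enumerate_pairs(
    expr: ExpressionMatrix,
    mode: str = "all_pairs",
    ppi: pd.DataFrame | None = None,
    score_min: float = 900.0,
) -> GenePairList:
    """Enumerate candidate gene-pairs for the edge transformation.

    ``all_pairs`` returns every unordered pair in deterministic row-major
    order over the upper triangle (g*(g-1)/2 pairs for g genes).
    ``ppi_filtered`` keeps only pairs whose interaction score strictly exceeds
    ``score_min`` and whose both members are rows of ``expr``; duplicate and
    reversed records collapse to one canonical pair.
    """
    genes = expr.row_ids
    if mode == "all_pairs":
        ia, ib = np.triu_indices(len(genes), k=1)
        return GenePairList(gene_ids=list(genes), idx_a=ia, idx_b=ib)
    if mode != "ppi_filtered":
        raise ValueError(f"unknown pair mode {mode!r}")
    if ppi is None:
        raise ValueError("ppi_filtered mode requires a PPI edge list")
    pos = {g: i for i, g in enumerate(genes)}
    seen: set[tuple[int, int]] = set()
    for p1, p2, score in ppi.itertuples(index=False):
        if score <= score_min:
            continue
        a, b = pos.get(str(p1)), pos.get(str(p2))
        if a is None or b is None or a == b:
            continue
        seen.add((min(a, b), max(a, b)))
    if not seen:
        raise ValueError(
            "no PPI pairs passed the score filter with both genes present in the "
            "expression matrix — check identifier types (gene symbols vs protein ids)"
        )
    ordered = sorted(seen)
    ia = np.array([p[0] for p in ordered], dtype=np.int64)
    ib = np.array([p[1] for p in ordered], dtype=np.int64)
    return GenePairList(gene_ids=list(genes), idx_a=ia, idx_b=ib)


def build_edge_matrix(
    expr: ExpressionMatrix,
    pairs: GenePairList,
    block_size: int | None = None,
) -> EdgeMatrix:
    """Transform expression into per-sample edge values e_ijk = z_ik * z_jk.

    The mean of each output row over samples equals the population Pearson
    correlation of its member genes. Rows are computed in blocks of
    ``block_size`` pairs (default: all at once); the output is identical for
    any block size.

    Pairs whose member gene was dropped at standardization are removed with a
    warning.
    """
    zed, dropped = standardize_genes(expr)
    if dropped:
        keep_pos = {g: i for i, g in enumerate(zed.row_ids)}
        ok = np.array([
            pairs.gene_ids[a] in keep_pos and pairs.gene_ids[b] in keep_pos
            for a, b in zip(pairs.idx_a, pairs.idx_b)
        ])
        n_removed = int((~ok).sum())
        if n_removed:
            logger.warning("removing %d pairs touching zero-variance genes", n_removed)
        ia = np.array([keep_pos[pairs.gene_ids[a]] for a in pairs.idx_a[ok]], dtype=np.int64)
        ib = np.array([keep_pos[pairs.gene_ids[b]] for b in pairs.idx_b[ok]], dtype=np.int64)
        eids = [edge_id(pairs.gene_ids[a], pairs.gene_ids[b])
                for a, b in zip(pairs.idx_a[ok], pairs.idx_b[ok])]
    else:
        ia, ib = pairs.idx_a, pairs.idx_b
        eids = pairs.edge_ids()
    z = zed.values
    n_pairs = len(ia)
    bs = n_pairs if block_size is None else max(1, int(block_size))
    out = np.empty((n_pairs, zed.n_samples))
    for start in range(0, n_pairs, bs):
        stop = min(start + bs, n_pairs)
        out[start:stop] = z[ia[start:stop]] * z[ib[start:stop]]
    return EdgeMatrix(row_ids=eids, sample_ids=list(zed.sample_ids), values=out)
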