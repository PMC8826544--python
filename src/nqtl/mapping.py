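"""Matrix-form association mapping between SNPs and traits.

Traits may be gene expression rows (eQTL) or per-sample edge rows (nQTL);
the engine is the same. For each (SNP, trait) pair the linear model

    g = alpha + beta * s + eps,    eps ~ iid N(0, sigma^2)

is tested after both sides are residualized against an intercept and any
covariates (residualize-then-correlate, the approach used by large-scale
eQTL engines): the t statistic is ``r * sqrt(df / (1 - r^2))`` with
``df = n - 2 - #covariates`` and ``r`` the correlation of the residualized
rows. The ANOVA variant encodes a {0,1,2} genotype as two indicator columns
and compares the full model against the covariate-only model with an F test.

Because the number of tests at edge scale can be enormous, only records with
``p <= p_report_threshold`` are materialized; the total test count is always
carried so Benjamini-Hochberg FDR is computed against the full multiplicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import GenotypeMatrix, SampleMatrix

logger = logging.getLogger("nqtl")

__all__ = [
    "AssociationTable",
    "residualize",
    "linear_stats",
    "map_linear",
    "map_anova",
    "bh_fdr",
    "empirical_fdr",
    "qq_summary",
    "manhattan_summary",
    "maf_filter",
]

#: smallest reportable p-value; underflowed tests are floored here, never 0
P_FLOOR = np.finfo(float).tiny


@dataclass
class AssociationTable:
    """Materialized (SNP, trait) test records plus the full test count.

    ``records`` has columns snp, trait, beta, stat, p, fdr and holds only the
    tests with ``p <= p_report_threshold``; ``n_tests_total`` counts every
    test performed, reported or not, and is the multiplicity used for FDR.
    """

    records: pd.DataFrame
    n_tests_total: int
    model: str
    p_report_threshold: float
    skipped_traits: list[str] = field(default_factory=list)
    skipped_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = ["snp", "trait", "beta", "stat", "p", "fdr"]
        if list(self.records.columns) != expected:
            raise ValueError(f"records must have columns {expected}")
        if len(self.records) > self.n_tests_total:
            raise ValueError("more records than tests performed")

    def __len__(self) -> int:
        return len(self.records)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, SampleMatrix) else np.asarray(x, dtype=float)


def _covariate_basis(n: int, covariates) -> np.ndarray:
    """Orthonormal basis (n x k) of span{intercept, covariate rows}.

    Raises when the covariate rows are linearly dependent after adding the
    intercept, naming the offending rows.
    """
    design = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        cov = _values(covariates)
        if cov.ndim == 1:
            cov = cov[None, :]
        for i in range(cov.shape[0]):
            design.append(cov[i])
            name = covariates.row_ids[i] if isinstance(covariates, SampleMatrix) else f"covariate_{i}"
            names.append(name)
    D = np.column_stack(design)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify the first row that adds no rank
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) == np.linalg.matrix_rank(D[:, :j]):
                raise ValueError(
                    f"covariates are rank-deficient: row {names[j]!r} is linearly "
                    "dependent on the intercept and preceding covariates"
                )
    Q, _ = np.linalg.qr(D)
    return Q


def residualize(matrix, covariates=None) -> np.ndarray:
    """Project each row onto the orthogonal complement of {intercept, covariates}.

    With no covariates this is plain row-centering. Accepts a SampleMatrix or
    a rows x samples array; returns an array of the same shape.
    """
    X = _values(matrix)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    Q = _covariate_basis(X.shape[1], covariates)
    R = X - (X @ Q) @ Q.T
    return R[0] if one_d else R


def n_covariates(covariates) -> int:
    if covariates is None:
        return 0
    cov = _values(covariates)
    return 1 if cov.ndim == 1 else cov.shape[0]


def linear_stats(G, T, covariates=None):
    """Full matrix-form linear association between all SNP and trait rows.

    Returns ``(beta, tstat, p, df)`` where each matrix is SNPs x traits.
    Zero-variance rows (after residualization) yield NaN columns/rows.
    This is the low-level engine behind :func:`map_linear`; use it when the
    complete statistic matrix is wanted (e.g., for AUC scoring).
    """
    Gv, Tv = _values(G), _values(T)
    n = Gv.shape[1]
    if Tv.shape[1] != n:
        raise ValueError("SNP and trait matrices must share samples")
    ncov = n_covariates(covariates)
    df = n - 2 - ncov
    if df < 1:
        raise ValueError(f"not enough samples: residual df = {df}")
    Gr = residualize(Gv, covariates)
    Tr = residualize(Tv, covariates)
    gnorm = np.linalg.norm(Gr, axis=1)
    tnorm = np.linalg.norm(Tr, axis=1)
    g_ok = gnorm > 0
    t_ok = tnorm > 0
    gn = np.where(g_ok[:, None], Gr / np.where(gnorm[:, None] == 0, 1, gnorm[:, None]), np.nan)
    tn = np.where(t_ok[:, None], Tr / np.where(tnorm[:, None] == 0, 1, tnorm[:, None]), np.nan)
    r = gn @ tn.T
    np.clip(r, -1.0, 1.0, out=r)
    denom = np.maximum(1.0 - r * r, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / denom)
        tstat = np.where(denom == 0, np.sign(r) * np.inf, tstat)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.isnan(tstat), np.nan, np.maximum(p, P_FLOOR))
    # beta on the original (unstandardized) trait scale: trait ~ alpha + beta*snp
    beta = (Gr @ Tr.T) / np.where(gnorm[:, None] == 0, np.nan, gnorm[:, None] ** 2)
    return beta, tstat, p, df


def _collect_records(snp_ids, trait_ids, beta, stat, p, threshold):
    mask = p <= threshold
    si, ti = np.nonzero(mask)
    return pd.DataFrame({
        "snp": np.asarray(snp_ids, dtype=object)[si],
        "trait": np.asarray(trait_ids, dtype=object)[ti],
        "beta": beta[si, ti],
        "stat": stat[si, ti],
        "p": p[si, ti],
        "fdr": np.nan,
    })


def _drop_monomorphic(G: SampleMatrix):
    var = _values(G).var(axis=1)
    keep = var > 0
    skipped = [G.row_ids[i] for i in np.flatnonzero(~keep)]
    if skipped:
        logger.warning("removing %d monomorphic SNPs", len(skipped))
        G = G.subset_rows(keep)
    return G, skipped


def map_linear(
    G: GenotypeMatrix,
    T: SampleMatrix,
    covariates=None,
    p_report_threshold: float = 1e-2,
    block_size: int = 2000,
) -> AssociationTable:
    """Linear SNP x trait mapping; materializes records with p <= threshold.

    Trait rows are processed in blocks of ``block_size`` so the full
    SNPs x traits statistic matrix never needs to be held at once; the record
    set is identical for any block size.
    """
    if p_report_threshold <= 0:
        raise ValueError("p_report_threshold must be positive")
    G, skipped_snps = _drop_monomorphic(G)
    t_var = _values(T).var(axis=1)
    skipped_traits = [T.row_ids[i] for i in np.flatnonzero(t_var == 0)]
    if skipped_traits:
        logger.warning("skipping %d zero-variance traits", len(skipped_traits))
        T = T.subset_rows(t_var > 0)
    chunks = []
    bs = max(1, int(block_size))
    for start in range(0, T.n_rows, bs):
        block = T.subset_rows(np.arange(start, min(start + bs, T.n_rows)))
        beta, tstat, p, _df = linear_stats(G, block, covariates)
        chunks.append(_collect_records(G.row_ids, block.row_ids, beta, tstat, p,
                                       p_report_threshold))
    records = pd.concat(chunks, ignore_index=True) if chunks else _collect_records(
        [], [], np.empty((0, 0)), np.empty((0, 0)), np.empty((0, 0)), 1.0)
    n_total = G.n_rows * T.n_rows
    records["fdr"] = bh_fdr(records["p"].to_numpy(), n_total)
    return AssociationTable(records, n_total, "linear", p_report_threshold,
                            skipped_traits, skipped_snps)


def map_anova(
    G: GenotypeMatrix,
    T: SampleMatrix,
    covariates=None,
    p_report_threshold: float = 1e-2,
) -> AssociationTable:
    """ANOVA SNP x trait mapping for {0,1,2}-coded genotypes.

    Genotype classes 1 and 2 become indicator columns against baseline 0; the
    F statistic compares the full model with the covariate-only model. SNPs
    with a single genotype class are skipped; with two classes the test
    degrades to one indicator (numerator df 1, logged).
    """
    if p_report_threshold <= 0:
        raise ValueError("p_report_threshold must be positive")
    Gv = _values(G)
    if not np.all(np.isin(Gv, (0.0, 1.0, 2.0))):
        raise ValueError("ANOVA mode requires genotype values coded 0/1/2")
    Tv = _values(T)
    n = Gv.shape[1]
    ncov = n_covariates(covariates)
    t_var = Tv.var(axis=1)
    skipped_traits = [T.row_ids[i] for i in np.flatnonzero(t_var == 0)]
    if skipped_traits:
        logger.warning("skipping %d zero-variance traits", len(skipped_traits))
    t_keep = np.flatnonzero(t_var > 0)
    Tk = Tv[t_keep]
    trait_ids = np.asarray(T.row_ids, dtype=object)[t_keep]
    Q0 = _covariate_basis(n, covariates)
    T0 = Tk - (Tk @ Q0) @ Q0.T  # residuals under the reduced model
    rss_red = (T0 * T0).sum(axis=1)
    rows = []
    skipped_snps = []
    n_tested = 0
    for s_idx, snp in enumerate(G.row_ids):
        g = Gv[s_idx]
        classes = sorted(set(g.tolist()))
        if len(classes) < 2:
            skipped_snps.append(snp)
            continue
        q = len(classes) - 1
        if q == 1:
            logger.debug("SNP %s has two genotype classes; one indicator used", snp)
        dummies = np.column_stack([(g == c).astype(float) for c in classes[1:]])
        df_den = n - 1 - q - ncov
        if df_den < 1:
            skipped_snps.append(snp)
            continue
        full = np.column_stack([Q0, dummies])
        Qf, _ = np.linalg.qr(full)
        Tf = Tk - (Tk @ Qf) @ Qf.T
        rss_full = (Tf * Tf).sum(axis=1)
        n_tested += len(Tk)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / q) / (rss_full / df_den)
        F = np.where(rss_full <= 0, np.inf, np.maximum(F, 0.0))
        p = np.maximum(stats.f.sf(F, q, df_den), P_FLOOR)
        mask = p <= p_report_threshold
        if mask.any():
            rows.append(pd.DataFrame({
                "snp": snp,
                "trait": trait_ids[mask],
                "beta": np.nan,
                "stat": F[mask],
                "p": p[mask],
                "fdr": np.nan,
            }))
    records = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["snp", "trait", "beta", "stat", "p", "fdr"]))
    records["fdr"] = bh_fdr(records["p"].to_numpy(dtype=float), max(n_tested, 1))
    return AssociationTable(records, max(n_tested, 1), "anova", p_report_threshold,
                            skipped_traits, skipped_snps)


def bh_fdr(p_values, n_tests_total: int) -> np.ndarray:
    """Benjamini-Hochberg q-values with an explicit total multiplicity.

    ``n_tests_total`` may exceed ``len(p_values)`` when only the smallest
    p-values were materialized; unmaterialized tests necessarily rank after
    the reported ones, so the step-up is still exact.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests_total < p.size:
        raise ValueError("n_tests_total smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * n_tests_total / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def empirical_fdr(
    G: GenotypeMatrix,
    T: SampleMatrix,
    covariates=None,
    threshold: float = 1e-5,
    n_perm: int = 10,
    seed: int = 0,
) -> float:
    """Permutation-based false discovery estimate at a fixed p threshold.

    Sample columns of the genotype matrix are permuted (breaking the
    genotype-trait link while preserving the trait correlation structure) and
    the mapping is rerun; the estimate is the mean over permutations of the
    permuted discovery count divided by the observed discovery count.

    Returns NaN when the observed run has no discoveries at the threshold.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _beta, _t, p, _df = linear_stats(G, T, covariates)
    observed = int(np.nansum(p <= threshold))
    if observed == 0:
        logger.warning("no observed discoveries at p <= %g; empirical FDR undefined", threshold)
        return float("nan")
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_perm):
        perm = rng.permutation(G.n_samples)
        Gp = GenotypeMatrix(list(G.row_ids), list(G.sample_ids), G.values[:, perm])
        _b, _t2, pp, _d = linear_stats(Gp, T, covariates)
        ratios.append(int(np.nansum(pp <= threshold)) / observed)
    return float(np.mean(ratios))


def qq_summary(assoc) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Accepts an AssociationTable (its materialized records) or a p-value
    sequence. Expected quantile for ascending rank i of m is (i - 0.5)/m.
    """
    if isinstance(assoc, AssociationTable):
        p = assoc.records["p"].to_numpy(dtype=float)
    else:
        p = np.asarray(assoc, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to summarize")
    obs = np.sort(p)
    m = obs.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(np.maximum(obs, P_FLOOR)),
    })


def manhattan_summary(assoc: AssociationTable, snp_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Best association per SNP, ready for a Manhattan plot.

    ``snp_annotation``, if given, has columns snp, chrom, pos; unannotated
    SNPs keep their record order.
    """
    recs = assoc.records
    best = recs.groupby("snp", sort=False)["p"].min().reset_index()
    best["neglog10_p"] = -np.log10(np.maximum(best["p"].to_numpy(), P_FLOOR))
    if snp_annotation is not None:
        ann = snp_annotation.rename(columns=dict(zip(snp_annotation.columns[:3],
                                                     ["snp", "chrom", "pos"])))
        best = best.merge(ann[["snp", "chrom", "pos"]], on="snp", how="left")
        best = best.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return best


def maf_filter(G: GenotypeMatrix, maf_min: float = 0.0) -> GenotypeMatrix:
    """Drop SNPs whose minor-allele frequency falls below ``maf_min``.

    Requires {0,1,2} dosage coding. The default 0 leaves the matrix
    untouched (filter off).
    """
    vals = _values(G)
    if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError("MAF filter requires genotype values coded 0/1/2")
    alt = vals.sum(axis=1) / (2 * G.n_samples)
    maf = np.minimum(alt, 1 - alt)
    keep = maf >= maf_min
    if not keep.all():
        logger.info("MAF filter removed %d of %d SNPs", int((~keep).sum()), G.n_rows)
    return G.subset_rows(keep)
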