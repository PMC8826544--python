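"""Linking network signatures to phenotypes.

Three complementary links close the genotype -> network -> phenotype
cascade:

* class phenotypes — PLS discriminant analysis of a module's per-sample edge
  values against class labels, with stratified cross-validated AUC;
* factor panels — first canonical correlation between the module block and a
  block of measured factors, ridge-regularized (modules typically have more
  edges than samples) with permutation significance;
* survival — a two-group log-rank test on the median split of a per-sample
  module score (the first principal component of the module's edge
  submatrix).

Modules are finally ranked by phenotype-link significance, then by their
genotype link counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .mapping import AssociationTable
from .modules import ModuleSet

logger = logging.getLogger("nqtl")

__all__ = [
    "PLSDAResult",
    "CCAResult",
    "plsda",
    "cca_first",
    "module_score",
    "survival_association",
    "rank_cascades",
]


@dataclass
class PLSDAResult:
    n_components: int
    classes: list
    scores: np.ndarray          # samples x components, training fit
    assignments: np.ndarray     # predicted class per sample (training fit)
    cv_auc: float               # stratified CV AUC (2-class) / macro OVR AUC


@dataclass
class CCAResult:
    rho: float
    a: np.ndarray
    b: np.ndarray
    perm_p: float
    n_perm: int
    ridge: float


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    return np.column_stack([(labels == c).astype(float) for c in classes])


def _centroid_assign(scores: np.ndarray, train_scores: np.ndarray,
                     train_labels: np.ndarray, classes: list) -> np.ndarray:
    cents = np.vstack([train_scores[train_labels == c].mean(axis=0) for c in classes])
    d = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(classes, dtype=object)[d.argmin(axis=1)]


def plsda(module_x: np.ndarray, labels, n_components: int = 2,
          cv_folds: int = 5, seed: int = 0) -> PLSDAResult:
    """PLS discriminant analysis of samples x features against class labels.

    A two-block PLS is fit against one-hot labels; samples are classified by
    the nearest class centroid in score space. The reported AUC is from
    stratified cross-validation using the continuous predicted class scores
    (macro one-vs-rest for >2 classes).
    """
    X = np.asarray(module_x, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLSDA requires at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < cv_folds:
        raise ValueError(f"every class needs >= cv_folds={cv_folds} members, got {counts}")
    ncomp = min(n_components, X.shape[1], X.shape[0] - 1)
    Y = _one_hot(labels, classes)
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X, Y)
    scores = pls.x_scores_
    assignments = _centroid_assign(scores, scores, labels, classes)
    # cross-validated AUC on continuous predicted class memberships
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.zeros_like(Y)
    for tr, te in skf.split(X, labels):
        ncomp_cv = min(ncomp, len(tr) - 1)
        m = PLSRegression(n_components=ncomp_cv, scale=False)
        m.fit(X[tr], Y[tr])
        pred[te] = m.predict(X[te])
    if len(classes) == 2:
        cv_auc = roc_auc_score((labels == classes[1]).astype(int), pred[:, 1])
    else:
        cv_auc = roc_auc_score(Y, pred, average="macro", multi_class="ovr")
    return PLSDAResult(ncomp, classes, scores, assignments, float(cv_auc))


def cca_first(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-3,
              n_perm: int = 1000, seed: int = 0) -> CCAResult:
    """First canonical correlation between two samples x variables blocks.

    Solves the ridge-regularized canonical eigenproblem on centered blocks;
    the regularizer added to each block covariance is ``ridge`` times that
    block's mean variance (so ridge=0 recovers classical CCA, and any
    positive value keeps the problem well-posed when variables outnumber
    samples). Significance is by permutation of Y's rows:
    p = (1 + #{rho_perm >= rho}) / (1 + n_perm).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")

    def drop_constant(M, name):
        sd = M.std(axis=0)
        if (sd == 0).any():
            logger.warning("dropping %d zero-variance columns from %s",
                           int((sd == 0).sum()), name)
            M = M[:, sd > 0]
        if M.shape[1] == 0:
            raise ValueError(f"block {name} has no varying columns")
        return M

    X = drop_constant(X, "X")
    Y = drop_constant(Y, "Y")
    if ridge == 0 and (X.shape[1] >= n or Y.shape[1] >= n):
        raise ValueError("ridge > 0 required when a block has >= n variables")

    def solve(Xc, Yc):
        Xc = Xc - Xc.mean(axis=0)
        Yc = Yc - Yc.mean(axis=0)
        Sxx = Xc.T @ Xc / (n - 1)
        Syy = Yc.T @ Yc / (n - 1)
        Sxy = Xc.T @ Yc / (n - 1)
        Sxx = Sxx + ridge * np.trace(Sxx) / Sxx.shape[0] * np.eye(Sxx.shape[0])
        Syy = Syy + ridge * np.trace(Syy) / Syy.shape[0] * np.eye(Syy.shape[0])
        L = np.linalg.cholesky(Sxx)
        R = np.linalg.cholesky(Syy)
        M = np.linalg.solve(L, Sxy)
        M = np.linalg.solve(R, M.T).T     # L^-1 Sxy R^-T
        U, s, Vt = np.linalg.svd(M)
        a = np.linalg.solve(L.T, U[:, 0])
        b = np.linalg.solve(R.T, Vt[0])
        u, v = Xc @ a, Yc @ b
        denom = u.std() * v.std()
        rho = 0.0 if denom == 0 else abs(float(np.mean((u - u.mean()) * (v - v.mean()))) / denom)
        return min(rho, 1.0), a, b

    rho, a, b = solve(X, Y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho_p, _, _ = solve(X, Y[perm])
        if rho_p >= rho:
            exceed += 1
    perm_p = (1 + exceed) / (1 + n_perm)
    return CCAResult(rho, a, b, float(perm_p), n_perm, ridge)


def module_score(edge_submatrix: np.ndarray) -> np.ndarray:
    """Per-sample module score: first principal component of samples x edges.

    The sign is fixed so the loading with the largest magnitude is positive,
    making the score deterministic.
    """
    X = np.asarray(edge_submatrix, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[0]
    sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
    return sign * U[:, 0] * s[0]


def survival_association(module_scores: np.ndarray, survival: pd.DataFrame,
                         split: str = "median") -> tuple[float, float]:
    """Two-group log-rank test on a split of the module score.

    ``survival`` needs columns ``time`` (> 0) and ``event`` (1 = observed,
    0 = censored); tied event times are handled by the standard
    hypergeometric increments. Returns (chi-square, p).
    """
    if split != "median":
        raise ValueError("only the median split is implemented")
    scores = np.asarray(module_scores, dtype=float)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("all samples censored; log-rank test undefined")
    high = scores > np.median(scores)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split leaves a group with fewer than 2 samples")
    res = logrank_test(time[high], time[~high],
                       event_observed_A=event[high], event_observed_B=event[~high])
    return float(res.test_statistic), float(res.p_value)


def rank_cascades(modules: ModuleSet, assoc: AssociationTable,
                  phenotype_p: dict[int, float],
                  p_threshold: float = 1e-5) -> pd.DataFrame:
    """Rank genotype -> network -> phenotype cascades.

    One row per module: its best SNP-link p, its significant-link count and
    the supplied phenotype-link p (from PLSDA/CCA/log-rank). Ordering is
    lexicographic: phenotype p ascending, link count descending, module
    index ascending; missing phenotype results sort last.
    """
    recs = assoc.records
    rows = []
    for m in range(1, modules.k + 1):
        edges = set(modules.members(m))
        sub = recs[recs["trait"].isin(edges)]
        n_links = int((sub["p"] <= p_threshold).sum())
        best_p = float(sub["p"].min()) if len(sub) else float("nan")
        rows.append({
            "module": m,
            "n_edges": len(edges),
            "best_snp_p": best_p,
            "n_links": n_links,
            "phenotype_p": float(phenotype_p.get(m, np.nan)),
        })
    table = pd.DataFrame(rows)
    key = table["phenotype_p"].fillna(np.inf)
    order = np.lexsort((table["module"], -table["n_links"], key))
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
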