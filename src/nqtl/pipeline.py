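"""End-to-end orchestration: transform -> map -> modules -> link -> rank.

A :class:`RunConfig` names the input files and every stage parameter; the
pipeline writes all intermediate and final tables as TSV/JSON beside a run
log and the resolved configuration, so any run is reproducible from the
config plus its seed.

The phenotype table is one TSV with a ``sample`` column and any of: a
``label`` column (class phenotype, PLSDA), ``time``/``event`` columns
(survival, log-rank) and any further numeric columns (factor panel, CCA).
Stages whose inputs are absent are skipped with a notice; earlier outputs
stay intact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import edges as edgekit
from . import mapping, modules as sigminer, pheno
from .matrixio import align_samples, read_matrix, write_matrix

logger = logging.getLogger("nqtl")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All file paths and stage parameters for one pipeline run."""

    expr: str
    snps: str
    out_dir: str
    covariates: str | None = None
    ppi: str | None = None
    phenotype: str | None = None
    snp_annotation: str | None = None
    # edge transformation
    pair_mode: str = "all_pairs"        # or "ppi_filtered"
    ppi_score_min: float = 900.0
    block_size: int = 2000
    write_edge_matrix: bool = True
    # mapping
    model: str = "linear"               # or "anova"
    p_report_threshold: float = 1e-5
    maf_min: float = 0.0
    # hot filtering / modules
    hot_p_threshold: float = 1e-5
    top_edges: int = 1000
    min_snp_connections: int | None = None
    profile_mode: str = "neglog"
    profile_cap: float = 16.0
    k_modules: int = 10
    # phenotype linking
    plsda_components: int = 2
    cv_folds: int = 5
    n_perm: int = 1000
    cca_ridge: float = 1e-3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _read_phenotype(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    tab = tab.rename(columns={tab.columns[0]: "sample"}).set_index("sample")
    return tab


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full cascade analysis; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        cfg.to_yaml(out / "config.yaml")
        _run(cfg, out)
    except Exception as exc:  # annotate which stage failed
        (out / "FAILED").write_text(str(exc))
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _run(cfg: RunConfig, out: Path) -> None:
    stage = "read"
    logger.info("[%s] loading inputs", stage)
    expr = read_matrix(cfg.expr, "expression")
    snps = read_matrix(cfg.snps, "genotype")
    cov = read_matrix(cfg.covariates, "covariate") if cfg.covariates else None
    mats = align_samples(expr, snps, *( [cov] if cov is not None else [] ))
    expr, snps = mats[0], mats[1]
    cov = mats[2] if cov is not None else None
    expr, n_imputed = expr.impute_row_means()
    if n_imputed:
        logger.info("[read] imputed %d missing expression cells by row means", n_imputed)
    if cfg.maf_min > 0:
        snps = mapping.maf_filter(snps, cfg.maf_min)

    stage = "transform"
    logger.info("[%s] building edge matrix (%s)", stage, cfg.pair_mode)
    ppi = edgekit.read_ppi_edges(cfg.ppi) if cfg.ppi else None
    pairs = edgekit.enumerate_pairs(expr, mode=cfg.pair_mode, ppi=ppi,
                                    score_min=cfg.ppi_score_min)
    edge_mat = edgekit.build_edge_matrix(expr, pairs, block_size=cfg.block_size)
    if cfg.write_edge_matrix:
        write_matrix(edge_mat, out / "edges.tsv", label="edge")

    stage = "map"
    logger.info("[%s] mapping %d SNPs x %d edges (%s model)", stage,
                snps.n_rows, edge_mat.n_rows, cfg.model)
    if cfg.model == "linear":
        assoc = mapping.map_linear(snps, edge_mat, cov, cfg.p_report_threshold,
                                   block_size=cfg.block_size)
    elif cfg.model == "anova":
        assoc = mapping.map_anova(snps, edge_mat, cov, cfg.p_report_threshold)
    else:
        raise ValueError(f"[map] unknown model {cfg.model!r}")
    assoc.records.to_csv(out / "associations.tsv", sep="\t", index=False,
                         float_format="%.6g")
    meta = {"n_tests_total": assoc.n_tests_total, "model": assoc.model,
            "p_report_threshold": assoc.p_report_threshold, "seed": cfg.seed,
            "n_records": len(assoc), "n_skipped_traits": len(assoc.skipped_traits),
            "n_skipped_snps": len(assoc.skipped_snps)}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    if len(assoc):
        mapping.qq_summary(assoc).to_csv(out / "qq.tsv", sep="\t", index=False)
        ann = (pd.read_csv(cfg.snp_annotation, sep="\t")
               if cfg.snp_annotation else None)
        mapping.manhattan_summary(assoc, ann).to_csv(out / "manhattan.tsv",
                                                     sep="\t", index=False)

    stage = "modules"
    edge_counts = sigminer.count_links(assoc, "edge", cfg.hot_p_threshold)
    snp_counts = sigminer.count_links(assoc, "snp", cfg.hot_p_threshold)
    hot_edges = sigminer.hot_select(edge_counts, top_k=cfg.top_edges,
                                    min_count=cfg.min_snp_connections)
    hot_snps = sigminer.hot_select(snp_counts, top_k=None, min_count=1)
    if not hot_edges or not hot_snps:
        logger.warning("[%s] no hot edges/SNPs at p<=%g; later stages skipped",
                       stage, cfg.hot_p_threshold)
        return
    profile = sigminer.build_profile(assoc, hot_edges, hot_snps,
                                     mode=cfg.profile_mode,
                                     p_threshold=cfg.hot_p_threshold,
                                     cap=cfg.profile_cap)
    pd.DataFrame(profile.values, index=profile.edge_ids,
                 columns=profile.snp_ids).to_csv(out / "profile.tsv", sep="\t")
    mods = sigminer.cluster_modules(profile, k=min(cfg.k_modules, len(hot_edges)))
    pd.DataFrame(sorted(mods.labels.items()),
                 columns=["edge", "module"]).to_csv(out / "modules.tsv",
                                                    sep="\t", index=False)
    sigminer.module_report(mods, assoc, cfg.hot_p_threshold).to_csv(
        out / "module_summary.tsv", sep="\t", index=False)

    stage = "link"
    phenotype_p: dict[int, float] = {}
    link_results: dict[str, dict] = {}
    if cfg.phenotype:
        ptab = _read_phenotype(cfg.phenotype)
        missing = [s for s in edge_mat.sample_ids if s not in ptab.index]
        if missing:
            raise ValueError(f"[link] phenotype table missing samples: {missing[:5]}")
        ptab = ptab.loc[list(edge_mat.sample_ids)]
        factor_cols = [c for c in ptab.columns
                       if c not in ("label", "time", "event")
                       and pd.api.types.is_numeric_dtype(ptab[c])]
        eid_pos = {e: i for i, e in enumerate(edge_mat.row_ids)}
        for m in range(1, mods.k + 1):
            edges_m = [e for e in mods.members(m) if e in eid_pos]
            X = edge_mat.values[[eid_pos[e] for e in edges_m]].T  # samples x edges
            res: dict = {"module": m, "n_edges": len(edges_m)}
            p_candidates = []
            if "label" in ptab.columns:
                try:
                    r = pheno.plsda(X, ptab["label"].to_numpy(),
                                    n_components=cfg.plsda_components,
                                    cv_folds=cfg.cv_folds, seed=cfg.seed)
                    res["plsda_cv_auc"] = r.cv_auc
                except ValueError as exc:
                    logger.warning("[link] PLSDA skipped for module %d: %s", m, exc)
            if factor_cols:
                r = pheno.cca_first(X, ptab[factor_cols].to_numpy(dtype=float),
                                    ridge=cfg.cca_ridge, n_perm=cfg.n_perm,
                                    seed=cfg.seed)
                res["cca_rho"] = r.rho
                res["cca_perm_p"] = r.perm_p
                p_candidates.append(r.perm_p)
            if {"time", "event"} <= set(ptab.columns):
                try:
                    score = pheno.module_score(X)
                    chi2, p = pheno.survival_association(score, ptab)
                    res["logrank_chi2"] = chi2
                    res["logrank_p"] = p
                    p_candidates.append(p)
                except ValueError as exc:
                    logger.warning("[link] log-rank skipped for module %d: %s", m, exc)
            if p_candidates:
                phenotype_p[m] = min(p_candidates)
            elif "plsda_cv_auc" in res:
                # discriminative link only: convert AUC to a rank key (1 - AUC)
                phenotype_p[m] = 1.0 - res["plsda_cv_auc"]
            link_results[str(m)] = res
        (out / "phenotype_links.json").write_text(json.dumps(link_results, indent=2))
    else:
        logger.info("[link] no phenotype table configured; stage skipped")

    stage = "rank"
    cascades = pheno.rank_cascades(mods, assoc, phenotype_p, cfg.hot_p_threshold)
    cascades.to_csv(out / "cascades.tsv", sep="\t", index=False,
                    float_format="%.6g")
    logger.info("[%s] wrote %d cascades", stage, len(cascades))
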