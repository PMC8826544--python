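"""Labelled samples-in-columns matrices and their TSV dialect.

Every data block in the pipeline — expression, genotype, covariates, edge
values — is a features x samples real matrix with a feature id in the first
column and sample ids in the header row (the MatrixEQTL file convention).
:class:`SampleMatrix` is the shared in-memory container; the thin subclasses
exist so signatures can say what kind of block they expect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nqtl")

__all__ = [
    "SampleMatrix",
    "ExpressionMatrix",
    "GenotypeMatrix",
    "EdgeMatrix",
    "CovariateMatrix",
    "read_matrix",
    "write_matrix",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class SampleMatrix:
    """A features x samples real matrix with row and column labels."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (rows x samples)")
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.sample_ids, "sample")

    # -- basic views ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    # -- manipulation --------------------------------------------------
    def subset_rows(self, keep: np.ndarray) -> "SampleMatrix":
        """Return a copy restricted to rows selected by a boolean/index array."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return type(self)(
            row_ids=[self.row_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "SampleMatrix":
        """Return a copy with columns in the given sample order.

        Raises if any requested sample is absent.
        """
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples not present: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return type(self)(
            row_ids=list(self.row_ids),
            sample_ids=[str(s) for s in sample_ids],
            values=self.values[:, idx],
        )

    def impute_row_means(self) -> tuple["SampleMatrix", int]:
        """Replace missing cells by their row mean; drop all-missing rows.

        Returns the cleaned matrix and the number of imputed cells.
        """
        vals = self.values.copy()
        mask = ~np.isfinite(vals)
        n_imputed = int(mask.sum())
        if n_imputed:
            row_ok = (~mask).sum(axis=1) > 0
            if not row_ok.all():
                dropped = [self.row_ids[i] for i in np.flatnonzero(~row_ok)]
                logger.warning("dropping %d all-missing rows: %s", len(dropped), dropped[:5])
            with np.errstate(invalid="ignore"):
                means = np.nanmean(np.where(mask, np.nan, vals), axis=1)
            rows, cols = np.nonzero(mask)
            vals[rows, cols] = means[rows]
            out = type(self)(list(self.row_ids), list(self.sample_ids), vals)
            if not row_ok.all():
                out = out.subset_rows(row_ok)
            return out, n_imputed
        return self, 0


class ExpressionMatrix(SampleMatrix):
    """Genes x samples expression levels (x_ik)."""


class GenotypeMatrix(SampleMatrix):
    """SNPs x samples genotype scores (dosages 0/1/2 or real scores)."""


class EdgeMatrix(SampleMatrix):
    """Gene-pairs x samples single-sample co-expression values (e_ijk)."""


class CovariateMatrix(SampleMatrix):
    """Covariates x samples nuisance variables."""


_KINDS = {
    "expression": ExpressionMatrix,
    "genotype": GenotypeMatrix,
    "edge": EdgeMatrix,
    "covariate": CovariateMatrix,
    "generic": SampleMatrix,
}


def read_matrix(path: str | Path, kind: str = "generic") -> SampleMatrix:
    """Read a features x samples TSV (feature ids in column 1, sample header).

    ``NA`` and empty cells become NaN for the caller's missing-value policy.
    Duplicate feature or sample ids, or non-numeric cells, raise with the file
    name and offending position.
    """
    path = Path(path)
    if kind not in _KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; one of {sorted(_KINDS)}")
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], dtype=str)
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                row = frame.index[np.flatnonzero(bad)[0]]
                raise ValueError(
                    f"{path.name}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    try:
        return _KINDS[kind](
            row_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=values,
        )
    except ValueError as exc:
        raise ValueError(f"{path.name}: {exc}") from None


def write_matrix(mat: SampleMatrix, path: str | Path, label: str = "id") -> None:
    """Write a matrix as the TSV dialect used throughout the pipeline."""
    frame = mat.to_frame()
    frame.index.name = label
    frame.to_csv(path, sep="\t", float_format="%.10g")


def align_samples(*mats: SampleMatrix) -> list[SampleMatrix]:
    """Reorder every matrix to the sample order of the first.

    All matrices must contain exactly the same sample ids; differing order is
    fixed with a log note, differing membership is an error.
    """
    ref = mats[0]
    ref_set = set(ref.sample_ids)
    out = [ref]
    for m in mats[1:]:
        if set(m.sample_ids) != ref_set:
            extra = sorted(set(m.sample_ids) - ref_set)[:5]
            missing = sorted(ref_set - set(m.sample_ids))[:5]
            raise ValueError(
                f"sample ids differ between matrices (extra={extra}, missing={missing})"
            )
        if m.sample_ids != ref.sample_ids:
            logger.info("reordering %d sample columns to match reference", m.n_samples)
            m = m.reorder_samples(ref.sample_ids)
        out.append(m)
    return out
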