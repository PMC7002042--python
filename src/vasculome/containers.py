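"""In-memory carriers shared by all pipeline stages.

The central object is :class:`ExpressionMatrix`, a gene x sample value matrix
(raw counts or log2 expression) paired with a per-sample metadata table.  Bulk
translatome samples carry tissue / compartment / timepoint / batch annotations;
single-cell matrices reuse the same container with one "sample" per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

#: metadata columns every bulk sample table carries
SAMPLE_COLUMNS = ("tissue", "compartment", "timepoint_h", "batch", "platform", "replicate")

COMPARTMENTS = ("EC", "whole")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.  Raw
        counts (``scale="counts"``) or log2 expression (``scale="log2"``).
    samples
        DataFrame indexed by sample id (same order as ``values`` columns).
        For bulk data the columns of :data:`SAMPLE_COLUMNS` are expected;
        single-cell tables may carry ``tissue`` and ``cell_type`` only.
    scale
        ``"counts"`` or ``"log2"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise DomainError(f"unknown scale {self.scale!r}; expected 'counts' or 'log2'")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DomainError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise DomainError("duplicate sample ids")
        if not self.values.columns.equals(self.samples.index):
            # tolerate same labels in same order under different index names
            if list(self.values.columns) != list(self.samples.index):
                raise DomainError("sample metadata index does not match value columns")
        if self.scale == "counts":
            arr = self.values.to_numpy()
            if arr.size and arr.min() < 0:
                raise DomainError("counts must be nonnegative")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> pd.Series:
        if self.scale != "counts":
            raise DomainError("library sizes are defined on the counts scale")
        return self.values.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes, name=self.gene_ids.name)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise DomainError(f"genes absent from matrix: {sorted(missing)[:10]}")
        return replace(self, values=self.values.loc[genes])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = pd.Index(sample_ids)
        return replace(self, values=self.values[ids], samples=self.samples.loc[ids])

    def where_samples(self, **criteria) -> "ExpressionMatrix":
        """Subset samples by metadata equality, e.g. ``where_samples(tissue="brain")``."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return self.subset_samples(self.samples.index[mask])


@dataclass
class DifferentialTable:
    """Per-gene differential-expression results for one contrast.

    ``table`` columns: gene (index), logFC, t, p, q, mean_expr.
    """

    table: pd.DataFrame
    contrast: str

    COLUMNS = ("logFC", "t", "p", "q", "mean_expr")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise DomainError(f"DifferentialTable missing columns {missing}")

    def significant_up(self, fdr_max: float = 0.05, logfc_min: float = 0.0) -> pd.DataFrame:
        tab = self.table
        return tab[(tab["q"] < fdr_max) & (tab["logFC"] > logfc_min)]


@dataclass
class SignatureResult:
    """One tissue's signature: the DE table plus derived marker lists."""

    tissue: str
    table: DifferentialTable
    up_genes: list[str]
    top_markers: list[str]
    surface_markers: list[str] = field(default_factory=list)


@dataclass
class PurityReport:
    """Rank-correlation contamination assessment between cell-type-enriched and
    whole-tissue samples."""

    tau_matrix: pd.DataFrame          # EC samples x whole-tissue samples
    gene_selection: list[str]
    selection_rule: str
    tissue_summary: pd.DataFrame      # per tissue: min / max / mean tau


@dataclass
class ConcordanceReport:
    """Cross-platform (bulk vs single-cell) concordance summary."""

    housekeeping_gene: str
    rho: pd.DataFrame                 # rows: (tissue, gene_subset); cols: rho, n_shared
    overlap: pd.DataFrame             # rows: (tissue, k); cols: overlap


@dataclass
class TrajectoryCall:
    """Rule-based classification of one gene's time course in one tissue."""

    gene: str
    tissue: str
    pattern: str                      # stable / transient_up / transient_down / sustained_up / sustained_down
    peak_timepoint_h: float
    peak_log2_change: float
    recovered_by_h: float | None


def as_float_array(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr
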