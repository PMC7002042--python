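"""Cross-platform concordance between bulk translatome and single-cell data.

All expression values are first anchored to an invariable housekeeping gene
(per-sample fold changes), which makes profiles from different platforms
comparable in relative abundance; concordance is then Spearman correlation
of per-tissue mean fold changes over shared detected genes, plus top-k
marker-list overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import DomainError
from .stats import spearman_rho

__all__ = [
    "select_housekeeping",
    "hk_fold_change",
    "platform_concordance",
    "top_marker_overlap",
    "parenchymal_gene_set",
    "pseudobulk_by_tissue",
]


def pseudobulk_by_tissue(sc: ExpressionMatrix) -> ExpressionMatrix:
    """Per-tissue mean CPM over cells, returned as a log2 matrix with one
    pseudo-sample per tissue."""
    lib = sc.library_sizes()
    cpm = sc.values / lib * 1e6
    tissues = sorted(sc.samples["tissue"].unique())
    cols = {
        t: cpm.loc[:, sc.samples.index[sc.samples["tissue"] == t]].mean(axis=1)
        for t in tissues
    }
    values = np.log2(pd.DataFrame(cols) + 0.5)
    meta = pd.DataFrame({"tissue": tissues}, index=pd.Index(tissues, name="sample_id"))
    return ExpressionMatrix(values=values, samples=meta, scale="log2")


def _linear_values(expr: ExpressionMatrix) -> pd.DataFrame:
    """Linear-scale expression: CPM for counts, 2**x for log2 matrices."""
    if expr.scale == "counts":
        lib = expr.library_sizes()
        return expr.values / lib * 1e6
    return 2.0**expr.values


def select_housekeeping(
    datasets: list[ExpressionMatrix], min_expression: float = 1.0
) -> str:
    """The gene most invariable across all datasets.

    Among genes whose linear expression exceeds ``min_expression`` in every
    sample of every dataset, returns the gene minimising the maximum
    per-dataset coefficient of variation; ties break lexicographically.
    """
    if len(datasets) < 2:
        raise DomainError("need at least 2 datasets")
    shared = datasets[0].gene_ids
    for d in datasets[1:]:
        shared = shared.intersection(d.gene_ids)
    if shared.empty:
        raise DomainError("datasets share no genes")
    linears = [_linear_values(d).loc[shared] for d in datasets]
    expressed = pd.Series(True, index=shared)
    for lin in linears:
        expressed &= (lin > min_expression).all(axis=1)
    if not expressed.any():
        detect = sum((lin > min_expression).mean(axis=1) for lin in linears) / len(linears)
        best = detect.idxmax()
        raise DomainError(
            f"no gene exceeds {min_expression} in every sample of every dataset; "
            f"tightest candidate is {best!r} (detected in {detect.max():.0%} of samples)"
        )
    candidates = shared[expressed]
    worst_cv = pd.Series(0.0, index=candidates)
    for lin in linears:
        sub = lin.loc[candidates]
        cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        worst_cv = np.maximum(worst_cv, cv.fillna(0.0))
    best_cv = worst_cv.min()
    ties = sorted(worst_cv.index[worst_cv == best_cv])
    return ties[0]


def hk_fold_change(expr: ExpressionMatrix, hk_gene: str) -> pd.DataFrame:
    """Linear-scale expression of every gene divided by the housekeeping gene,
    per sample.  The housekeeping row is identically 1."""
    if hk_gene not in expr.gene_ids:
        raise DomainError(f"housekeeping gene {hk_gene!r} absent from matrix")
    lin = _linear_values(expr)
    hk = lin.loc[hk_gene]
    zero = hk.index[hk <= 0]
    if len(zero):
        raise DomainError(
            f"housekeeping gene {hk_gene!r} has zero expression in sample {zero[0]!r}"
        )
    return lin / hk


def platform_concordance(
    fc_a: pd.DataFrame,
    fc_b: pd.DataFrame,
    gene_subset: list[str] | None = None,
) -> tuple[float, int]:
    """Spearman rho of per-gene mean fold changes between two platforms.

    Per platform, the gene summary is the geometric mean fold change across
    that platform's samples; only genes with strictly positive fold change in
    every sample of both platforms (detected genes) enter the correlation.
    Returns (rho, number of shared genes used).
    """
    shared = fc_a.index.intersection(fc_b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    a = fc_a.loc[shared]
    b = fc_b.loc[shared]
    detected = (a > 0).all(axis=1) & (b > 0).all(axis=1)
    a = a[detected]
    b = b[detected]
    if a.shape[0] < 3:
        raise DomainError(f"only {a.shape[0]} shared detected genes; need >= 3")
    mean_a = np.log2(a).mean(axis=1)
    mean_b = np.log2(b).mean(axis=1)
    rho = spearman_rho(mean_a.to_numpy(), mean_b.to_numpy()).coefficient
    return float(rho), int(a.shape[0])


def top_marker_overlap(markers_a: list[str], markers_b: list[str], k: int = 50) -> int:
    """|top-k of list A  intersect  full set of B| (asymmetric convention:
    only the first list is truncated)."""
    if k <= 0:
        raise DomainError("k must be positive")
    return len(set(markers_a[:k]) & set(markers_b))


def parenchymal_gene_set(
    whole_signatures: dict[str, list[str]], endothelial_reference: list[str]
) -> dict[str, list[str]]:
    """Per tissue, whole-tissue-specific upregulated genes minus the
    pan-endothelial reference list."""
    ref = set(endothelial_reference)
    return {t: [g for g in genes if g not in ref] for t, genes in whole_signatures.items()}
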