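"""Organ-specific signature derivation.

One-vs-rest moderated differential expression on the endothelial compartment
defines each organ's signature; top markers and surface markers are ranked by
log2 fold change, functional-panel tables intersect signatures with curated
gene sets, and single-cell marker tables use a tie-corrected Wilcoxon
rank-sum test per organ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import DifferentialTable, ExpressionMatrix, SignatureResult
from .errors import DomainError, ModelError
from .preprocess import log_cpm
from .stats import bh_adjust, fit_moderated

__all__ = [
    "voom_weights",
    "one_vs_rest_de",
    "top_markers",
    "surface_marker_ranking",
    "functional_panels",
    "sc_markers_ranksum",
    "tissue_signatures",
    "group_design",
]


def group_design(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Cell-means design (one indicator column per group level)."""
    levels = sorted(pd.Series(labels).astype(str).unique())
    X = np.column_stack([(labels.astype(str) == lv).to_numpy(dtype=float) for lv in levels])
    return X, levels


def voom_weights(counts: ExpressionMatrix, design: np.ndarray) -> pd.DataFrame:
    """Precision weights from the empirical mean-variance trend of log-counts.

    Fits each gene's log2-CPM linear model, smooths sqrt(residual sd) against
    average log2 count by lowess, predicts a standard deviation for every
    observation from its fitted log-count, and returns the inverse predicted
    variances — the standard route for feeding count data into a normal-theory
    moderated-t analysis.
    """
    if counts.scale != "counts":
        raise DomainError("voom_weights expects raw counts")
    X = np.asarray(design, dtype=float)
    n = counts.n_samples
    p = X.shape[1]
    if n < p + 1:
        raise ModelError(f"need more samples ({n}) than design columns + 1 ({p + 1})")
    lib = counts.library_sizes().to_numpy().astype(float)
    y = log_cpm(counts).values.to_numpy()                   # genes x samples
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                                       # genes x p
    fitted = beta @ X.T
    df = n - p
    sigma = np.sqrt(((y - fitted) ** 2).sum(axis=1) / df)   # residual sd per gene
    # mean log2 count per gene (shift log-CPM back to the count scale)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    trend = lowess(sy, sx, frac=0.5, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    # per-observation fitted log2 counts
    fitted_counts = fitted + (np.log2(lib + 1.0)[None, :] - np.log2(1e6))
    pred_sqrt_sd = np.interp(fitted_counts, tx, ty)
    w = 1.0 / np.maximum(pred_sqrt_sd, 1e-6) ** 4
    return pd.DataFrame(w, index=counts.gene_ids, columns=counts.sample_ids)


def _one_vs_rest_contrast(levels: list[str], target: str) -> np.ndarray:
    if target not in levels:
        raise DomainError(f"target tissue {target!r} not among labels {levels}")
    rest = [lv for lv in levels if lv != target]
    c = np.zeros(len(levels))
    c[levels.index(target)] = 1.0
    for lv in rest:
        c[levels.index(lv)] = -1.0 / len(rest)
    return c


def one_vs_rest_de(
    expr: ExpressionMatrix,
    weights: pd.DataFrame,
    tissue_labels: pd.Series,
    target_tissue: str,
) -> DifferentialTable:
    """Moderated-t contrast of one tissue's mean against the average of the
    other tissues' means (equal tissue weighting), BH-adjusted."""
    if expr.scale != "log2":
        raise DomainError("one_vs_rest_de expects log2 expression")
    labels = pd.Series(tissue_labels).astype(str)
    counts_per_group = labels.value_counts()
    small = sorted(counts_per_group.index[counts_per_group < 2])
    if small:
        raise ModelError(f"groups with fewer than 2 samples: {small}")
    X, levels = group_design(labels)
    c = _one_vs_rest_contrast(levels, str(target_tissue))
    w = weights.loc[expr.gene_ids, expr.sample_ids].to_numpy()
    fit = fit_moderated(expr.values.to_numpy(), w, X, c)
    q = bh_adjust(fit.p)
    table = pd.DataFrame(
        {
            "logFC": fit.coef,
            "t": fit.t,
            "p": fit.p,
            "q": q,
            "mean_expr": expr.values.to_numpy().mean(axis=1),
        },
        index=expr.gene_ids,
    )
    return DifferentialTable(table=table, contrast=f"{target_tissue}_vs_rest")


def top_markers(table: DifferentialTable, fdr_max: float = 0.05, k: int = 10) -> list[str]:
    """Significantly upregulated genes ranked by logFC, truncated to k.

    Ties in logFC break by smaller q, then lexicographic gene id.
    """
    sig = table.significant_up(fdr_max=fdr_max)
    # stable lexicographic tie-break: pre-sort by gene id
    ordered = sig.loc[sorted(sig.index)].sort_values(
        by=["logFC", "q"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered.index[:k])


def surface_marker_ranking(
    signature: SignatureResult, surface_catalog: list[str], k: int = 10
) -> list[str]:
    """Upregulated genes intersected with the surface-protein catalogue,
    ranked by logFC."""
    if not surface_catalog:
        raise DomainError("surface catalog is empty")
    catalog = set(surface_catalog)
    tab = signature.table.table
    members = [g for g in signature.up_genes if g in catalog]
    sub = tab.loc[sorted(members)]
    ordered = sub.sort_values(by=["logFC", "q"], ascending=[False, True], kind="mergesort")
    return list(ordered.index[:k])


def functional_panels(
    signatures: dict[str, SignatureResult], panels: "GeneSetCollection"
) -> tuple[pd.DataFrame, dict[str, dict[str, list[str]]]]:
    """Intersect each tissue signature with each functional panel.

    Returns a (tissue, panel) count table and the underlying gene lists.
    """
    if len(panels) == 0:
        raise DomainError("no panels supplied")
    rows = []
    tables: dict[str, dict[str, list[str]]] = {}
    for tissue, sig in signatures.items():
        up = set(sig.up_genes)
        tables[tissue] = {}
        for name in panels.names():
            members = [g for g in panels.members(name) if g in up]
            tables[tissue][name] = members
            rows.append({"tissue": tissue, "panel": name, "count": len(members)})
    return pd.DataFrame(rows), tables


def sc_markers_ranksum(
    sc_expr: ExpressionMatrix, tissue_labels: pd.Series | None = None
) -> dict[str, DifferentialTable]:
    """One-vs-rest Wilcoxon rank-sum marker tables per tissue.

    p-values use the normal approximation with tie correction; fold changes
    are ratios of per-group linear means recovered from the log values
    (expm1-style); q is BH within each contrast.  Constant genes are
    degenerate and get p = 1.
    """
    if sc_expr.scale != "log2":
        raise DomainError("sc_markers_ranksum expects log2 expression")
    labels = (
        pd.Series(tissue_labels).astype(str)
        if tissue_labels is not None
        else sc_expr.samples["tissue"].astype(str)
    )
    out: dict[str, DifferentialTable] = {}
    Y = sc_expr.values.to_numpy()
    linear = np.maximum(2.0**Y - 1.0, 0.0)
    eps = 1e-9
    for tissue in sorted(labels.unique()):
        in_grp = (labels == tissue).to_numpy()
        if in_grp.sum() < 2 or (~in_grp).sum() < 2:
            raise ModelError(f"group {tissue!r} or its complement has fewer than 2 cells")
        x = Y[:, in_grp]
        y = Y[:, ~in_grp]
        constant = (Y == Y[:, [0]]).all(axis=1)
        p = np.ones(Y.shape[0])
        if (~constant).any():
            res = sps.mannwhitneyu(
                x[~constant], y[~constant], axis=1, alternative="two-sided", method="asymptotic"
            )
            p[~constant] = res.pvalue
        lfc = np.log2((linear[:, in_grp].mean(axis=1) + eps) / (linear[:, ~in_grp].mean(axis=1) + eps))
        table = pd.DataFrame(
            {
                "logFC": lfc,
                "t": np.zeros(Y.shape[0]),
                "p": p,
                "q": bh_adjust(p),
                "mean_expr": Y.mean(axis=1),
            },
            index=sc_expr.gene_ids,
        )
        out[tissue] = DifferentialTable(table=table, contrast=f"{tissue}_vs_rest_ranksum")
    return out


def tissue_signatures(
    counts: ExpressionMatrix,
    expr: ExpressionMatrix | None = None,
    fdr_max: float = 0.05,
    k: int = 10,
    surface_catalog: list[str] | None = None,
    min_cpm: float = 1.0,
) -> dict[str, SignatureResult]:
    """Derive all one-vs-rest signatures for the tissues present in ``counts``.

    Unexpressed genes are filtered first (``min_cpm`` in at least the
    smallest group's worth of samples); ``counts`` then supplies voom
    weights, and ``expr`` (defaults to log-CPM of ``counts``) supplies the
    modelled log2 values — pass a batch-adjusted matrix when batches are
    present.
    """
    from .preprocess import filter_expressed_genes

    labels = counts.samples["tissue"]
    min_group = int(labels.value_counts().min())
    counts = filter_expressed_genes(counts, min_cpm=min_cpm, min_samples=min_group)
    X, _ = group_design(labels)
    weights = voom_weights(counts, X)
    if expr is None:
        expr = log_cpm(counts)
    else:
        expr = expr.subset_genes(counts.gene_ids)
    results: dict[str, SignatureResult] = {}
    for tissue in sorted(labels.astype(str).unique()):
        table = one_vs_rest_de(expr, weights, labels, tissue)
        up = list(table.significant_up(fdr_max=fdr_max).index)
        sig = SignatureResult(
            tissue=tissue,
            table=table,
            up_genes=up,
            top_markers=top_markers(table, fdr_max=fdr_max, k=k),
        )
        if surface_catalog:
            sig.surface_markers = surface_marker_ranking(sig, surface_catalog, k=k)
        results[tissue] = sig
    return results
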