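"""Normalisation, batch adjustment, PCA, clustering and single-cell filters.

``batch_adjust`` re-implements the parametric empirical-Bayes location/scale
batch-correction model (additive batch effects with a normal prior,
multiplicative effects with an inverse-gamma prior, covariate-associated
structure preserved) that is standard for harmonising expression cohorts
sequenced in batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix
from .errors import DegenerateInputError, DomainError, ModelError

__all__ = [
    "log_cpm",
    "batch_adjust",
    "pca",
    "PCAResult",
    "hierarchical_cluster",
    "ClusterResult",
    "filter_sc_genes",
    "select_ec_cells",
    "log_normalize_cells",
]


def log_cpm(counts: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2((c + pc) / (lib + 2 pc) * 1e6)``."""
    if counts.scale != "counts":
        raise DomainError("log_cpm expects a counts-scale matrix")
    lib = counts.library_sizes()
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise DegenerateInputError(f"zero library size for samples {bad}")
    if pseudocount < 0:
        raise DomainError("pseudocount must be nonnegative")
    if pseudocount == 0 and (counts.values.to_numpy() == 0).any():
        raise DomainError("pseudocount 0 with zero counts would produce -inf log-CPM")
    vals = np.log2(
        (counts.values + pseudocount)
        / (lib + 2.0 * pseudocount)
        * 1e6
    )
    return ExpressionMatrix(values=vals, samples=counts.samples.copy(), scale="log2")


def _dummy_design(samples: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Drop-first dummy coding of the given metadata columns (no intercept)."""
    if not covariates:
        return np.empty((len(samples), 0))
    frames = []
    for col in covariates:
        d = pd.get_dummies(samples[col].astype(str), prefix=col, drop_first=True)
        frames.append(d.to_numpy(dtype=float))
    return np.column_stack(frames) if frames else np.empty((len(samples), 0))


def batch_adjust(
    expr: ExpressionMatrix,
    batch_column: str = "batch",
    covariates: Sequence[str] = ("tissue", "compartment", "timepoint_h"),
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """Empirical-Bayes batch adjustment of a log2 expression matrix.

    Per gene, a location/scale model is fit with batch indicators and the
    given covariates; batch effects are shrunk across genes (parametric
    priors) and removed, covariate effects are retained.  A single batch is
    an exact identity.
    """
    if expr.scale != "log2":
        raise DomainError("batch_adjust expects log2-scale expression")
    batches = expr.samples[batch_column].astype(str)
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return replace(expr, values=expr.values.copy())
    counts = batches.value_counts()
    singletons = sorted(counts.index[counts < 2])
    if singletons:
        raise ModelError(
            f"batches {singletons} have a single sample; merge them with another "
            "batch or drop those samples before adjustment"
        )
    covariates = [c for c in covariates if c in expr.samples.columns
                  and expr.samples[c].astype(str).nunique() > 1]

    Y = expr.values.to_numpy()                       # genes x samples
    n_genes, n_samples = Y.shape
    B = pd.get_dummies(batches).loc[:, levels].to_numpy(dtype=float)  # samples x batches
    C = _dummy_design(expr.samples, covariates)
    X = np.column_stack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("batch indicators plus covariates are collinear (rank deficient)")

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)   # (n_batch + n_cov) x genes
    n_b = len(levels)
    batch_sizes = B.sum(axis=0)
    grand_mean = (batch_sizes / n_samples) @ beta[:n_b]              # per gene
    var_pooled = ((Y.T - X @ beta) ** 2).mean(axis=0)                # per gene
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[None, :] + C @ beta[n_b:]                # samples x genes
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)[None, :]            # samples x genes

    adjusted = Z.copy()
    for i, level in enumerate(levels):
        idx = np.where(B[:, i] == 1)[0]
        nb = len(idx)
        Zb = Z[idx]                                                   # nb x genes
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        # parametric priors across genes
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        if d_var <= 0:
            a_prior, b_prior = 2.0, d_mean
        else:
            a_prior = (2.0 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (nb * tau2 + delta_star)
            sse = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sse + b_prior) / (nb / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0.0),
                np.abs(d_new - delta_star).max(initial=0.0),
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[idx] = (Zb - gamma_star[None, :]) / np.sqrt(np.maximum(delta_star, 1e-12))[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    values = pd.DataFrame(out.T, index=expr.gene_ids, columns=expr.sample_ids)
    return replace(expr, values=values)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # genes x components (orthonormal columns)
    variance_fractions: np.ndarray


def pca(expr: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """Principal components of samples (genes centred, full SVD)."""
    if n_components < 1 or n_components > min(expr.n_genes, expr.n_samples):
        raise DomainError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(expr.n_genes, expr.n_samples)}"
        )
    X = expr.values.to_numpy().T                       # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    frac = (s**2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * s[:n_components], index=expr.sample_ids, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=expr.gene_ids, columns=comp)
    return PCAResult(scores=scores, loadings=loadings, variance_fractions=frac[:n_components])


@dataclass
class ClusterResult:
    linkage: np.ndarray
    sample_ids: list[str]

    def cut(self, k: int) -> pd.Series:
        """Partition samples into k clusters."""
        if len(self.sample_ids) == 1:
            return pd.Series([1], index=self.sample_ids)
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def leaf_order(self) -> list[str]:
        if len(self.sample_ids) == 1:
            return list(self.sample_ids)
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]


def hierarchical_cluster(
    expr: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of samples on a gene panel."""
    if gene_subset is not None:
        present = expr.gene_ids.intersection(pd.Index(gene_subset))
        if present.empty:
            missing = sorted(set(gene_subset))[:10]
            raise DomainError(f"no panel genes present in matrix; missing include {missing}")
        mat = expr.values.loc[present]
    else:
        mat = expr.values
    samples = list(expr.sample_ids)
    if len(samples) == 1:
        return ClusterResult(linkage=np.empty((0, 4)), sample_ids=samples)
    dist = pdist(mat.to_numpy().T, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    return ClusterResult(linkage=Z, sample_ids=samples)


def filter_expressed_genes(
    counts: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> ExpressionMatrix:
    """Keep genes reaching ``min_cpm`` in at least ``min_samples`` samples
    (default: half the samples, at least 2).

    Unexpressed genes carry no information and their near-zero residual
    variances distort the mean-variance trend and the variance prior, so
    differential testing runs on the expressed set.
    """
    if counts.scale != "counts":
        raise DomainError("filter_expressed_genes expects raw counts")
    if min_samples is None:
        min_samples = max(2, counts.n_samples // 2)
    lib = counts.library_sizes()
    cpm = counts.values / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return replace(counts, values=counts.values.loc[keep])


def filter_sc_genes(sc: ExpressionMatrix, min_cell_fraction: float = 0.10) -> ExpressionMatrix:
    """Discard genes not detected (count > 0) in at least ``min_cell_fraction``
    of all cells."""
    if sc.n_samples < 1:
        raise DomainError("matrix has no cells")
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise DomainError("min_cell_fraction must lie in [0, 1]")
    detected = (sc.values > 0).sum(axis=1) / sc.n_samples
    keep = detected >= min_cell_fraction
    if not keep.any():
        warnings.warn("no genes pass the detection filter; returning an empty matrix")
    return replace(sc, values=sc.values.loc[keep])


def select_ec_cells(sc: ExpressionMatrix, marker_genes: Sequence[str]) -> ExpressionMatrix:
    """Keep cells with nonzero counts for every listed endothelial marker
    (double-positive rule)."""
    if len(marker_genes) == 0:
        warnings.warn("empty marker list: keeping all cells")
        return replace(sc, values=sc.values.copy(), samples=sc.samples.copy())
    for g in marker_genes:
        if g not in sc.gene_ids:
            raise DomainError(f"marker gene {g!r} absent from matrix")
    mask = (sc.values.loc[list(marker_genes)] > 0).all(axis=0)
    keep = sc.sample_ids[mask.to_numpy()]
    return sc.subset_samples(keep)


def log_normalize_cells(sc: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per-cell depth normalisation followed by log2(1 + x) (counts per
    ``scale``, the droplet single-cell convention)."""
    if sc.scale != "counts":
        raise DomainError("log_normalize_cells expects counts")
    lib = sc.library_sizes()
    if (lib <= 0).any():
        raise DegenerateInputError("cells with zero total counts; filter them first")
    vals = np.log2(1.0 + sc.values / lib * scale)
    return ExpressionMatrix(values=vals, samples=sc.samples.copy(), scale="log2")
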