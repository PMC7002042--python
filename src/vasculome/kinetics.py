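"""Inflammatory time-course analysis.

Per-timepoint moderated differential expression against the 0 h baseline,
restricted to an inflammatory-response gene set, and rule-based
classification of per-gene trajectories into stable / transient / sustained
patterns.  Thresholds (default 1.0 log2 for "changed", 0.5 log2 for
"recovered") are recorded in every call.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DifferentialTable, ExpressionMatrix, TrajectoryCall
from .errors import DomainError, ModelError
from .signatures import group_design
from .stats import bh_adjust, fit_moderated

__all__ = [
    "timepoint_de",
    "classify_trajectory",
    "classify_gene_trajectories",
    "timecourse_table",
]

REQUIRED_TIMEPOINTS = (0.0, 6.0, 24.0, 48.0, 72.0, 168.0)


def timepoint_de(
    expr: ExpressionMatrix,
    weights: pd.DataFrame,
    tissue: str,
    timepoint_h: float,
    restrict_set: Sequence[str] | None = None,
    set_name: str = "restricted set",
    compartment: str = "EC",
) -> DifferentialTable:
    """Moderated-t contrast of one timepoint against baseline within a tissue.

    BH adjustment runs within the restricted gene set (the test universe is
    the supplied set, matching an analysis confined to a functional term).
    """
    if expr.scale != "log2":
        raise DomainError("timepoint_de expects log2 expression")
    sub = expr.where_samples(tissue=tissue, compartment=compartment)
    meta = sub.samples
    base_ids = meta.index[meta["timepoint_h"] == 0.0]
    tp_ids = meta.index[meta["timepoint_h"] == float(timepoint_h)]
    if len(base_ids) < 2:
        raise ModelError(f"fewer than 2 baseline samples for tissue {tissue!r}")
    if len(tp_ids) < 2:
        raise ModelError(f"fewer than 2 samples at {timepoint_h} h for tissue {tissue!r}")
    sub = sub.subset_samples(list(base_ids) + list(tp_ids))
    if restrict_set is not None:
        present = sub.gene_ids.intersection(pd.Index(list(restrict_set)))
        if present.empty:
            raise DomainError(f"{set_name} shares no genes with the expression matrix")
        sub = sub.subset_genes(present)
    group = pd.Series(
        ["baseline"] * len(base_ids) + ["treated"] * len(tp_ids), index=sub.sample_ids
    )
    X, levels = group_design(group)
    c = np.array([-1.0 if lv == "baseline" else 1.0 for lv in levels])
    w = weights.loc[sub.gene_ids, sub.sample_ids].to_numpy()
    fit = fit_moderated(sub.values.to_numpy(), w, X, c)
    table = pd.DataFrame(
        {
            "logFC": fit.coef,
            "t": fit.t,
            "p": fit.p,
            "q": bh_adjust(fit.p),
            "mean_expr": sub.values.to_numpy().mean(axis=1),
        },
        index=sub.gene_ids,
    )
    return DifferentialTable(table=table, contrast=f"{tissue}_{timepoint_h}h_vs_0h")


def classify_trajectory(
    series: Mapping[float, float] | pd.Series,
    up_threshold_log2: float = 1.0,
    recovery_tolerance_log2: float = 0.5,
    gene: str = "",
    tissue: str = "",
) -> TrajectoryCall:
    """Classify a per-timepoint mean log2-change series (relative to 0 h).

    stable        max |change| < up_threshold;
    transient_*   peaked but |change at 168 h| < recovery_tolerance;
    sustained_*   peaked and still displaced at 168 h.
    Direction comes from the sign at the peak (largest |change|, earliest on
    ties).  Changes are baseline-relative, so adding a constant to the whole
    series including baseline leaves the call unchanged.
    """
    s = pd.Series(dict(series)).sort_index()
    missing = [t for t in REQUIRED_TIMEPOINTS if t not in s.index]
    if missing:
        raise DomainError(f"series is missing timepoints {missing}")
    post = s.loc[[t for t in s.index if t > 0.0]]
    peak_t = float(post.abs().idxmax())
    peak = float(post.loc[peak_t])
    last = float(s.loc[168.0])
    if abs(peak) < up_threshold_log2:
        return TrajectoryCall(gene, tissue, "stable", peak_t, peak, None)
    direction = "up" if peak > 0 else "down"
    if abs(last) < recovery_tolerance_log2:
        after_peak = post.loc[[t for t in post.index if t > peak_t]]
        rec = next((float(t) for t, v in after_peak.items() if abs(v) < recovery_tolerance_log2), 168.0)
        return TrajectoryCall(gene, tissue, f"transient_{direction}", peak_t, peak, rec)
    return TrajectoryCall(gene, tissue, f"sustained_{direction}", peak_t, peak, None)


def classify_gene_trajectories(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    tissue: str,
    compartment: str = "EC",
    up_threshold_log2: float = 1.0,
    recovery_tolerance_log2: float = 0.5,
) -> list[TrajectoryCall]:
    """Build baseline-relative mean series from the data and classify them."""
    sub = expr.where_samples(tissue=tissue, compartment=compartment).subset_genes(genes)
    tps = sorted(sub.samples["timepoint_h"].unique())
    means = {
        tp: sub.values.loc[:, sub.samples.index[sub.samples["timepoint_h"] == tp]].mean(axis=1)
        for tp in tps
    }
    calls = []
    for g in genes:
        series = {tp: float(means[tp].loc[g] - means[0.0].loc[g]) for tp in tps}
        calls.append(
            classify_trajectory(
                series,
                up_threshold_log2=up_threshold_log2,
                recovery_tolerance_log2=recovery_tolerance_log2,
                gene=g,
                tissue=tissue,
            )
        )
    return calls


def timecourse_table(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    tissue_order: Sequence[str],
    compartment: str = "EC",
) -> pd.DataFrame:
    """Gene x (tissue, timepoint) mean log2 expression in fixed column order."""
    unknown = [g for g in genes if g not in expr.gene_ids]
    if unknown:
        raise DomainError(f"unknown genes: {unknown[:10]}")
    tps = sorted(expr.samples["timepoint_h"].unique())
    cols = pd.MultiIndex.from_product([tissue_order, tps], names=["tissue", "timepoint_h"])
    out = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=cols, dtype=float)
    for t in tissue_order:
        sub = expr.where_samples(tissue=t, compartment=compartment)
        for tp in tps:
            ids = sub.samples.index[sub.samples["timepoint_h"] == tp]
            out[(t, tp)] = sub.values.loc[genes, ids].mean(axis=1)
    return out
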