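"""Preranked gene-set enrichment.

Significantly upregulated genes are ranked by ascending p-value; a running
sum walks the ranking, incrementing by weighted hit mass inside the set and
decrementing by 1/(N - |S|) outside it.  The enrichment score (ES) is the
signed maximum deviation; significance comes from gene-label permutations
that preserve set sizes, with normalised scores (NES) and an FDR computed by
the pooled-NES convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DifferentialTable
from .errors import DegenerateInputError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "rank_for_enrichment",
    "enrichment_score",
    "enrichment_significance",
    "EnrichmentResult",
]


def rank_for_enrichment(
    table: DifferentialTable,
    logfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> pd.Series:
    """Significantly upregulated genes (q < fdr_max, logFC > logfc_min)
    ordered by ascending p-value, scored by -log10(p).

    Equal p-values order by larger logFC first, then by gene id.
    """
    tab = table.table
    sel = tab[(tab["q"] < fdr_max) & (tab["logFC"] > logfc_min)]
    if sel.empty:
        raise DomainError(
            f"no genes pass q < {fdr_max} and logFC > {logfc_min}; relax the thresholds"
        )
    sel = sel.loc[sorted(sel.index)]
    ordered = sel.sort_values(by=["p", "logFC"], ascending=[True, False], kind="mergesort")
    p = np.maximum(ordered["p"].to_numpy(), 1e-300)
    return pd.Series(-np.log10(p), index=ordered.index, name="score")


def _es_from_hits(
    hit_pos: np.ndarray, hit_scores: np.ndarray, n_total: int, weight_exponent: float
) -> tuple[float, int]:
    """ES and the 0-based rank of its extremum from sorted hit positions."""
    s = hit_pos.size
    w = np.abs(hit_scores) ** weight_exponent
    total = w.sum()
    if total == 0:
        w = np.ones(s)
        total = float(s)
    cum = np.cumsum(w) / total
    miss = (hit_pos - np.arange(s)) / (n_total - s)
    after = cum - miss                       # running sum just after each hit
    before = np.concatenate([[0.0], cum[:-1]]) - miss   # just before each hit
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(np.clip(after[i_max], -1.0, 1.0)), int(hit_pos[i_max])
    return float(np.clip(before[i_min], -1.0, 1.0)), int(hit_pos[i_min])


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set over a scored ranking, plus the full running sum.

    The running sum starts and ends at zero; |ES| <= 1.  Empty or full
    intersections are degenerate.
    """
    genes = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    n = len(genes)
    members = set(gene_set)
    hit_mask = np.array([g in members for g in genes])
    s = int(hit_mask.sum())
    if s == 0 or s == n:
        raise DegenerateInputError(
            f"set intersects the ranking in {s} of {n} genes; ES is undefined"
        )
    w = np.where(hit_mask, np.abs(scores) ** weight_exponent, 0.0)
    total = w.sum()
    if total == 0:
        w = hit_mask.astype(float)
        total = float(s)
    # integer miss counts keep the decrement side exact
    miss_counts = np.cumsum(~hit_mask)
    running = np.cumsum(w) / total - miss_counts / (n - s)
    running = np.clip(running, -1.0, 1.0)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    rng: np.random.Generator,
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    weight_exponent: float,
) -> np.ndarray:
    """Vectorised null ES for random position sets of one size."""
    n = scores.size
    # sample positions without replacement per permutation (random-key trick)
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    pos.sort(axis=1)
    w = np.abs(scores[pos]) ** weight_exponent
    tot = w.sum(axis=1, keepdims=True)
    tot = np.where(tot == 0, set_size, tot)
    cum = np.cumsum(w, axis=1) / tot
    miss = (pos - np.arange(set_size)[None, :]) / (n - set_size)
    after = cum - miss
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.clip(np.where(hi >= -lo, hi, lo), -1.0, 1.0)


@dataclass
class EnrichmentResult:
    results: pd.DataFrame             # per set: size, es, nes, p, q
    leading_edge: dict[str, list[str]]

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.results.sort_values(by=["q", "p", "nes"], ascending=[True, True, False]).head(k)


def enrichment_significance(
    ranked: pd.Series,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 2000,
) -> EnrichmentResult:
    """Permutation significance for a collection of gene sets.

    The null preserves set sizes and permutes gene labels over ranking
    positions.  The nominal p compares the observed ES against same-sign null
    scores: p = (1 + #{same-sign null |ES| >= |obs ES|}) / (1 + #{same-sign
    null}), which keeps null p-values uniform; NES = ES / mean(|null ES| of
    the same sign); FDR follows the pooled-NES convention.  Sets outside
    [min_size, max_size] after intersection are skipped with a log entry.
    """
    if n_perm < 100:
        raise DomainError("n_perm must be >= 100")
    genes = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    n = len(genes)
    rng = np.random.default_rng(seed)

    names, sizes, es_obs = [], [], []
    leading: dict[str, list[str]] = {}
    nulls: list[np.ndarray] = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    iterator = gene_sets.items() if hasattr(gene_sets, "items") else gene_sets
    for name, members in iterator:
        hit_pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        s = hit_pos.size
        if s < min_size or s > max_size or s == n:
            logger.info("skipping set %s: size %d outside [%d, %d]", name, s, min_size, max_size)
            continue
        es, peak = _es_from_hits(hit_pos, scores[hit_pos], n, weight_exponent)
        # independent permutations per set: p-values of different sets must
        # not share one finite null sample
        nulls.append(_null_es(rng, scores, s, n_perm, weight_exponent))
        names.append(name)
        sizes.append(s)
        es_obs.append(es)
        if es >= 0:
            leading[name] = [genes[i] for i in hit_pos if i <= peak]
        else:
            leading[name] = [genes[i] for i in hit_pos if i >= peak]

    if not names:
        return EnrichmentResult(
            results=pd.DataFrame(columns=["size", "es", "nes", "p", "q"]), leading_edge={}
        )

    es_obs_arr = np.array(es_obs)
    p = np.empty(len(names))
    nes = np.empty(len(names))
    null_nes_pool = []
    for i, (s, es) in enumerate(zip(sizes, es_obs_arr)):
        null = nulls[i]
        same_sign = null >= 0 if es >= 0 else null < 0
        pool = null[same_sign]
        denom = np.abs(pool).mean() if pool.size else np.nan
        p[i] = (1.0 + np.sum(np.abs(pool) >= abs(es))) / (1.0 + pool.size)
        nes[i] = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        # normalise the null the same way for the pooled-FDR denominator
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
    pooled = np.concatenate(null_nes_pool)

    q = np.empty(len(names))
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            q[i] = np.nan
            continue
        finite = nes[np.isfinite(nes)]
        if v >= 0:
            side_null, side_obs = pooled[pooled >= 0], finite[finite >= 0]
            null_frac = np.mean(side_null >= v) if side_null.size else 0.0
            obs_frac = np.mean(side_obs >= v) if side_obs.size else 0.0
        else:
            side_null, side_obs = pooled[pooled < 0], finite[finite < 0]
            null_frac = np.mean(side_null <= v) if side_null.size else 0.0
            obs_frac = np.mean(side_obs <= v) if side_obs.size else 0.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0

    results = pd.DataFrame(
        {"size": sizes, "es": es_obs_arr, "nes": nes, "p": p, "q": q},
        index=pd.Index(names, name="set"),
    )
    return EnrichmentResult(results=results, leading_edge=leading)
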