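# vasculome

Organ-specific endothelial translatome analysis: tissue-specific gene
signatures, rank-correlation mRNA-purity assessment, bulk/single-cell
concordance, and inflammatory time-course kinetics — with a ground-truth
synthetic-data generator so every stage can be validated end to end.

## The problem

Endothelial cells (ECs) line the vasculature of every organ, yet behave very
differently across vascular beds. Ribosome-tagging strategies (RiboTag)
capture an organ's EC translatome *in situ* — without dissociating the
tissue — by immunoprecipitating tagged ribosomes from whole-tissue lysates.
Three analysis questions follow, and this package implements each:

1. **Signatures.** Which genes define brain, lung, or heart ECs? Each organ
   is contrasted against the rest with a voom-weighted, empirical-Bayes
   moderated t-test: per gene, the residual variance s² is shrunk toward a
   prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), and significance is BH-FDR q < 0.05.
   Top markers and cell-surface markers are ranked by log2 fold change;
   signatures intersect with functional gene panels (endothelial markers,
   metabolism, transporters); upregulated genes feed a preranked gene-set
   enrichment (running-sum ES, gene-label permutations, NES, pooled FDR).
2. **Purity.** Is the enriched mRNA contaminated by whole tissue? If the
   most abundant whole-tissue genes keep their abundance *ranks* inside the
   EC samples, tissue mRNA has leaked in; if the ranks differ, shared genes
   reflect EC-intrinsic programming ("adaptation"). The statistic is
   Kendall's tau-b between each EC and whole-tissue sample over the top-k
   abundant whole-tissue genes, and its response to a known contamination
   fraction f is characterised on synthetic mixtures (1−f)·EC + f·whole.
3. **Concordance and kinetics.** Are bulk signatures reproduced in
   single-cell atlases? Profiles are anchored to an invariable housekeeping
   gene (per-sample fold changes), compared by Spearman's rho over shared
   genes and by top-50 marker overlap. After an inflammatory challenge,
   per-timepoint moderated contrasts against baseline (restricted to an
   inflammatory-response gene set) and a rule-based classifier label each
   gene's trajectory stable / transient / sustained, up or down.

All shared statistics (tau-b, Spearman, BH, the moderated-t machinery, the
enrichment running sum, the empirical-Bayes batch adjustment) are
implemented in this package and validated against independent oracles —
including limma and sva through Rscript — in the test suite.

## Worked example

Simulate the default synthetic study (3 organs × {EC, whole tissue} × 6
timepoints × 3 replicates, 2000 genes with planted roles, 5% contamination,
3 sequencing batches), derive signatures, and assess purity:

```python
import vasculome as v
from vasculome.preprocess import batch_adjust, log_cpm
from vasculome.purity import abundant_gene_selection, purity_matrix
from vasculome.signatures import tissue_signatures

cfg = v.TruthConfig(seed=1)
truth = v.build_truth(cfg)
counts = v.simulate_bulk(truth, cfg)
expr = batch_adjust(log_cpm(counts))

baseline_ec = counts.where_samples(compartment="EC", timepoint_h=0.0)
sigs = tissue_signatures(
    baseline_ec, expr=expr.where_samples(compartment="EC", timepoint_h=0.0)
)
for tissue, sig in sigs.items():
    planted = set(truth.signature_genes(tissue))
    up = set(sig.up_genes)
    print(f"{tissue}: {len(up)} upregulated genes, "
          f"recall of planted signature = {len(up & planted) / len(planted):.2f}, "
          f"top markers: {sig.top_markers[:3]}")

whole = expr.where_samples(compartment="whole", timepoint_h=0.0)
ec = expr.where_samples(compartment="EC", timepoint_h=0.0)
for tissue in cfg.tissues:
    sel = abundant_gene_selection(whole, tissue, k=500)
    rep = purity_matrix(ec.where_samples(tissue=tissue),
                        whole.where_samples(tissue=tissue), sel)
    row = rep.tissue_summary.iloc[0]
    print(f"{tissue}: tau in [{row.min_tau:.2f}, {row.max_tau:.2f}] "
          f"(mean {row.mean_tau:.2f}) at planted contamination f = {cfg.contamination_fraction_f}")
```

Output:

```
brain: 331 upregulated genes, recall of planted signature = 1.00, top markers: ['g0661', 'g0655', 'g0371']
heart: 319 upregulated genes, recall of planted signature = 0.99, top markers: ['g1012', 'g1473', 'g0129']
lung: 334 upregulated genes, recall of planted signature = 1.00, top markers: ['g1389', 'g0271', 'g0743']
brain: tau in [0.04, 0.07] (mean 0.06) at planted contamination f = 0.05
lung: tau in [0.11, 0.12] (mean 0.11) at planted contamination f = 0.05
heart: tau in [0.10, 0.12] (mean 0.11) at planted contamination f = 0.05
```

Each organ's one-vs-rest analysis recovers essentially all 100 planted
signature genes (the extra upregulated genes are the planted surface
markers, organ-preferring pan-endothelial markers, adaptation genes, and the
parenchymal genes that the 5% contamination genuinely carries into the EC
samples). The purity statistic sits near zero — at f = 0 it is slightly
negative and it climbs toward the whole-tissue replicate ceiling as f grows,
which is what makes it a contamination indicator.

The same pipeline runs from the shell:

```bash
vasculome simulate --out run/sim --seed 7
vasculome preprocess --counts run/sim/bulk_counts.tsv --metadata run/sim/bulk_metadata.tsv --out run/prep
vasculome signatures --counts run/sim/bulk_counts.tsv --metadata run/sim/bulk_metadata.tsv \
    --expr run/prep/expr_adjusted.tsv --surface run/sim/surface_catalog.txt \
    --panels run/sim/gene_sets.gmt --out run/sig
vasculome enrich --table run/sig/brain_de.tsv --gmt run/sim/gene_sets.gmt --out run/enr --seed 7
vasculome purity --expr run/prep/expr_adjusted.tsv --metadata run/sim/bulk_metadata.tsv --out run/pur
vasculome concord --bulk-counts run/sim/bulk_counts.tsv --bulk-metadata run/sim/bulk_metadata.tsv \
    --sc-dir run/sim/sc --out run/con
vasculome kinetics --counts run/sim/bulk_counts.tsv --metadata run/sim/bulk_metadata.tsv \
    --gmt run/sim/gene_sets.gmt --out run/kin
vasculome report --dir run
```

Outputs are deterministic: two runs with the same seed are byte-identical.
Real data enter through the same readers (gene × sample count TSVs,
MatrixMarket triplets for single cell, GMT gene sets).

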