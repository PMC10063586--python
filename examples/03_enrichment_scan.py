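"""Regulatory enrichment of GWAS associations, with a planted enriched cell.

Variants are LD-pruned (r2 > 0.01 within 500 kb removed, most significant
kept), significance is dichotomized at T, and a logistic regression with
matched confounder bins (MAF, TSS distance, LD-proxy count) estimates the
annotation log-odds. cell0 carries a planted log-OR of log 2.
"""

import warnings

import numpy as np

from cellrisk import annotation, enrichment, synthio

warnings.filterwarnings("ignore")

genome = synthio.generate_genome(
    synthio.GenomeConfig(n_variants=30_000, block_size=10, n_genes=300), seed=3
)
truth = synthio.make_truth(
    genome, seed=4, n_causal_variants=300, causal_beta=0.045,
    enriched_annotations={"cell0": float(np.log(2))}, plant_threshold=1e-5,
)
stats = synthio.generate_gwas(genome, truth, n_eff=50_000, seed=5)
peaks, _ = synthio.generate_annotations(
    genome, synthio.AnnotationConfig(n_cell_types=4, n_background_peaks=0),
    seed=6, truth=truth, stats=stats,
)

am = annotation.build_annotation_matrix(stats, peaks)
results = enrichment.run_enrichment_scan(
    stats, am, genome.ld, genome.genes, thresholds=(1e-5,)
)
print("cell       OR     95% CI          p         significant")
for r in results:
    lo, hi = np.exp(r.estimate - 1.96 * r.se), np.exp(r.estimate + 1.96 * r.se)
    print(
        f"{r.annotation_id:8s} {r.odds_ratio:5.2f}  [{lo:4.2f}, {hi:4.2f}]  "
        f"{r.p:9.2e}  {r.significant_after_correction}"
    )
# cell0 should show OR near 2 (the planted enrichment); the other cell types
# hover around 1 and fail the multiple-testing-corrected significance flag.
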