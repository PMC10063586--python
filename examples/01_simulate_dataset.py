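"""Generate a synthetic GWAS dataset with planted truth.

Builds an LD-blocked genome with gene models, plants causal variants, and
draws summary statistics whose Z-scores propagate through LD.
"""

import numpy as np

from cellrisk import synthio

genome = synthio.generate_genome(
    synthio.GenomeConfig(n_variants=5000, block_size=10, n_genes=250), seed=7
)
truth = synthio.make_truth(
    genome, seed=8, n_causal_genes=10, causal_beta=0.06, n_causal_variants=10
)
stats = synthio.generate_gwas(genome, truth, n_eff=50_000, seed=9)

n_sig = int((stats.p < 5e-8).sum())
print(f"variants: {genome.n_variants} in {genome.ld.n_blocks} LD blocks")
print(f"genes: {len(genome.genes)} ({sum(g.biotype == 'protein_coding' for g in genome.genes)} protein-coding)")
print(f"planted causal variants: {len(truth.causal_variants)}")
print(f"genome-wide significant variants (p < 5e-8): {n_sig}")
print(f"median p of causal variants: {np.median([stats.table.set_index('variant_id')['p'][v] for v in truth.causal_variants]):.2e}")
# The causal variants (and their LD proxies) dominate the significant tail;
# everything else behaves as uniform null noise.
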