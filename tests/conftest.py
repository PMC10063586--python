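import numpy as np
import pandas as pd
import pytest

from cellrisk import synthio
from cellrisk.models import PeakSet, SummaryStats


@pytest.fixture(scope="session")
def small_genome():
    cfg = synthio.GenomeConfig(n_variants=500, block_size=10, n_genes=50)
    return synthio.generate_genome(cfg, seed=1)


@pytest.fixture(scope="session")
def null_stats(small_genome):
    truth = synthio.make_truth(small_genome, seed=2)
    return synthio.generate_gwas(small_genome, truth, n_eff=50_000, seed=3)


def make_stats(n, seed=0, chrom="chr1", spacing=100):
    """Minimal hand-built summary stats for unit fixtures."""
    rng = np.random.default_rng(seed)
    pos = spacing * np.arange(1, n + 1)
    return SummaryStats(
        pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "chrom": chrom,
                "pos": pos,
                "effect_allele": "A",
                "other_allele": "G",
                "beta": rng.normal(0, 0.1, n),
                "se": 0.1,
                "p": rng.uniform(1e-8, 1, n),
                "maf": rng.uniform(0.01, 0.5, n),
                "info": 1.0,
            }
        )
    )


def make_peaks(intervals, cell_type="cell"):
    return PeakSet(
        cell_type, pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    )
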