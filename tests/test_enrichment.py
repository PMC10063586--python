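"""LD pruning, confounder binning and the enrichment regression, checked
against independent greedy and closed-form 2x2 oracles."""

import numpy as np
import pandas as pd
import pytest

from cellrisk import enrichment as enr
from cellrisk import synthio
from cellrisk.ld import BlockLDMatrix
from cellrisk.models import SummaryStats

from conftest import make_stats


def greedy_prune_oracle(p, pos, r2_full, r2_threshold, window_bp):
    """Independent greedy oracle on a dense r2 matrix (single chromosome)."""
    order = np.lexsort((pos, p))
    kept = []
    for i in order:
        if all(
            not (r2_full[i, j] > r2_threshold and abs(pos[i] - pos[j]) <= window_bp)
            for j in kept
        ):
            kept.append(i)
    return sorted(kept)


# -- prune_variants ---------------------------------------------------------


def test_no_ld_keeps_everything():
    stats = make_stats(30, seed=0)
    ld = BlockLDMatrix.identity(30)
    assert len(enr.prune_variants(stats, ld)) == 30


def test_perfect_proxies_keep_smaller_p():
    stats = make_stats(2, seed=1, spacing=100)
    stats.table.loc[0, "p"] = 0.5
    stats.table.loc[1, "p"] = 0.001
    ld = BlockLDMatrix(np.array([0]), [np.array([[1.0, 1.0], [1.0, 1.0]])])
    kept = enr.prune_variants(stats, ld)
    assert kept.tolist() == [1]


@pytest.mark.parametrize("seed", range(20))
def test_pruning_matches_independent_greedy_oracle(seed):
    g = synthio.generate_genome(
        synthio.GenomeConfig(n_variants=50, block_size=5, n_genes=5,
                             ld_profile="decaying", ld_rho=0.8),
        seed=seed,
    )
    truth = synthio.make_truth(g, seed + 100)
    stats = synthio.generate_gwas(g, truth, 1e4, seed=seed + 200)
    r2_full = g.ld.submatrix_r(np.arange(50)) ** 2
    for r2_t, win_kb in ((0.01, 500), (0.3, 500), (0.5, 0.2)):
        got = enr.prune_variants(stats, g.ld, r2_t, win_kb).tolist()
        exp = greedy_prune_oracle(stats.p, stats.pos, r2_full, r2_t, win_kb * 1000)
        assert got == exp


def test_pruned_set_is_maximal():
    g = synthio.generate_genome(
        synthio.GenomeConfig(n_variants=40, block_size=8, n_genes=4), seed=3
    )
    truth = synthio.make_truth(g, 4)
    stats = synthio.generate_gwas(g, truth, 1e4, seed=5)
    kept = set(enr.prune_variants(stats, g.ld, 0.1, 500).tolist())
    r2 = g.ld.submatrix_r(np.arange(40)) ** 2
    pos = stats.pos
    for i in range(40):
        if i in kept:
            continue
        # every excluded variant conflicts with some kept variant
        assert any(
            r2[i, j] > 0.1 and abs(pos[i] - pos[j]) <= 500_000 for j in kept
        )


# -- bin_confounders --------------------------------------------------------


def test_identical_mafs_collapse_to_one_bin(small_genome):
    stats = make_stats(50, seed=6)
    stats.table["maf"] = 0.25
    with pytest.warns(UserWarning, match="collapse"):
        bins = enr.bin_confounders(stats, small_genome.genes, np.zeros(50), 5)
    assert bins["maf_bin"].nunique() == 1


def test_uniform_values_fill_quantile_bins_evenly(small_genome):
    stats = make_stats(100, seed=7)
    stats.table["maf"] = np.linspace(0.01, 0.5, 100)
    bins = enr.bin_confounders(stats, small_genome.genes, np.arange(100.0), 5)
    assert bins["maf_bin"].value_counts().tolist() == [20] * 5


def test_variant_at_tss_gets_distance_zero_lowest_bin(small_genome):
    tss0 = small_genome.genes[0].isoforms[0].tss
    stats = make_stats(10, seed=8)
    stats.table.loc[0, "pos"] = tss0
    stats.table.loc[0, "chrom"] = small_genome.genes[0].chrom
    stats.table["chrom"] = small_genome.genes[0].chrom
    d = enr.tss_distances(stats, small_genome.genes)
    assert d[0] == 0
    bins = enr.bin_confounders(stats, small_genome.genes, np.zeros(10), 3)
    assert bins.loc[0, "tss_bin"] == 0


def test_tss_distance_is_min_over_isoforms(small_genome):
    gene = next(g for g in small_genome.genes if len(g.isoforms) > 1)
    tss_list = [i.tss for i in gene.isoforms]
    probe = make_stats(1)
    probe.table["chrom"] = gene.chrom
    probe.table["pos"] = max(tss_list) + 1
    d = enr.tss_distances(probe, [gene])
    assert d[0] == min(abs(max(tss_list) + 1 - t) for t in tss_list)


# -- test_enrichment --------------------------------------------------------


def _stats_from_counts(n_sig_annot, n_sig_plain, n_nonsig_annot, n_nonsig_plain):
    n = n_sig_annot + n_sig_plain + n_nonsig_annot + n_nonsig_plain
    p = np.concatenate(
        [
            np.full(n_sig_annot + n_sig_plain, 1e-8),
            np.full(n_nonsig_annot + n_nonsig_plain, 0.5),
        ]
    )
    annot = np.concatenate(
        [
            np.ones(n_sig_annot),
            np.zeros(n_sig_plain),
            np.ones(n_nonsig_annot),
            np.zeros(n_nonsig_plain),
        ]
    )
    stats = make_stats(n, seed=9)
    stats.table["p"] = p
    return stats, annot


def test_enrichment_without_covariates_equals_2x2_odds_ratio():
    stats, annot = _stats_from_counts(30, 70, 10, 90)
    res = enr.test_enrichment(stats, annot, threshold=1e-5)
    expected = (30 * 90) / (70 * 10)
    assert res.odds_ratio == pytest.approx(expected, rel=1e-6)
    # Wald SE of a 2x2 log-OR
    assert res.se == pytest.approx(np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), rel=1e-4)


def test_independent_annotation_gives_or_near_one():
    stats, annot = _stats_from_counts(20, 80, 20, 80)
    res = enr.test_enrichment(stats, annot, threshold=1e-5)
    assert res.estimate == pytest.approx(0.0, abs=1e-8)


def test_no_significant_variants_flagged_untestable():
    stats = make_stats(50, seed=10)
    stats.table["p"] = 0.5
    res = enr.test_enrichment(stats, np.ones(50), threshold=1e-5)
    assert not res.testable and res.estimate is None


def test_or_invariant_to_bin_relabeling():
    rng = np.random.default_rng(11)
    stats = make_stats(400, seed=12)
    stats.table["p"] = rng.uniform(0, 1, 400)
    annot = (rng.random(400) < 0.3).astype(float)
    codes = rng.integers(0, 4, 400)
    bins1 = pd.DataFrame({"b": codes})
    bins2 = pd.DataFrame({"b": (codes + 7) * 3})  # relabeled, same partition
    r1 = enr.test_enrichment(stats, annot, 0.05, bins1)
    r2 = enr.test_enrichment(stats, annot, 0.05, bins2)
    assert r1.estimate == pytest.approx(r2.estimate, rel=1e-9)


# -- effective number / scan ------------------------------------------------


def test_identical_columns_have_effective_number_one():
    col = (np.random.default_rng(13).random(200) < 0.4).astype(float)
    vals = np.column_stack([col] * 7)
    assert enr.effective_n_annotations(vals) == 1


def test_independent_columns_have_effective_number_near_k():
    rng = np.random.default_rng(14)
    vals = (rng.random((5000, 6)) < 0.5).astype(float)
    assert enr.effective_n_annotations(vals) >= 5


def test_single_annotation_single_threshold_correction_is_identity(small_genome):
    truth = synthio.make_truth(small_genome, 15)
    stats = synthio.generate_gwas(small_genome, truth, 5e4, seed=16)
    rng = np.random.default_rng(17)
    from cellrisk.models import AnnotationMatrix

    am = AnnotationMatrix(
        stats.variant_ids, ["a0"], (rng.random((500, 1)) < 0.3).astype(np.int8)
    )
    res = enr.run_enrichment_scan(
        stats, am, small_genome.ld, small_genome.genes, thresholds=(0.05,), n_bins=1
    )
    (r,) = res
    assert r.significant_after_correction == (r.p < 0.05)
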