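"""Gene-SNP annotation routes, Brown's gene statistic and the FDR filter,
against arithmetic, brute-force and closed-form chi-square oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cellrisk import gene_mapping as gm
from cellrisk import synthio
from cellrisk.ld import BlockLDMatrix
from cellrisk.models import Gene, GeneSnpAnnotation, InteractionSet, Isoform

from conftest import make_stats


def _gene(gene_id="G", strand="+", exons=((9_000, 11_000),), chrom="chr1",
          biotype="protein_coding"):
    exons = [tuple(e) for e in exons]
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    iso = Isoform(tss=lo if strand == "+" else hi - 1, exons=exons)
    return Gene(gene_id, chrom, strand, biotype, [iso])


def _stats_at(positions, chrom="chr1"):
    stats = make_stats(len(positions))
    stats.table["pos"] = list(positions)
    stats.table["chrom"] = chrom
    return stats


# -- location annotation ----------------------------------------------------


def test_plus_strand_promoter_window():
    gene = _gene(exons=((10_000, 10_100),))  # TSS 10,000
    # 9,999 inside; 8,000 at 2,000 bp still inside; 7,999 outside; 10,050 exonic
    stats = _stats_at([9_999, 8_000, 7_999, 10_050])
    ann = gm.build_location_annotation(stats, [gene])
    routes = ann.assignments["G"]
    assert routes[stats.variant_ids[0]] == {"promoter"}
    assert routes[stats.variant_ids[1]] == {"promoter"}
    assert stats.variant_ids[2] not in routes
    assert routes[stats.variant_ids[3]] == {"exonic"}


def test_minus_strand_promoter_is_upstream_in_increasing_coordinates():
    gene = _gene(strand="-", exons=((49_000, 50_001),))  # TSS 50,000
    # independent strand-flip arithmetic: upstream = (50_000, 50_000 + 2000]
    stats = _stats_at([50_500, 50_001, 52_000, 52_001, 50_000])
    ann = gm.build_location_annotation(stats, [gene])
    routes = ann.assignments["G"]
    ids = stats.variant_ids
    assert routes[ids[0]] == {"promoter"}
    assert routes[ids[1]] == {"promoter"}
    assert routes[ids[2]] == {"promoter"}  # exactly 2,000 bp upstream
    assert ids[3] not in routes  # 2,001 bp upstream
    assert routes[ids[4]] == {"exonic"}  # the TSS base itself is transcript


def test_exon_and_promoter_variant_counted_once_with_both_routes():
    # two isoforms: the upstream exon of one lies in the other's promoter
    iso_a = Isoform(tss=10_000, exons=[(10_000, 10_100)])
    iso_b = Isoform(tss=8_500, exons=[(8_500, 8_600)])
    gene = Gene("G", "chr1", "+", "protein_coding", [iso_a, iso_b])
    stats = _stats_at([8_550])
    ann = gm.build_location_annotation(stats, [gene])
    assert ann.assignments["G"][stats.variant_ids[0]] == {"exonic", "promoter"}
    assert ann.n_pairs() == 1


def test_gene_without_isoforms_skipped_with_warning():
    gene = Gene("EMPTY", "chr1", "+", "protein_coding", [])
    stats = _stats_at([100])
    with pytest.warns(UserWarning, match="EMPTY"):
        ann = gm.build_location_annotation(stats, [gene])
    assert ann.n_pairs() == 0


# -- interaction annotation -------------------------------------------------


def _loops(rows):
    return InteractionSet(
        "x",
        pd.DataFrame(
            rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        ),
    )


def test_variant_in_partner_anchor_assigned_via_promoter():
    gene = _gene(exons=((10_000, 10_100),))
    loops = _loops([("chr1", 9_000, 9_500, "chr1", 100_000, 101_000)])
    stats = _stats_at([100_500])
    ann = gm.build_interaction_annotation(stats, [gene], loops)
    assert ann.assignments["G"][stats.variant_ids[0]] == {"interaction"}


def test_partner_anchor_without_gene_feature_assigns_nothing():
    gene = _gene(exons=((10_000, 10_100),))
    loops = _loops([("chr1", 500_000, 501_000, "chr1", 100_000, 101_000)])
    stats = _stats_at([100_500])
    ann = gm.build_interaction_annotation(stats, [gene], loops)
    assert ann.n_pairs() == 0


def test_anchor_overlapping_two_genes_assigns_to_both():
    g1 = _gene("G1", exons=((10_000, 10_100),))
    g2 = _gene("G2", exons=((10_050, 10_200),))
    loops = _loops([("chr1", 10_060, 10_070, "chr1", 100_000, 101_000)])
    stats = _stats_at([100_500])
    ann = gm.build_interaction_annotation(stats, [g1, g2], loops)
    assert ann.variants_for("G1") == ann.variants_for("G2") == {stats.variant_ids[0]}


@pytest.mark.parametrize("seed", range(10))
def test_interaction_annotation_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    genes = [
        _gene(f"G{i}", strand=rng.choice(["+", "-"]),
              exons=((int(s), int(s) + int(rng.integers(50, 500))),))
        for i, s in enumerate(rng.integers(0, 50_000, 8))
    ]
    loops = _loops(
        [
            ("chr1", int(a), int(a) + 800, "chr1", int(b), int(b) + 800)
            for a, b in rng.integers(0, 55_000, (12, 2))
        ]
    )
    stats = _stats_at(sorted(rng.choice(60_000, 40, replace=False)))
    got = gm.build_interaction_annotation(stats, genes, loops)

    # brute-force triple loop: loops x genes x variants
    expected: set[tuple[str, str]] = set()
    for rec in loops.loops.itertuples(index=False):
        for ga, va in (((rec.start1, rec.end1), (rec.start2, rec.end2)),
                       ((rec.start2, rec.end2), (rec.start1, rec.end1))):
            for gene in genes:
                feats = list(gene.isoforms[0].exons) + [
                    gm.promoter_window(gene.isoforms[0].tss, gene.strand)
                ]
                if not any(ga[0] < e and s < ga[1] for s, e in feats):
                    continue
                for vid, pos in zip(stats.variant_ids, stats.pos):
                    if va[0] <= pos < va[1]:
                        expected.add((gene.gene_id, vid))
    got_pairs = {
        (g, v) for g in got.genes for v in got.variants_for(g)
    }
    assert got_pairs == expected


# -- merge ------------------------------------------------------------------


def test_merge_disjoint_sizes_add():
    a, b = GeneSnpAnnotation(), GeneSnpAnnotation()
    a.add("G1", "v1", "exonic")
    b.add("G2", "v2", "interaction")
    m = gm.merge_annotations(a, b)
    assert m.n_pairs() == 2


def test_merge_is_idempotent():
    a = GeneSnpAnnotation()
    a.add("G1", "v1", "exonic")
    a.add("G1", "v2", "promoter")
    m = gm.merge_annotations(a, a)
    assert m.assignments == a.assignments


@pytest.mark.parametrize("seed", range(5))
def test_merge_union_size_matches_inclusion_exclusion(seed):
    rng = np.random.default_rng(seed)
    a, b = GeneSnpAnnotation(), GeneSnpAnnotation()
    for ann_obj in (a, b):
        for _ in range(rng.integers(5, 30)):
            ann_obj.add(
                f"G{rng.integers(5)}", f"v{rng.integers(20)}",
                str(rng.choice(["exonic", "promoter", "interaction"])),
            )
    pa = {(g, v) for g in a.genes for v in a.variants_for(g)}
    pb = {(g, v) for g in b.genes for v in b.variants_for(g)}
    m = gm.merge_annotations(a, b)
    pm = {(g, v) for g in m.genes for v in m.variants_for(g)}
    assert len(pm) == len(pa) + len(pb) - len(pa & pb)
    # route tags are unioned on collisions
    for g, v in pa & pb:
        assert m.assignments[g][v] == a.assignments[g][v] | b.assignments[g][v]


# -- gene-level statistic ---------------------------------------------------


def test_single_snp_gene_p_equals_snp_p():
    stats = _stats_at([100])
    stats.table["p"] = [0.0123]
    ann = GeneSnpAnnotation()
    ann.add("G", stats.variant_ids[0], "exonic")
    ld = BlockLDMatrix.identity(1)
    (res,) = gm.gene_level_test(stats, ann, ld, [_gene("G")])
    assert res.p == pytest.approx(0.0123, rel=1e-9)


def test_independent_snps_match_chisquare_closed_form():
    rng = np.random.default_rng(20)
    k = 7
    pvals = rng.uniform(0.001, 0.9, k)
    stats = _stats_at(100 * np.arange(1, k + 1))
    stats.table["p"] = pvals
    ann = GeneSnpAnnotation()
    for v in stats.variant_ids:
        ann.add("G", v, "exonic")
    ld = BlockLDMatrix.identity(k)
    (res,) = gm.gene_level_test(stats, ann, ld, [_gene("G")])
    s = np.sum(sps.norm.isf(pvals / 2) ** 2)
    assert res.statistic == pytest.approx(s, rel=1e-12)
    assert res.p == pytest.approx(sps.chi2.sf(s, k), rel=1e-9)
    assert res.n_snps == k


def test_duplicate_snp_adds_no_information():
    # two perfectly correlated SNPs: eigenvalues (2, 0), so S = 2 z^2 is
    # referred to 2 * chi2(1) and the gene p equals the single-SNP p
    stats = _stats_at([100, 200])
    stats.table["p"] = [0.01, 0.01]
    ann = GeneSnpAnnotation()
    for v in stats.variant_ids:
        ann.add("G", v, "exonic")
    ld = BlockLDMatrix(np.array([0]), [np.array([[1.0, 1.0], [1.0, 1.0]])])
    (res,) = gm.gene_level_test(stats, ann, ld, [_gene("G")])
    # duplicate SNP adds no information: gene p equals the single-SNP p
    assert res.p == pytest.approx(0.01, rel=1e-6)


@pytest.mark.parametrize(
    "lam", [[1.7071, 0.2929], [3.83, 0.29, 0.29, 0.29, 0.29], [5, 1, 0.5, 0.1]]
)
def test_weighted_chisquare_null_matches_monte_carlo(lam):
    from cellrisk._quadform import wchi2_sf

    lam = np.array(lam, dtype=float)
    rng = np.random.default_rng(42)
    q = rng.standard_normal((200_000, lam.size)) ** 2 @ lam
    for quant in (0.5, 0.9, 0.99):
        x = np.quantile(q, quant)
        mc = (q > x).mean()
        assert wchi2_sf(x, lam) == pytest.approx(
            mc, abs=4 * np.sqrt(mc * (1 - mc) / 200_000)
        )


def test_null_gene_pvalues_uniform_with_ld():
    g = synthio.generate_genome(
        synthio.GenomeConfig(
            n_variants=3000, block_size=5, n_genes=600,
            ld_profile="exchangeable", ld_rho=np.sqrt(0.5),
        ),
        seed=21,
    )
    truth = synthio.make_truth(g, 22)
    stats = synthio.generate_gwas(g, truth, 5e4, seed=23)
    ann = gm.build_location_annotation(stats, g.genes)
    res = gm.gene_level_test(stats, ann, g.ld, g.genes)
    pv = np.array([r.p for r in res])
    assert len(pv) > 400
    assert sps.kstest(pv, "uniform").pvalue > 0.01


def test_loop_assigning_causal_variant_lowers_gene_p_in_expectation():
    """Paired simulation: adding an interaction that brings a causal variant
    into a gene reduces that gene's p-value on average."""
    g = synthio.generate_genome(
        synthio.GenomeConfig(n_variants=200, block_size=10, n_genes=10), seed=30
    )
    # causal variant in a gene-free block (genes occupy blocks 0..9)
    causal_idx = 150
    vid = g.variants["variant_id"].iloc[causal_idx]
    truth = synthio.SyntheticTruth(causal_variants={vid: 0.08})
    gene = g.genes[0]
    pos_c = int(g.variants["pos"].iloc[causal_idx])
    tss = gene.isoforms[0].tss
    loops = _loops([("chr1", tss - 100, tss + 100, "chr1", pos_c - 50, pos_c + 50)])
    p_with, p_without = [], []
    for rep in range(20):
        stats = synthio.generate_gwas(g, truth, 5e4, seed=400 + rep)
        loc = gm.build_location_annotation(stats, [gene])
        merged = gm.merge_annotations(
            loc, gm.build_interaction_annotation(stats, [gene], loops)
        )
        (r_with,) = gm.gene_level_test(stats, merged, g.ld, [gene])
        (r_without,) = gm.gene_level_test(stats, loc, g.ld, [gene])
        p_with.append(np.log(r_with.p))
        p_without.append(np.log(r_without.p))
    assert np.mean(p_with) < np.mean(p_without)


# -- FDR / set comparison ---------------------------------------------------


def test_fdr_hand_oracle():
    results = [
        gm.GeneResult("G1", "protein_coding", 1, 0.0, 0.001),
        gm.GeneResult("G2", "protein_coding", 1, 0.0, 0.2),
        gm.GeneResult("G3", "protein_coding", 1, 0.0, 0.3),
    ]
    risk = gm.fdr_filter(results)
    assert [r.q for r in results] == pytest.approx([0.003, 0.3, 0.3])
    assert risk == {"G1"}


def test_all_p_one_gives_empty_risk_set():
    results = [gm.GeneResult(f"G{i}", "protein_coding", 1, 0.0, 1.0) for i in range(5)]
    assert gm.fdr_filter(results) == set()


def test_noncoding_gene_excluded_from_risk_set_but_kept_in_results():
    results = [
        gm.GeneResult("GN", "other", 1, 0.0, 1e-10),
        gm.GeneResult("GP", "protein_coding", 1, 0.0, 0.5),
    ]
    risk = gm.fdr_filter(results)
    assert risk == set()
    assert results[0].q is not None and results[0].q < 0.05


def test_compare_identical_sets_all_shared():
    out = gm.compare_gene_sets({"a": {"G1", "G2"}, "b": {"G1", "G2"}})
    assert out["shared"] == {"G1", "G2"}
    assert all(not u for u in out["unique"].values())


def test_compare_disjoint_sets_all_unique():
    out = gm.compare_gene_sets({"a": {"G1"}, "b": {"G2"}, "c": {"G3"}})
    assert out["shared"] == set()
    assert out["unique"] == {"a": {"G1"}, "b": {"G2"}, "c": {"G3"}}


@pytest.mark.parametrize("seed", range(5))
def test_compare_random_sets_matches_set_algebra(seed):
    rng = np.random.default_rng(seed)
    sets = {
        c: {f"G{i}" for i in rng.integers(0, 40, rng.integers(5, 25))}
        for c in ("a", "b", "c")
    }
    out = gm.compare_gene_sets(sets)
    assert out["shared"] == sets["a"] & sets["b"] & sets["c"]
    assert out["unique"]["a"] == sets["a"] - (sets["b"] | sets["c"])
    assert out["pairwise"].loc["a", "b"] == len(sets["a"] & sets["b"])
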