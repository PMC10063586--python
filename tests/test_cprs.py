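"""Score QC, universes, clumping, PRS arithmetic, evaluation and
stratification, against loop/closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellrisk import cprs, synthio
from cellrisk.ld import BlockLDMatrix
from cellrisk.models import CohortData, GeneSnpAnnotation, ScoreModel

from conftest import make_stats


def _cohort(dosages, status=None, alleles=None, **kw):
    n = len(dosages)
    return CohortData(
        dosages=dosages,
        status=np.zeros(n, dtype=int) if status is None else status,
        phenotypes=pd.DataFrame(index=range(n)),
        covariates=pd.DataFrame(index=range(n)),
        variant_alleles=alleles,
        **kw,
    )


def _alleles(ids, ea="A", oa="G", maf=0.3):
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "maf": maf,
        }
    )


# -- QC ---------------------------------------------------------------------


def test_qc_removes_low_info_and_low_maf():
    stats = make_stats(4, seed=0)
    stats.table["info"] = [0.5, 0.61, 1.0, 1.0]
    stats.table["maf"] = [0.3, 0.3, 0.005, 0.3]
    out, _, report = cprs.qc_filter(stats)
    assert set(out.variant_ids) == {"v1", "v3"}
    assert report["n_info"] == 1 and report["n_maf"] == 1


def test_qc_removes_hwe_and_missingness_failures():
    rng = np.random.default_rng(1)
    n = 2000
    stats = make_stats(3, seed=2)
    # v0: HWE-consistent; v1: all hets (HWE p ~ 0); v2: 20% missing
    d = pd.DataFrame(
        {
            "v0": rng.binomial(2, 0.3, n).astype(float),
            "v1": np.ones(n),
            "v2": rng.binomial(2, 0.3, n).astype(float),
        }
    )
    d.loc[: n * 0.2, "v2"] = np.nan
    cohort = _cohort(d)
    out, _, report = cprs.qc_filter(stats.subset([0, 1, 2]), cohort)
    # hand-check: hwe p for all-het is far below 1e-6
    assert set(out.variant_ids) == {"v0"}
    assert report["n_hwe"] == 1 and report["n_missing"] == 1


def test_qc_drops_one_of_each_related_pair():
    stats = make_stats(2, seed=3)
    d = pd.DataFrame(
        {"v0": [0.0, 1, 2, 0], "v1": [1.0, np.nan, 0, 2]}, index=list("abcd")
    )
    cohort = _cohort(d)
    kin = pd.DataFrame(
        {"id1": ["a", "c"], "id2": ["b", "d"], "kinship": [0.09, 0.02]}
    )
    _, out, report = cprs.qc_filter(stats, cohort, kin)
    # a/b related: b has a missing dosage, so b is dropped; c/d unrelated
    assert list(out.dosages.index) == ["a", "c", "d"]
    assert report["n_individuals_removed"] == 1


# -- universes --------------------------------------------------------------


def _ann(pairs):
    a = GeneSnpAnnotation()
    for g, v in pairs:
        a.add(g, v, "exonic")
    return a


def test_identical_annotations_give_empty_unique_universe():
    anns = {c: _ann([("G1", "v1"), ("G2", "v2")]) for c in ("b", "mono")}
    with pytest.raises(ValueError, match="empty"):
        cprs.restrict_universe(anns, "b", "unique")


def test_disjoint_annotations_unique_equals_all():
    anns = {"b": _ann([("G1", "v1")]), "mono": _ann([("G2", "v2")])}
    assert cprs.restrict_universe(anns, "b", "unique") == {"v1"}
    assert cprs.restrict_universe(anns, "b", "all") == {"v1"}
    assert cprs.restrict_universe(anns, None, "combined") == {"v1", "v2"}


@pytest.mark.parametrize("seed", range(5))
def test_universe_set_algebra_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    anns = {}
    raw = {}
    for c in ("b", "mono", "mg"):
        pairs = [
            (f"G{rng.integers(10)}", f"v{rng.integers(30)}")
            for _ in range(rng.integers(10, 40))
        ]
        anns[c] = _ann(pairs)
        raw[c] = {v for _, v in pairs}
    assert cprs.restrict_universe(anns, "b", "all") == raw["b"]
    expect_unique = raw["b"] - (raw["mono"] | raw["mg"])
    if expect_unique:
        assert cprs.restrict_universe(anns, "b", "unique") == expect_unique
    assert cprs.restrict_universe(anns, None, "combined") == set.union(*raw.values())


# -- clumping ---------------------------------------------------------------


def test_clump_keeps_all_without_ld():
    stats = make_stats(8, seed=4)
    assert len(cprs.clump(stats, BlockLDMatrix.identity(8))) == 8


def test_clump_keeps_smaller_p_of_correlated_pair():
    stats = make_stats(2, seed=5, spacing=100)
    stats.table["p"] = [0.2, 0.01]
    ld = BlockLDMatrix(np.array([0]), [np.array([[1.0, 0.7], [0.7, 1.0]])])
    assert cprs.clump(stats, ld).tolist() == [1]  # r2 = 0.49 > 0.1


def test_clump_matches_greedy_oracle_on_fixture():
    from test_enrichment import greedy_prune_oracle

    g = synthio.generate_genome(
        synthio.GenomeConfig(n_variants=8, block_size=4, n_genes=1), seed=6
    )
    truth = synthio.make_truth(g, 7)
    stats = synthio.generate_gwas(g, truth, 1e4, seed=8)
    r2 = g.ld.submatrix_r(np.arange(8)) ** 2
    got = cprs.clump(stats, g.ld).tolist()
    assert got == greedy_prune_oracle(stats.p, stats.pos, r2, 0.1, 250_000)


# -- PRS --------------------------------------------------------------------


def test_zero_weights_give_zero_scores():
    d = pd.DataFrame({"v0": [0.0, 1], "v1": [2.0, 1]})
    cohort = _cohort(d, alleles=_alleles(["v0", "v1"]))
    model = ScoreModel(np.array(["v0", "v1"]), np.zeros(2), np.array(["A", "A"]), 1.0)
    np.testing.assert_array_equal(cprs.compute_prs(cohort, model), [0.0, 0.0])


def test_prs_direct_arithmetic():
    d = pd.DataFrame({"v0": [2.0], "v1": [1.0]})
    cohort = _cohort(d, alleles=_alleles(["v0", "v1"]))
    model = ScoreModel(
        np.array(["v0", "v1"]), np.array([0.2, -0.1]), np.array(["A", "A"]), 1.0
    )
    assert cprs.compute_prs(cohort, model)[0] == pytest.approx(0.3)


@pytest.mark.parametrize("seed", range(10))
def test_prs_matches_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n, m = 50, 20
    ids = [f"v{i}" for i in range(m)]
    d = pd.DataFrame(rng.integers(0, 3, (n, m)).astype(float), columns=ids)
    w = rng.normal(0, 0.2, m)
    cohort = _cohort(d, alleles=_alleles(ids))
    model = ScoreModel(np.array(ids), w, np.array(["A"] * m), 1.0)
    got = cprs.compute_prs(cohort, model)
    expected = np.zeros(n)
    for j in range(n):
        for i in range(m):
            expected[j] += w[i] * d.iloc[j, i]
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_allele_flip_invariance():
    rng = np.random.default_rng(9)
    ids = ["v0", "v1"]
    d = pd.DataFrame(rng.integers(0, 3, (20, 2)).astype(float), columns=ids)
    cohort = _cohort(d, alleles=_alleles(ids, ea="A", oa="G"))
    w = np.array([0.3, -0.2])
    direct = cprs.compute_prs(
        cohort, ScoreModel(np.array(ids), w, np.array(["A", "A"]), 1.0)
    )
    flipped = cprs.compute_prs(
        cohort, ScoreModel(np.array(ids), -w, np.array(["G", "G"]), 1.0)
    )
    # swapping effect/other allele with sign-flipped weights shifts each
    # variant's contribution by 2w but leaves score differences unchanged
    np.testing.assert_allclose(
        direct - direct.mean(), flipped - flipped.mean(), atol=1e-12
    )


def test_unmatched_allele_raises_listing_variant():
    d = pd.DataFrame({"v0": [1.0]})
    cohort = _cohort(d, alleles=_alleles(["v0"], ea="A", oa="G"))
    model = ScoreModel(np.array(["v0"]), np.array([0.1]), np.array(["T"]), 1.0)
    with pytest.raises(ValueError, match="v0"):
        cprs.compute_prs(cohort, model)


def test_missing_dosage_imputed_to_twice_maf():
    d = pd.DataFrame({"v0": [np.nan, 2.0]})
    cohort = _cohort(d, alleles=_alleles(["v0"], maf=0.25))
    model = ScoreModel(np.array(["v0"]), np.array([1.0]), np.array(["A"]), 1.0)
    got = cprs.compute_prs(cohort, model)
    assert got[0] == pytest.approx(0.5)  # 2 * 0.25


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_prs_linearity_in_weights(seed):
    rng = np.random.default_rng(seed)
    ids = [f"v{i}" for i in range(5)]
    d = pd.DataFrame(rng.integers(0, 3, (8, 5)).astype(float), columns=ids)
    cohort = _cohort(d, alleles=_alleles(ids))
    w1, w2 = rng.normal(size=5), rng.normal(size=5)
    ea = np.array(["A"] * 5)
    s1 = cprs.compute_prs(cohort, ScoreModel(np.array(ids), w1, ea, 1.0))
    s2 = cprs.compute_prs(cohort, ScoreModel(np.array(ids), w2, ea, 1.0))
    s12 = cprs.compute_prs(cohort, ScoreModel(np.array(ids), w1 + w2, ea, 1.0))
    np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)


# -- evaluation -------------------------------------------------------------


def test_null_score_auc_half_and_zero_liability_r2():
    rng = np.random.default_rng(10)
    n = 10_000
    status = rng.integers(0, 2, n)
    score = rng.normal(size=n)
    res = cprs.evaluate(score, status, prevalence=0.01)
    assert abs(res.auc - 0.5) < 0.02
    assert res.r2_liability < 0.005


def test_perfectly_separating_score_has_auc_one():
    status = np.array([0] * 50 + [1] * 50)
    score = np.concatenate([np.zeros(50), np.ones(50)])
    res = cprs.evaluate(score, status, prevalence=0.01)
    assert res.auc == 1.0


def test_one_class_status_rejected():
    with pytest.raises(ValueError, match="cases and controls"):
        cprs.evaluate(np.ones(10), np.zeros(10))


def test_liability_transformation_monotone_and_zero_at_zero():
    assert cprs.liability_r2(0.0, 0.01, 0.5) == 0.0
    vals = [cprs.liability_r2(r, 0.01, 0.5) for r in (0.01, 0.05, 0.1, 0.3)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_optimize_threshold_single_value_trivial(small_genome):
    truth = synthio.make_truth(
        small_genome, 11, n_causal_variants=10, causal_beta=0.8,
        heritability=0.2, prevalence=0.3,
    )
    stats = synthio.generate_gwas(small_genome, truth, 5e4, seed=12)
    coh = synthio.generate_cohort(
        small_genome, truth, 13, sampling="population", n_individuals=500
    )
    model, table = cprs.optimize_threshold(
        stats, small_genome.ld, coh, thresholds=(0.5,), prevalence=0.3
    )
    assert model.p_threshold == 0.5 and len(table) == 1


def test_optimize_threshold_tie_breaks_to_smaller(small_genome):
    truth = synthio.make_truth(
        small_genome, 14, n_causal_variants=5, causal_beta=1.2,
        heritability=0.3, prevalence=0.3,
    )
    stats = synthio.generate_gwas(small_genome, truth, 5e4, seed=15)
    # make every variant pass every threshold: identical models -> exact tie
    stats.table["p"] = 1e-10
    coh = synthio.generate_cohort(
        small_genome, truth, 16, sampling="population", n_individuals=400
    )
    model, _ = cprs.optimize_threshold(
        stats, small_genome.ld, coh, thresholds=(5e-8, 0.05, 1.0), prevalence=0.3
    )
    assert model.p_threshold == 5e-8


# -- stratification ---------------------------------------------------------


def test_stratify_two_strata_matches_2x2_oracle():
    # bottom half: 20 cases / 80 controls; top half (the median falls on the
    # boundary and joins the upper stratum, which becomes the reference):
    # 10 cases / 90 controls
    score = np.concatenate([np.arange(100), 100 + np.arange(100)])
    status = np.zeros(200)
    status[:20] = 1
    status[100:110] = 1
    strata = cprs.stratify_or(score, status, edges=(0.0, 0.5, 1.0))
    by_lo = {s.lo_quantile: s for s in strata}
    assert by_lo[0.5].is_reference
    assert by_lo[0.0].odds_ratio == pytest.approx((20 * 90) / (80 * 10), rel=1e-4)


def test_null_score_strata_or_near_one():
    rng = np.random.default_rng(18)
    n = 100_000
    score = rng.normal(size=n)
    status = rng.integers(0, 2, n)
    strata = cprs.stratify_or(score, status)
    for s in strata:
        if not s.is_reference:
            assert abs(np.log(s.odds_ratio)) < 3 * s.se_log_or


def test_reference_stratum_contains_median():
    rng = np.random.default_rng(19)
    score = rng.normal(size=5000)
    status = rng.integers(0, 2, 5000)
    strata = cprs.stratify_or(score, status)
    ref = next(s for s in strata if s.is_reference)
    assert ref.lo_quantile <= 0.5 <= ref.hi_quantile


# -- MHC --------------------------------------------------------------------


@pytest.mark.parametrize(
    "chrom,pos,kept",
    [
        ("chr6", 30_000_000, False),
        ("chr6", 10_000_000, True),
        ("chr7", 30_000_000, True),
        ("chr6", 25_000_000, False),  # start inclusive
        ("chr6", 35_000_000, True),  # end exclusive (half-open)
        ("chr6", 34_999_999, False),
    ],
)
def test_mhc_filter_respects_bounds(chrom, pos, kept):
    stats = make_stats(1)
    stats.table["chrom"] = chrom
    stats.table["pos"] = pos
    out = cprs.exclude_mhc(stats)
    assert (len(out) == 1) == kept
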