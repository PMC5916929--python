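"""LD clump construction, EB-shrunken overlap fractions and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cagekit.clustering import TagCluster
from cagekit.gwas import (
    BetaBinomialShrinkage,
    build_ld_clumps,
    clump_enrichment_test,
    clump_overlap_fractions,
    eb_shrink_fractions,
    enhancer_regions,
    promoter_regions,
    regions_overlapping_clumps,
)
from cagekit.io import GenomicInterval

from conftest import make_cluster


def _snps(rows):
    return pd.DataFrame(rows, columns=["trait", "chrom", "pos", "rsid"])


def _ld(rows):
    return pd.DataFrame(
        rows, columns=["chrom_a", "pos_a", "snp_a", "chrom_b", "pos_b", "snp_b", "r2"]
    )


def test_snp_without_partners_is_1bp_clump():
    snps = _snps([("t", "chr1", 500, "rs1")])
    with pytest.warns(UserWarning, match="absent"):
        clumps = build_ld_clumps(snps, _ld([]))
    (c,) = clumps["t"]
    assert (c.start, c.end) == (500, 500)


def test_overlapping_blocks_merge():
    snps = _snps([("t", "chr1", 1000, "rs1"), ("t", "chr1", 1800, "rs2")])
    ld = _ld([
        ("chr1", 1000, "rs1", "chr1", 1500, "rsA", 0.9),
        ("chr1", 1800, "rs2", "chr1", 1400, "rsB", 0.8),
    ])
    (c,) = build_ld_clumps(snps, ld)["t"]
    assert (c.start, c.end) == (1000, 1800)
    assert sorted(c.gwas_snps) == ["rs1", "rs2"]


def test_r2_boundary_is_strict():
    snps = _snps([("t", "chr1", 1000, "rs1")])
    ld = _ld([("chr1", 1000, "rs1", "chr1", 1500, "rsA", 0.75)])
    (c,) = build_ld_clumps(snps, ld)["t"]
    assert (c.start, c.end) == (1000, 1000)  # R2 = 0.75 exactly: no partner


def test_window_limits_partners():
    snps = _snps([("t", "chr1", 1000, "rs1")])
    ld = _ld([("chr1", 1000, "rs1", "chr1", 600_000, "rsA", 0.99)])
    (c,) = build_ld_clumps(snps, ld, window=500_000)["t"]
    assert (c.start, c.end) == (1000, 1000)


def brute_force_clumps(snp_positions, partner_spans):
    """Interval union oracle: expand each SNP, merge by pairwise overlap."""
    spans = [
        (min([p] + partner_spans.get(p, [])), max([p] + partner_spans.get(p, [])))
        for p in snp_positions
    ]
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def test_clumps_match_bruteforce_on_random_panels(rng):
    for trial in range(100):
        positions = sorted(rng.choice(100_000, size=50, replace=False) + 1)
        snp_rows, ld_rows, partner_spans = [], [], {}
        for i, p in enumerate(positions):
            rsid = f"rs{trial}_{i}"
            snp_rows.append(("t", "chr1", int(p), rsid))
            for _ in range(int(rng.integers(0, 4))):
                q = int(np.clip(p + rng.integers(-3000, 3001), 1, None))
                r2 = float(rng.uniform(0.5, 1.0))
                ld_rows.append(("chr1", int(p), rsid, "chr1", q, f"px{trial}_{i}_{q}", r2))
                if r2 > 0.75:
                    partner_spans.setdefault(int(p), []).append(q)
        clumps = build_ld_clumps(_snps(snp_rows), _ld(ld_rows))["t"]
        ours = [(c.start, c.end) for c in clumps]
        assert ours == brute_force_clumps(positions, partner_spans)


def test_clump_construction_order_invariant(rng):
    rows = [("t", "chr1", int(p), f"rs{i}")
            for i, p in enumerate(rng.choice(50_000, size=30, replace=False) + 1)]
    ld = _ld([("chr1", r[2], r[3], "chr1", r[2] + 400, f"px{i}", 0.9)
              for i, r in enumerate(rows)])
    a = build_ld_clumps(_snps(rows), ld)["t"]
    b = build_ld_clumps(_snps(rows[::-1]), ld)["t"]
    assert [(c.start, c.end) for c in a] == [(c.start, c.end) for c in b]


# -- regions and overlap ----------------------------------------------------


def test_promoter_region_strand_arithmetic():
    minus_tc = make_cluster([1.0], start=10_000, strand="-")
    (r,) = promoter_regions([minus_tc])
    assert (r.start + 1, r.end) == (9_900, 10_500)  # 1-based inclusive
    plus_tc = make_cluster([1.0], start=10_000, strand="+")
    (r,) = promoter_regions([plus_tc])
    assert (r.start + 1, r.end) == (9_500, 10_100)


def test_one_bp_touch_counts_as_overlap():
    snps = _snps([("t", "chr1", 1000, "rs1")])
    with pytest.warns(UserWarning):
        clumps = build_ld_clumps(snps, _ld([]))
    region = [GenomicInterval("chr1", 999, 1500)]  # starts exactly at 1000
    fr = clump_overlap_fractions(clumps, region)
    assert fr.loc["t", "x"] == 1
    region_miss = [GenomicInterval("chr1", 1000, 1500)]  # starts at 1001
    fr2 = clump_overlap_fractions(clumps, region_miss)
    assert fr2.loc["t", "x"] == 0


def test_zero_clumps_rejected():
    with pytest.raises(ValueError, match="zero clumps"):
        clump_overlap_fractions({"t": []}, [])


# -- shrinkage --------------------------------------------------------------


def test_shrunken_between_raw_and_prior_mean(rng):
    n = rng.integers(20, 200, size=12)
    p_true = rng.beta(2, 8, size=12)
    x = rng.binomial(n, p_true)
    res = eb_shrink_fractions(pd.DataFrame({"x": x, "n": n}))
    prior_mean = res.prior_mean
    for _, row in res.table.iterrows():
        lo, hi = sorted([row["raw"], prior_mean])
        assert lo - 1e-12 <= row["shrunken"] <= hi + 1e-12


def test_shrinkage_formula_with_pinned_prior():
    # with alpha = beta = 2: (5 + 2) / (10 + 4) = 0.5
    assert (5 + 2) / (10 + 2 + 2) == pytest.approx(0.5)
    res = eb_shrink_fractions(pd.DataFrame({"x": [5, 3, 7], "n": [10, 12, 11]}))
    a, b = res.alpha, res.beta
    expected = (res.table["x"] + a) / (res.table["n"] + a + b)
    assert np.allclose(res.table["shrunken"], expected)


def test_large_n_shrinks_to_raw():
    res = eb_shrink_fractions(
        pd.DataFrame({"x": [5000, 30, 70, 55], "n": [10_000, 100, 200, 150]})
    )
    assert res.table.loc[0, "shrunken"] == pytest.approx(0.5, abs=0.01)


def test_degenerate_fractions_return_raw():
    with pytest.warns(UserWarning, match="degenerate"):
        res = eb_shrink_fractions(pd.DataFrame({"x": [5, 10, 15], "n": [10, 20, 30]}))
    assert np.allclose(res.table["shrunken"], 0.5)


def test_minimum_traits_enforced():
    with pytest.raises(ValueError, match="at least 3"):
        BetaBinomialShrinkage(pd.DataFrame({"x": [1], "n": [10]}))


# -- enrichment -------------------------------------------------------------


def test_de_equal_to_universe_gives_p_1():
    universe = {f"r{i}" for i in range(20)}
    table = clump_enrichment_test(universe, universe, {"t": {"r0", "r1"}})
    assert table.loc["t", "p"] == pytest.approx(1.0)


def test_empty_de_set_gives_p_1():
    universe = {f"r{i}" for i in range(20)}
    table = clump_enrichment_test(set(), universe, {"t": {"r0"}})
    assert table.loc["t", "p"] == 1.0


def hypergeom_bruteforce(k, big_n, big_k, n_de):
    """Upper-tail P(X >= k) by direct pmf summation."""
    return sum(
        stats.hypergeom.pmf(i, big_n, big_k, n_de)
        for i in range(k, min(big_k, n_de) + 1)
    )


def test_enrichment_matches_bruteforce(rng):
    universe = {f"r{i}" for i in range(40)}
    for _ in range(20):
        de = set(rng.choice(sorted(universe), size=10, replace=False))
        overlap = set(rng.choice(sorted(universe), size=8, replace=False))
        table = clump_enrichment_test(de, universe, {"t": overlap})
        k = len(de & overlap)
        expected = hypergeom_bruteforce(k, 40, len(overlap), 10)
        assert table.loc["t", "p"] == pytest.approx(expected, rel=1e-9)


def test_enriched_trait_ranks_first(cohort):
    from cagekit import synthetic as syn

    snps, ld = syn.simulate_gwas_panel(cohort.truth, seed=205)
    clumps = build_ld_clumps(snps, ld)
    regions = [
        GenomicInterval(cohort.truth.chrom, lo - 1, hi)
        for lo, hi in syn.upregulated_regions(cohort.truth)
    ]
    fractions = clump_overlap_fractions(clumps, regions)
    res = eb_shrink_fractions(fractions)
    assert res.table["shrunken"].idxmax() == "IBD_like"
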