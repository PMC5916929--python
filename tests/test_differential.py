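"""NB-GLM contrasts, DE set logic, size factors and overlap enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cagekit.differential import (
    NBDifferentialModel,
    define_de_sets,
    overlap_enrichment_from_counts,
    region_overlap_enrichment,
    tss_size_factors,
)
from cagekit.io import GenomicInterval


def _simulate_counts(rng, n_features, groups, lfc_by_group, base=50.0,
                     dispersion=0.1, batch_lfc=None):
    """NB counts with known group log2 effects (simulation oracle input)."""
    samples, group_col, batch_col = [], [], []
    for g, n in groups.items():
        for k in range(n):
            samples.append(f"{g}{k}")
            group_col.append(g)
            batch_col.append(f"b{k % 2}")
    table = pd.DataFrame({"group": group_col, "batch": batch_col},
                         index=pd.Index(samples, name="sample_id"))
    rows = []
    for _ in range(n_features):
        mu = base * np.exp2(np.array([lfc_by_group.get(g, 0.0) for g in group_col]))
        if batch_lfc:
            mu = mu * np.exp2(np.array([batch_lfc.get(b, 0.0) for b in batch_col]))
        lam = rng.gamma(1 / dispersion, mu * dispersion)
        rows.append(rng.poisson(lam))
    counts = pd.DataFrame(rows, columns=samples,
                          index=[f"f{i}" for i in range(n_features)])
    return counts, table


def test_null_features_centered_with_high_fdr(rng):
    counts, table = _simulate_counts(
        rng, 60, {"CDa": 8, "UCa": 8, "Ctrl": 8}, {}
    )
    res = NBDifferentialModel(counts, table).fit("IBD")
    assert abs(res.table["log2fc"].median()) < 0.2
    assert (res.table["fdr"] < 0.05).mean() <= 0.07


def test_fourfold_effect_recovered(rng):
    # 4-fold CDa & UCa increase, n = 10/group, dispersion 0.1
    counts, table = _simulate_counts(
        rng, 100, {"CDa": 10, "UCa": 10, "Ctrl": 10},
        {"CDa": 2.0, "UCa": 2.0}, dispersion=0.1,
    )
    res = NBDifferentialModel(counts, table).fit("IBD")
    assert 1.6 <= res.table["log2fc"].median() <= 2.4
    assert (res.table["fdr"] < 0.05).mean() > 0.95


def test_batch_effect_blocked_not_inflating_contrast(rng):
    # strong batch signal, no group signal: contrast p-values stay flat
    counts, table = _simulate_counts(
        rng, 80, {"CDa": 10, "UCa": 10, "Ctrl": 10}, {},
        batch_lfc={"b0": 1.0, "b1": -1.0},
    )
    res = NBDifferentialModel(counts, table).fit("IBD")
    assert (res.table["p"] < 0.05).mean() <= 0.10
    assert (res.table["fdr"] < 0.05).mean() <= 0.05


def test_all_zero_feature_skipped(rng):
    counts, table = _simulate_counts(rng, 5, {"CDa": 3, "UCa": 3, "Ctrl": 3}, {})
    counts.iloc[0] = 0
    res = NBDifferentialModel(counts, table).fit("IBD")
    assert res.table["fdr"].iloc[0] == 1.0 and res.table["log2fc"].iloc[0] == 0.0


def test_small_group_rejected(rng):
    counts, table = _simulate_counts(rng, 5, {"CDa": 1, "UCa": 3, "Ctrl": 3}, {})
    with pytest.raises(ValueError, match="fewer than 2"):
        NBDifferentialModel(counts, table)


# -- set logic --------------------------------------------------------------


def _tables(rows):
    idx = [r[0] for r in rows]
    ibd = pd.DataFrame({"log2fc": [r[1] for r in rows], "fdr": [r[2] for r in rows]},
                       index=idx)
    cduc = pd.DataFrame({"log2fc": [r[3] for r in rows], "fdr": [r[4] for r in rows]},
                        index=idx)
    return ibd, cduc


def test_de_set_rules():
    ibd, cduc = _tables([
        ("up", 1.5, 0.01, 0.0, 1.0),
        ("weak", -0.9, 0.001, 0.0, 1.0),
        ("ucspec", 0.0, 1.0, -2.0, 0.01),
        ("down", -1.5, 0.001, 0.0, 1.0),
        ("null", 0.1, 0.9, 0.2, 0.8),
    ])
    sets = define_de_sets(ibd, cduc)
    assert sets.loc["up", "set"] == "IBD_up"
    assert sets.loc["weak", "set"] == "none"  # |lfc| <= 1 despite tiny FDR
    assert sets.loc["ucspec", "set"] == "UC_spec"  # negative CDa-vs-UCa lfc
    assert sets.loc["down", "set"] == "IBD_down"
    assert sets.loc["null", "set"] == "none"


def test_de_sets_pure_function_of_rows():
    ibd, cduc = _tables([
        ("a", 1.5, 0.01, 0.0, 1.0),
        ("b", -1.5, 0.01, 0.0, 1.0),
        ("c", 0.0, 1.0, 2.0, 0.01),
    ])
    direct = define_de_sets(ibd, cduc)
    perm = ["c", "a", "b"]
    permuted = define_de_sets(ibd.loc[perm], cduc.loc[perm])
    pd.testing.assert_frame_equal(direct.loc[perm], permuted)


# -- size factors -----------------------------------------------------------


def test_size_factors_identity_and_scaling(rng):
    counts = pd.DataFrame(
        rng.integers(10, 100, size=(100, 6)).astype(float),
        columns=[f"s{i}" for i in range(6)],
    )
    same = pd.concat([counts["s0"]] * 6, axis=1)
    same.columns = counts.columns
    assert np.allclose(tss_size_factors(same), 1.0)
    scaled = counts.copy()
    scaled["s0"] = scaled["s0"] * 3
    f_before, f_after = tss_size_factors(counts), tss_size_factors(scaled)
    ratio = f_after / f_before
    # the scaled sample's factor triples relative to the others
    assert ratio["s0"] / np.exp(np.log(ratio.drop("s0")).mean()) == pytest.approx(3.0)


def test_size_factors_degenerate_rejected():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["a", "b"]).astype(float)
    with pytest.raises(ValueError):
        tss_size_factors(counts)


# -- overlap enrichment -----------------------------------------------------


def test_enrichment_balanced_table_is_zero():
    enr, p = overlap_enrichment_from_counts(10, 10, 10, 10)
    assert enr == 0.0 and p == pytest.approx(1.0)


def test_enrichment_arithmetic():
    enr, _ = overlap_enrichment_from_counts(8, 2, 2, 8)
    assert enr == pytest.approx(2.0)


def test_enrichment_antisymmetric_under_swap(rng):
    for _ in range(20):
        a, b, c, d = rng.integers(1, 30, size=4)
        e1, _ = overlap_enrichment_from_counts(a, c, b, d)
        e2, _ = overlap_enrichment_from_counts(b, d, a, c)
        assert e1 == pytest.approx(-e2)


def fisher_bruteforce(a, c, b, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, row2 = a + c, b + d
    col1 = a + b
    n = row1 + row2
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, col1 - row2), min(col1, row1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def test_fisher_matches_enumeration(rng):
    for _ in range(50):
        a, c, b, d = (int(x) for x in rng.integers(0, 13, size=4))
        if a + c == 0 or b + d == 0:
            continue
        _, p = overlap_enrichment_from_counts(a, c, b, d)
        assert p == pytest.approx(fisher_bruteforce(a, c, b, d), rel=1e-9)


def test_enrichment_zero_margin_reported_na():
    enr, p = overlap_enrichment_from_counts(0, 5, 3, 7)
    assert np.isnan(enr) and 0 <= p <= 1
    enr_cc, _ = overlap_enrichment_from_counts(0, 5, 3, 7, continuity=True)
    assert np.isfinite(enr_cc)


def test_enrichment_on_intervals_and_sets():
    interest = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(4)]
    background = [GenomicInterval("chr1", 10_000 + i * 100, 10_000 + i * 100 + 50)
                  for i in range(4)]
    peaks = [GenomicInterval("chr1", 0, 400)]  # covers all interest regions
    enr, p = region_overlap_enrichment(interest, background, peaks)
    assert enr > 0 or np.isnan(enr)
    enr_sets, _ = region_overlap_enrichment({"a", "b"}, {"c", "d"}, {"a", "b", "c"})
    assert enr_sets == pytest.approx(1.0)  # log2((2/2) / (1/2))
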