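"""Tag-cluster calling: TPM, pooling, merging, queue trimming, summits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagekit.clustering import (
    cluster_ctss,
    find_summit,
    pool_ctss,
    quantify_and_filter,
    tpm_normalize,
    trim_cluster_queue,
)
from cagekit.io import CtssProfile

from conftest import make_cluster


def profile(entries, sample_id="s1", library_size=0):
    return CtssProfile(sample_id, dict(entries), library_size)


# -- TPM --------------------------------------------------------------------


def test_tpm_unit_library():
    p = profile({("chr1", 100, "+"): 5}, library_size=1_000_000)
    assert tpm_normalize(p)[("chr1", 100, "+")] == pytest.approx(5.0)


def test_tpm_absent_positions_not_stored():
    p = profile({("chr1", 100, "+"): 5}, library_size=1_000_000)
    assert ("chr1", 101, "+") not in tpm_normalize(p)


def test_tpm_arithmetic():
    p = profile({("chr1", 1, "+"): 17}, library_size=17_300_000)
    assert tpm_normalize(p)[("chr1", 1, "+")] == pytest.approx(17 / 17.3e6 * 1e6)


def test_tpm_zero_library_rejected():
    with pytest.raises(ValueError):
        tpm_normalize(CtssProfile("s", {}, 0))


# -- pooling ----------------------------------------------------------------


def test_pool_drops_singletons():
    p = profile({("chr1", 100, "+"): 1, ("chr1", 200, "+"): 5})
    joint = pool_ctss([p])
    positions, _ = joint[("chr1", "+")]
    assert positions.tolist() == [200]


def test_pool_sums_per_library_tpm():
    p1 = profile({("chr1", 100, "+"): 2}, "a", library_size=1_000_000)
    p2 = profile({("chr1", 100, "+"): 2}, "b", library_size=1_000_000)
    positions, tpm = pool_ctss([p1, p2])[("chr1", "+")]
    assert tpm.tolist() == [4.0]  # 2 TPM from each library


def test_pool_filter_is_per_library():
    p1 = profile({("chr1", 100, "+"): 1}, "a", library_size=1_000_000)
    p2 = profile({("chr1", 100, "+"): 3}, "b", library_size=1_000_000)
    positions, tpm = pool_ctss([p1, p2])[("chr1", "+")]
    assert tpm.tolist() == [3.0]  # only library b contributes


# -- clustering -------------------------------------------------------------


def _joint(positions, strand="+", chrom="chr1"):
    pos = np.array(sorted(positions), dtype=np.int64)
    return {(chrom, strand): (pos, np.ones(len(pos)))}


def test_gap_of_20_merges():
    (tc,) = cluster_ctss(_joint([100, 120]))
    assert (tc.start, tc.end) == (100, 120)


def test_gap_of_21_splits():
    clusters = cluster_ctss(_joint([100, 121]))
    assert [(c.start, c.end) for c in clusters] == [(100, 100), (121, 121)]


def test_strands_never_merge():
    joint = {**_joint([100, 110], "+"), **_joint([100, 110], "-")}
    clusters = cluster_ctss(joint)
    assert len(clusters) == 2
    assert {c.strand for c in clusters} == {"+", "-"}


def test_every_pooled_position_in_exactly_one_cluster(rng):
    positions = sorted(rng.choice(5000, size=300, replace=False) + 1)
    clusters = cluster_ctss(_joint(positions))
    covered = sorted(p for c in clusters for p in c.positions)
    assert covered == positions
    spans = sorted((c.start, c.end) for c in clusters)
    assert all(s2 - e1 > 20 for (_, e1), (s2, _) in zip(spans, spans[1:]))


# -- queue trimming ---------------------------------------------------------


def test_trim_hand_simulation():
    tc = make_cluster([1, 5, 10, 5, 1])
    out = trim_cluster_queue(tc, 0.10)  # budget 2.2: remove both 1-TPM edges
    assert out.tpm.tolist() == [5, 10, 5]


def test_trim_single_position_unchanged():
    tc = make_cluster([4.0])
    out = trim_cluster_queue(tc, 0.10)
    assert out.tpm.tolist() == [4.0]


def test_trim_uniform_profile_unchanged():
    tc = make_cluster([4, 4, 4, 4, 4])
    out = trim_cluster_queue(tc, 0.10)  # budget 2 < any edge
    assert len(out.positions) == 5


def exhaustive_trim_spans(tpm, trim_fraction=0.10):
    """All reachable trimmed spans under the greedy edge-removal rule,
    exploring every tie branch (independent oracle)."""
    total = float(np.sum(tpm))
    budget = trim_fraction * total
    results = set()

    def recurse(lo, hi, removed):
        if lo == hi:
            results.add((lo, hi))
            return
        left, right = tpm[lo], tpm[hi]
        smallest = min(left, right)
        if removed + smallest > budget:
            results.add((lo, hi))
            return
        if left == smallest:
            recurse(lo + 1, hi, removed + left)
        if right == smallest:  # both branches explored on ties
            recurse(lo, hi - 1, removed + right)

    recurse(0, len(tpm) - 1, 0.0)
    return results


def test_trim_matches_exhaustive_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(1, 50))
        tpm = rng.integers(1, 10, size=n).astype(float)
        tc = make_cluster(tpm)
        out = trim_cluster_queue(tc, 0.10)
        span = (int(out.positions[0] - tc.positions[0]), int(out.positions[-1] - tc.positions[0]))
        assert span in exhaustive_trim_spans(tpm, 0.10)
        assert out.tpm.sum() >= 0.9 * tc.tpm.sum() - 1e-9


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(min_value=0.01, max_value=100), min_size=1, max_size=40),
    st.floats(min_value=0.0, max_value=0.5),
)
def test_trim_invariants(tpm, frac):
    tc = make_cluster(tpm)
    out = trim_cluster_queue(tc, frac)
    # contiguous sub-span retaining >= (1 - frac) of the mass
    assert out.start >= tc.start and out.end <= tc.end
    assert out.tpm.sum() >= (1 - frac) * tc.tpm.sum() - 1e-9
    # idempotent relative to the original budget: retrimming with the
    # leftover budget removes nothing more
    total = tc.tpm.sum()
    removed = total - out.tpm.sum()
    leftover = (frac * total - removed) / out.tpm.sum() if out.tpm.sum() else 0.0
    again = trim_cluster_queue(out, max(leftover, 0.0) * (1 - 1e-9))
    assert len(again.positions) == len(out.positions)


# -- summit -----------------------------------------------------------------


def test_summit_argmax_and_tie_break():
    assert find_summit(make_cluster([1, 9, 3], start=100)) == 101
    assert find_summit(make_cluster([5, 5], start=100)) == 100


def test_trimmed_span_contains_summit_when_peak_exceeds_budget(rng):
    for _ in range(200):
        tpm = rng.integers(1, 30, size=int(rng.integers(2, 30))).astype(float)
        tc = make_cluster(tpm)
        if tc.tpm.max() <= 0.10 * tc.tpm.sum():
            continue
        out = trim_cluster_queue(tc, 0.10)
        assert out.start <= tc.summit <= out.end


# -- quantification & filtering --------------------------------------------


def test_quantify_filter_three_library_rule():
    # per-sample TPM [1.2, 0.5, 1.0, 1.1] with unit-size libraries
    tc = make_cluster([1.0], start=100)
    profiles = [
        profile({("chr1", 100, "+"): c}, f"s{i}", library_size=10_000_000)
        for i, c in enumerate([12, 5, 10, 11])
    ]
    counts, kept = quantify_and_filter([tc], profiles, min_tpm=1, min_libraries=3)
    assert len(kept) == 1

    # TPM >= 1 in only two libraries: dropped
    profiles2 = [
        profile({("chr1", 100, "+"): c}, f"s{i}", library_size=10_000_000)
        for i, c in enumerate([12, 5, 9, 11])
    ]
    counts2, kept2 = quantify_and_filter([tc], profiles2, min_tpm=1, min_libraries=3)
    assert kept2 == []


def test_quantify_includes_singletons():
    # a singleton CTSS is excluded from clustering but counted here
    tc = make_cluster([5.0, 5.0], start=100)
    p = profile({("chr1", 100, "+"): 1, ("chr1", 101, "+"): 4}, "s0")
    counts, _ = quantify_and_filter([tc], [p], min_tpm=0, min_libraries=0)
    assert counts.iloc[0, 0] == 5


def test_quantify_rejects_overlapping_clusters():
    a = make_cluster([1, 1, 1], start=100)
    b = make_cluster([1, 1, 1], start=101, tc_id="tc_other")
    with pytest.raises(ValueError, match="overlap"):
        quantify_and_filter([a, b], [profile({("chr1", 100, "+"): 2})])
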