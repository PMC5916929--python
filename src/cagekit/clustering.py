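"""Tag-cluster (CAGE-defined TSS) calling from CTSS profiles.

The pipeline mirrors standard CAGE promoter calling: per-library
singleton CTSSs are dropped, surviving positions are TPM-normalized and
summed into a joint profile, same-strand positions within 20 bp are
merged into tag clusters (TCs), weak cluster tails are trimmed by a
queue algorithm until just under 10% of cluster TPM is removed, and the
trimmed TCs are quantified in every sample (singletons included at this
step) and filtered on a minimum-TPM / minimum-library rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtssProfile, GenomicInterval

# joint pooled profile: (chrom, strand) -> (sorted positions, pooled TPM)
JointProfile = dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


@dataclass
class TagCluster:
    """A called TSS region on one strand.

    ``positions`` are the 1-based CTSS positions retained in the cluster
    (ascending) and ``tpm`` the pooled per-position TPM.  The span is
    ``[start, end]`` 1-based inclusive.
    """

    tc_id: str
    chrom: str
    strand: str
    positions: np.ndarray
    tpm: np.ndarray
    summit: int = 0

    def __post_init__(self) -> None:
        if len(self.positions) == 0:
            raise ValueError("empty tag cluster")
        if self.summit == 0:
            self.summit = find_summit(self)

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def total_tpm(self) -> float:
        return float(self.tpm.sum())

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start - 1, self.end, self.strand)


def tpm_normalize(profile: CtssProfile) -> dict[tuple[str, int, str], float]:
    """Tags-per-million: count / library_size * 1e6 at every stored position."""
    if profile.library_size <= 0:
        raise ValueError(f"{profile.sample_id}: library_size must be positive")
    scale = 1e6 / profile.library_size
    return {key: count * scale for key, count in profile.entries.items()}


def pool_ctss(
    profiles: list[CtssProfile], min_tags_per_library: int = 2
) -> JointProfile:
    """Sum per-library TPM profiles into a joint CTSS profile.

    Positions supported by fewer than ``min_tags_per_library`` tags in a
    library are ignored for that library (singleton CTSSs carry no
    weight at the cluster-definition stage).
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    pooled: dict[tuple[str, int, str], float] = {}
    for profile in profiles:
        scale = 1e6 / profile.library_size if profile.library_size else 0.0
        for key, count in profile.entries.items():
            if count < min_tags_per_library:
                continue
            pooled[key] = pooled.get(key, 0.0) + count * scale
    joint: JointProfile = {}
    by_cs: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for (chrom, pos, strand), tpm in pooled.items():
        by_cs.setdefault((chrom, strand), []).append((pos, tpm))
    for cs, items in by_cs.items():
        items.sort()
        joint[cs] = (
            np.array([p for p, _ in items], dtype=np.int64),
            np.array([t for _, t in items], dtype=float),
        )
    return joint


def cluster_ctss(joint: JointProfile, merge_dist: int = 20) -> list[TagCluster]:
    """Single-linkage merge of same-strand CTSSs with gaps <= merge_dist."""
    clusters: list[TagCluster] = []
    for (chrom, strand) in sorted(joint):
        positions, tpm = joint[(chrom, strand)]
        if len(positions) == 0:
            continue
        gaps = np.diff(positions)
        breaks = np.flatnonzero(gaps > merge_dist) + 1
        for chunk_pos, chunk_tpm in zip(
            np.split(positions, breaks), np.split(tpm, breaks)
        ):
            clusters.append(
                TagCluster(
                    tc_id=f"tc_{chrom}_{strand}_{chunk_pos[0]}",
                    chrom=chrom,
                    strand=strand,
                    positions=chunk_pos,
                    tpm=chunk_tpm,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def trim_cluster_queue(cluster: TagCluster, trim_fraction: float = 0.10) -> TagCluster:
    """Trim weakly expressed cluster tails edge by edge.

    Repeatedly removes the more lowly expressed of the two current edge
    positions, stopping before the cumulative removed TPM would exceed
    ``trim_fraction`` of the original total; the last position is never
    removed.  When both edges are equal the lower-coordinate edge goes.
    The result is a contiguous sub-span retaining at least
    ``1 - trim_fraction`` of the original TPM.
    """
    total = float(cluster.tpm.sum())
    if total <= 0:
        raise ValueError(f"{cluster.tc_id}: all-zero TPM profile")
    budget = trim_fraction * total
    lo, hi = 0, len(cluster.positions) - 1
    removed = 0.0
    while lo < hi:
        left, right = cluster.tpm[lo], cluster.tpm[hi]
        edge = left if left <= right else right
        if removed + edge > budget:
            break
        if left <= right:
            lo += 1
        else:
            hi -= 1
        removed += edge
    trimmed = TagCluster(
        tc_id=cluster.tc_id,
        chrom=cluster.chrom,
        strand=cluster.strand,
        positions=cluster.positions[lo : hi + 1],
        tpm=cluster.tpm[lo : hi + 1],
    )
    return trimmed


def find_summit(cluster: TagCluster) -> int:
    """Position of maximal pooled TPM; ties go to the lowest coordinate."""
    return int(cluster.positions[int(np.argmax(cluster.tpm))])


def quantify_clusters(
    clusters: list[TagCluster], profiles: list[CtssProfile]
) -> pd.DataFrame:
    """Raw tag counts per (cluster, sample), singleton CTSSs included."""
    _check_disjoint(clusters)
    sample_ids = [p.sample_id for p in profiles]
    counts = np.zeros((len(clusters), len(profiles)), dtype=np.int64)
    index: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, tc in enumerate(clusters):
        index.setdefault((tc.chrom, tc.strand), []).append((tc.start, tc.end, i))
    for spans in index.values():
        spans.sort()
    for j, profile in enumerate(profiles):
        for (chrom, pos, strand), count in profile.entries.items():
            spans = index.get((chrom, strand))
            if not spans:
                continue
            k = _bisect_span(spans, pos)
            if k is not None:
                counts[k, j] += count
    return pd.DataFrame(counts, index=[tc.tc_id for tc in clusters], columns=sample_ids)


def _bisect_span(spans: list[tuple[int, int, int]], pos: int) -> int | None:
    import bisect

    i = bisect.bisect_right(spans, (pos, np.iinfo(np.int64).max, 0)) - 1
    if i >= 0 and spans[i][0] <= pos <= spans[i][1]:
        return spans[i][2]
    return None


def _check_disjoint(clusters: list[TagCluster]) -> None:
    seen: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for tc in clusters:
        seen.setdefault((tc.chrom, tc.strand), []).append((tc.start, tc.end))
    for key, spans in seen.items():
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping clusters on {key}: [{s1},{e1}] vs start {s2}")


def quantify_and_filter(
    clusters: list[TagCluster],
    profiles: list[CtssProfile],
    min_tpm: float = 1.0,
    min_libraries: int = 3,
) -> tuple[pd.DataFrame, list[TagCluster]]:
    """Count tags per TC/sample and keep TCs with >= min_tpm TPM in
    >= min_libraries samples."""
    counts = quantify_clusters(clusters, profiles)
    lib_sizes = np.array([p.library_size for p in profiles], dtype=float)
    tpm = counts.to_numpy() / lib_sizes[None, :] * 1e6
    keep = (tpm >= min_tpm).sum(axis=1) >= min_libraries
    kept_clusters = [tc for tc, k in zip(clusters, keep) if k]
    return counts.loc[keep], kept_clusters


@dataclass
class TssCallResult:
    clusters: list[TagCluster]
    counts: pd.DataFrame
    tpm: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def call_tag_clusters(
    profiles: list[CtssProfile],
    merge_dist: int = 20,
    trim_fraction: float = 0.10,
    min_tags_per_library: int = 2,
    min_tpm: float = 1.0,
    min_libraries: int = 3,
) -> TssCallResult:
    """End-to-end TC calling: pool, cluster, trim, quantify, filter."""
    joint = pool_ctss(profiles, min_tags_per_library=min_tags_per_library)
    raw = cluster_ctss(joint, merge_dist=merge_dist)
    trimmed = [trim_cluster_queue(tc, trim_fraction=trim_fraction) for tc in raw]
    counts, kept = quantify_and_filter(
        trimmed, profiles, min_tpm=min_tpm, min_libraries=min_libraries
    )
    lib_sizes = np.array([p.library_size for p in profiles], dtype=float)
    tpm = counts / lib_sizes[None, :] * 1e6
    return TssCallResult(clusters=kept, counts=counts, tpm=tpm)
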