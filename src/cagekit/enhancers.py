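"""Transcribed-enhancer detection from bidirectional CAGE signal.

Enhancers are called as balanced divergent transcription (a minus-strand
arm to the left of a plus-strand arm) outside annotated promoters and
exons.  Arms are ordinary tag clusters built by the same 20-bp
merge / queue-trim machinery as promoters, restricted to positions
outside the exclusion mask.  Candidates keep a directionality score

    D = (plus - minus) / (plus + minus)

computed from pooled arm TPM; only |D| < 0.6 survives.  Support tiers:
``permissive`` needs >= 2 tags in >= 1 sample within the enhancer span
(both strands summed), ``strict`` >= 2 tags in >= 8 samples.  Strict
enhancers whose consecutive midpoints lie within 15 kb chain into
enhancer clusters of >= 3 members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import JointProfile, TagCluster, cluster_ctss, trim_cluster_queue
from .io import CtssProfile, GeneModel, GenomicInterval

# exclusion mask: chrom -> sorted merged list of (start, end) 1-based inclusive
Mask = dict[str, list[tuple[int, int]]]


@dataclass
class EnhancerCandidate:
    enh_id: str
    chrom: str
    minus_arm: TagCluster
    plus_arm: TagCluster
    midpoint: int
    d: float
    tier: str = "candidate"  # candidate | rejected | permissive | strict

    @property
    def start(self) -> int:
        return self.minus_arm.start

    @property
    def end(self) -> int:
        return self.plus_arm.end

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start - 1, self.end, ".")


@dataclass
class EnhancerCluster:
    cluster_id: str
    members: list[str]
    chrom: str
    span: tuple[int, int]
    midpoints: list[int] = field(default_factory=list)


def build_exclusion_mask(
    gene_models: list[GeneModel], exon_pad: int = 200, tss_pad: int = 500
) -> Mask:
    """Union of +/-exon_pad around exons and +/-tss_pad around annotated
    TSSs, merged per chromosome, strand-ignored (1-based inclusive)."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for gene in gene_models:
        spans = raw.setdefault(gene.chrom, [])
        for exon in gene.exons:
            spans.append((exon.start + 1 - exon_pad, exon.end + exon_pad))
        for tss in gene.transcript_tss:
            spans.append((tss - tss_pad, tss + tss_pad))
    mask: Mask = {}
    for chrom, spans in raw.items():
        spans.sort()
        merged: list[tuple[int, int]] = []
        for start, end in spans:
            start = max(start, 1)
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        mask[chrom] = merged
    return mask


def mask_overlaps(mask: Mask, chrom: str, start: int, end: int) -> bool:
    """Does the 1-based inclusive span [start, end] touch the mask?"""
    import bisect

    spans = mask.get(chrom)
    if not spans:
        return False
    i = bisect.bisect_right(spans, (end, np.iinfo(np.int64).max))
    if i == 0:
        return False
    return spans[i - 1][1] >= start


def apply_mask(joint: JointProfile, mask: Mask) -> JointProfile:
    """Drop joint-profile positions that fall inside the mask."""
    out: JointProfile = {}
    for (chrom, strand), (positions, tpm) in joint.items():
        keep = np.array(
            [not mask_overlaps(mask, chrom, int(p), int(p)) for p in positions],
            dtype=bool,
        )
        if keep.any():
            out[(chrom, strand)] = (positions[keep], tpm[keep])
    return out


def directionality_score(plus_expr: float, minus_expr: float) -> float:
    """D = (plus - minus) / (plus + minus); undefined when both are zero."""
    total = plus_expr + minus_expr
    if total <= 0:
        raise ValueError("directionality undefined for zero expression")
    return (plus_expr - minus_expr) / total


def detect_bidirectional_candidates(
    joint: JointProfile,
    mask: Mask,
    pairing_dist: int = 400,
    max_abs_d: float = 0.6,
    merge_dist: int = 20,
    trim_fraction: float = 0.10,
) -> list[EnhancerCandidate]:
    """Pair divergent strand-specific arms into enhancer candidates.

    Each minus-strand arm pairs with the nearest unused plus-strand arm
    entirely to its right, inner edges at most ``pairing_dist`` bp apart.
    Midpoint = floor of the mean of the inner arm edges.  Candidates with
    |D| >= ``max_abs_d`` or any mask overlap are discarded.
    """
    unmasked = apply_mask(joint, mask)
    arms = [
        trim_cluster_queue(tc, trim_fraction=trim_fraction)
        for tc in cluster_ctss(unmasked, merge_dist=merge_dist)
    ]
    by_chrom: dict[str, dict[str, list[TagCluster]]] = {}
    for arm in arms:
        by_chrom.setdefault(arm.chrom, {"+": [], "-": []})[arm.strand].append(arm)
    candidates: list[EnhancerCandidate] = []
    for chrom in sorted(by_chrom):
        minus_arms = sorted(by_chrom[chrom]["-"], key=lambda a: a.start)
        plus_arms = sorted(by_chrom[chrom]["+"], key=lambda a: a.start)
        used_plus: set[int] = set()
        for m_arm in minus_arms:
            best: tuple[int, int] | None = None  # (gap, index)
            for i, p_arm in enumerate(plus_arms):
                if i in used_plus or p_arm.start <= m_arm.end:
                    continue
                gap = p_arm.start - m_arm.end
                if gap > pairing_dist:
                    break
                if best is None or gap < best[0]:
                    best = (gap, i)
            if best is None:
                continue
            p_arm = plus_arms[best[1]]
            d = directionality_score(p_arm.total_tpm, m_arm.total_tpm)
            if abs(d) >= max_abs_d:
                continue
            if mask_overlaps(mask, chrom, m_arm.start, p_arm.end):
                continue
            used_plus.add(best[1])
            midpoint = (m_arm.end + p_arm.start) // 2
            candidates.append(
                EnhancerCandidate(
                    enh_id=f"enh_{chrom}_{midpoint}",
                    chrom=chrom,
                    minus_arm=m_arm,
                    plus_arm=p_arm,
                    midpoint=midpoint,
                    d=d,
                )
            )
    return candidates


def quantify_enhancers(
    candidates: list[EnhancerCandidate], profiles: list[CtssProfile]
) -> pd.DataFrame:
    """Raw tag counts per (candidate, sample), both strands summed over
    the full candidate span."""
    sample_ids = [p.sample_id for p in profiles]
    counts = np.zeros((len(candidates), len(profiles)), dtype=np.int64)
    spans: dict[str, list[tuple[int, int, int]]] = {}
    for i, cand in enumerate(candidates):
        spans.setdefault(cand.chrom, []).append((cand.start, cand.end, i))
    for chrom_spans in spans.values():
        chrom_spans.sort()
    for j, profile in enumerate(profiles):
        for (chrom, pos, _strand), count in profile.entries.items():
            chrom_spans = spans.get(chrom)
            if not chrom_spans:
                continue
            # enhancer spans may in principle overlap; scan the local window
            import bisect

            k = bisect.bisect_right(chrom_spans, (pos, np.iinfo(np.int64).max, 0))
            for s, e, i in reversed(chrom_spans[:k]):
                if e < pos:
                    if pos - s > 100000:
                        break
                    continue
                counts[i, j] += count
    return pd.DataFrame(
        counts, index=[c.enh_id for c in candidates], columns=sample_ids
    )


def filter_by_support(
    candidates: list[EnhancerCandidate],
    profiles: list[CtssProfile],
    min_tags: int = 2,
    permissive_samples: int = 1,
    strict_samples: int = 8,
) -> tuple[list[EnhancerCandidate], pd.DataFrame]:
    """Assign support tiers from raw per-sample tag counts."""
    counts = quantify_enhancers(candidates, profiles)
    supported = (counts.to_numpy() >= min_tags).sum(axis=1)
    for cand, n_sup in zip(candidates, supported):
        if n_sup >= strict_samples:
            cand.tier = "strict"
        elif n_sup >= permissive_samples:
            cand.tier = "permissive"
        else:
            cand.tier = "rejected"
    return candidates, counts


def chain_enhancer_clusters(
    enhancers: list[EnhancerCandidate], gap: int = 15000, min_members: int = 3
) -> tuple[list[EnhancerCluster], list[list[EnhancerCandidate]]]:
    """Chain enhancers whose consecutive midpoints are <= gap apart.

    Returns (clusters with >= min_members, sub-threshold chains).
    """
    by_chrom: dict[str, list[EnhancerCandidate]] = {}
    for enh in enhancers:
        by_chrom.setdefault(enh.chrom, []).append(enh)
    clusters: list[EnhancerCluster] = []
    leftovers: list[list[EnhancerCandidate]] = []
    n = 0
    for chrom in sorted(by_chrom):
        chain: list[EnhancerCandidate] = []
        for enh in sorted(by_chrom[chrom], key=lambda e: e.midpoint):
            if chain and enh.midpoint - chain[-1].midpoint > gap:
                n = _emit_chain(chain, clusters, leftovers, min_members, n)
                chain = []
            chain.append(enh)
        if chain:
            n = _emit_chain(chain, clusters, leftovers, min_members, n)
    return clusters, leftovers


def _emit_chain(chain, clusters, leftovers, min_members, n) -> int:
    if len(chain) >= min_members:
        clusters.append(
            EnhancerCluster(
                cluster_id=f"ec_{n}",
                members=[e.enh_id for e in chain],
                chrom=chain[0].chrom,
                span=(chain[0].start, chain[-1].end),
                midpoints=[e.midpoint for e in chain],
            )
        )
        return n + 1
    leftovers.append(list(chain))
    return n
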