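"""Categorize tag clusters against gene models; aggregate to gene level.

Categories, in priority order for gene assignment:

* ``canonical`` — TC summit within +/-window of a gene's most upstream
  annotated TSS, same strand;
* ``known_alternative`` — within +/-window of any other annotated
  transcript TSS, same strand;
* ``novel_alternative`` — inside the gene span (introns included), same
  strand, outside all TSS windows;
* ``novel_antisense`` — inside a gene span on the opposite strand;
* ``novel_intergenic`` — none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clustering import TagCluster
from .io import GeneModel

CATEGORY_PRIORITY = {
    "canonical": 0,
    "known_alternative": 1,
    "novel_alternative": 2,
    "novel_antisense": 3,
    "novel_intergenic": 4,
}

# categories that tie a TC to a gene for aggregation (same strand only)
GENE_CATEGORIES = ("canonical", "known_alternative", "novel_alternative")


@dataclass
class TssAnnotation:
    tc_id: str
    category: str
    gene_id: str | None
    distance: int | None  # summit to nearest annotated TSS of the gene


def annotate_tc(
    tc: TagCluster, gene_models: list[GeneModel], window: int = 100
) -> TssAnnotation:
    """Annotate one TC by its summit position against the gene models.

    Multi-gene conflicts resolve by category priority, then by distance
    to the nearest annotated TSS.
    """
    summit = tc.summit
    best: tuple[int, int, str, str] | None = None  # (priority, distance, cat, gene)
    antisense_hit: tuple[int, str] | None = None
    for gene in gene_models:
        if gene.chrom != tc.chrom:
            continue
        in_span = gene.span.start < summit <= gene.span.end  # span is 0-based
        if gene.strand != tc.strand:
            if in_span and (antisense_hit is None):
                antisense_hit = (0, gene.gene_id)
            continue
        d_upstream = abs(summit - gene.upstream_tss)
        if d_upstream <= window:
            cand = (CATEGORY_PRIORITY["canonical"], d_upstream, "canonical", gene.gene_id)
        else:
            d_other = min(
                (abs(summit - t) for t in gene.transcript_tss if t != gene.upstream_tss),
                default=None,
            )
            if d_other is not None and d_other <= window:
                cand = (
                    CATEGORY_PRIORITY["known_alternative"],
                    d_other,
                    "known_alternative",
                    gene.gene_id,
                )
            elif in_span:
                cand = (
                    CATEGORY_PRIORITY["novel_alternative"],
                    d_upstream,
                    "novel_alternative",
                    gene.gene_id,
                )
            else:
                continue
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is not None:
        return TssAnnotation(tc.tc_id, best[2], best[3], best[1])
    if antisense_hit is not None:
        return TssAnnotation(tc.tc_id, "novel_antisense", antisense_hit[1], None)
    return TssAnnotation(tc.tc_id, "novel_intergenic", None, None)


def annotate_clusters(
    clusters: list[TagCluster], gene_models: list[GeneModel], window: int = 100
) -> pd.DataFrame:
    rows = [annotate_tc(tc, gene_models, window=window) for tc in clusters]
    return pd.DataFrame(
        {
            "tc_id": [r.tc_id for r in rows],
            "category": [r.category for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "distance": [r.distance for r in rows],
        }
    ).set_index("tc_id")


def aggregate_gene_level(
    tc_matrix: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Sum TC counts to gene level.

    Only same-strand gene-linked categories contribute; every TC counts
    toward at most one gene (the priority-resolved assignment made at
    annotation time).  Antisense and intergenic TCs contribute nowhere.
    """
    ann = annotations.loc[annotations.index.intersection(tc_matrix.index)]
    gene_linked = ann[ann["category"].isin(GENE_CATEGORIES) & ann["gene_id"].notna()]
    grouped = tc_matrix.loc[gene_linked.index].groupby(gene_linked["gene_id"]).sum()
    grouped.index.name = "gene_id"
    return grouped
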