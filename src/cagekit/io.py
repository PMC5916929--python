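"""Genomic and tabular I/O plus the core coordinate conventions.

Internal CTSS coordinates are 1-based single base pairs (the CAGE
convention); everything written to or read from BED/bedGraph is 0-based
half-open.  All conversions between the two live in this module so the
rest of the package never does coordinate arithmetic on file formats.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd

STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``"+"``/``"-"`` for stranded features and ``"."`` for
    unstranded regions such as enhancers.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CtssProfile:
    """Per-sample 5'-end tag counts: (chrom, 1-based pos, strand) -> count.

    Zero counts are never stored.  ``library_size`` defaults to the sum of
    stored counts; the total of mapped tags may be larger and can be
    supplied explicitly (TPM normalization divides by it).
    """

    sample_id: str
    entries: dict[tuple[str, int, str], int] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.library_size == 0:
            self.library_size = sum(self.entries.values())

    def total_tags(self) -> int:
        return sum(self.entries.values())


@dataclass
class GeneModel:
    """A gene with its transcript start sites and exon structure.

    ``upstream_tss`` is the most upstream annotated TSS: the minimum
    transcript start on the plus strand, the maximum on the minus strand.
    All positions are 1-based.
    """

    gene_id: str
    chrom: str
    strand: str
    transcript_tss: list[int]
    upstream_tss: int
    exons: list[GenomicInterval]
    span: GenomicInterval


# ---------------------------------------------------------------------------
# CTSS tables


def read_ctss(path: str, sample_id: str, library_size: int | None = None) -> CtssProfile:
    """Read a 4-column CTSS TSV (chrom, 1-based pos, strand, count)."""
    entries: dict[tuple[str, int, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, strand, count_s = fields
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if count <= 0:
                raise FormatError(f"{path}:{lineno}: count must be positive")
            key = (chrom, pos, strand)
            entries[key] = entries.get(key, 0) + count
    return CtssProfile(sample_id, entries, library_size or 0)


def write_ctss(profile: CtssProfile, path: str) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, strand), count in sorted(profile.entries.items()):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")


def read_ctss_bedgraph(
    plus_path: str, minus_path: str, sample_id: str, library_size: int | None = None
) -> CtssProfile:
    """Read a per-strand bedGraph pair into a CTSS profile.

    bedGraph intervals are 0-based half-open; each covered base becomes a
    1-based CTSS position carrying the interval's value.
    """
    entries: dict[tuple[str, int, str], int] = {}
    for bg_path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(bg_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise FormatError(f"{bg_path}:{lineno}: expected 4 columns")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
                count = int(float(value))
                if count <= 0:
                    raise FormatError(f"{bg_path}:{lineno}: count must be positive")
                for base0 in range(start, end):
                    key = (chrom, base0 + 1, strand)
                    entries[key] = entries.get(key, 0) + count
    return CtssProfile(sample_id, entries, library_size or 0)


def write_ctss_bedgraph(profile: CtssProfile, plus_path: str, minus_path: str) -> None:
    """Write one bedGraph per strand (one line per CTSS base)."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for (chrom, pos, st), count in sorted(profile.entries.items()):
                if st == strand:
                    fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{count}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF)


def read_gene_models(gtf_path: str) -> list[GeneModel]:
    """Parse a GENCODE-style GTF into one :class:`GeneModel` per gene.

    Transcript TSSs are deduplicated.  A transcript without exons is used
    via its own start with a warning from gffutils suppressed (the
    transcript feature itself provides the TSS).
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise FormatError(f"{gtf_path}: gene feature without gene_id")
        strand = gene.strand
        tss: set[int] = set()
        exons: list[GenomicInterval] = []
        for tx in db.children(gene, featuretype="transcript"):
            tss.add(tx.start if strand == "+" else tx.end)
        for exon in db.children(gene, featuretype="exon"):
            exons.append(GenomicInterval(gene.seqid, exon.start - 1, exon.end, strand))
        if not tss:  # gene without transcript features: use the gene span
            tss.add(gene.start if strand == "+" else gene.end)
        upstream = min(tss) if strand == "+" else max(tss)
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=strand,
                transcript_tss=sorted(tss),
                upstream_tss=upstream,
                exons=exons,
                span=span,
            )
        )
    return models


# ---------------------------------------------------------------------------
# BED


def write_bed(
    regions: list[GenomicInterval],
    path: str,
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write BED6 (0-based half-open), sorted by (chrom, start)."""
    names = names or [f"region_{i}" for i in range(len(regions))]
    scores = scores or [0] * len(regions)
    rows = sorted(zip(regions, names, scores), key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


# ---------------------------------------------------------------------------
# Matrices and sample tables


def read_matrix(path: str) -> pd.DataFrame:
    """Read a feature-by-sample TSV; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids: {dups[:5]}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_sample_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if table.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return table


def validate_matrix_samples(matrix: pd.DataFrame, sample_table: pd.DataFrame) -> None:
    """Every expression-matrix column must have a sample-table row."""
    orphans = [c for c in matrix.columns if c not in sample_table.index]
    if orphans:
        raise FormatError(f"matrix columns missing from sample table: {orphans}")


def validate_file(path: str) -> str:
    """Best-effort format detection + validation; returns the detected kind."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".bed":
        read_bed(path)
        return "bed"
    if ext == ".gtf":
        read_gene_models(path)
        return "gtf"
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if len(first) == 4 and first[2] in STRANDS:
        read_ctss(path, "validate")
        return "ctss"
    read_matrix(path)
    return "matrix"
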