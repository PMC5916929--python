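"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates a CAGE study of colon biopsies at desk scale: a
toy genome with non-overlapping genes and intergenic enhancers (a
fraction arranged into clusters), per-sample CTSS profiles with
negative-binomial counts shaped as sharp unidirectional promoter peaks
and balanced divergent enhancer arm pairs, planted differential
expression in groups {CDa, UCa, (CDi, UCi,) Ctrl} with batch structure,
enhancer-TSS links induced by shared latent activity, GWAS SNP panels
with block LD enriched in upregulated regions, and qPCR dCq matrices
with planted organoid/monocyte response overlap.

Every planted fact is recorded in :class:`SimulationTruth`;
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtssProfile, GeneModel, GenomicInterval

DEFAULT_GROUPS = {"CDa": 20, "UCa": 25, "Ctrl": 29}
# planted differential gene counts under the default cohort
DEFAULT_GENE_DE = {"IBD_up": 12, "IBD_down": 8, "CD_spec": 8, "UC_spec": 7}
# planted enhancer pattern counts (pattern 2 split into up/down)
DEFAULT_ENH_PATTERNS = {
    "pattern2_up": 20,
    "pattern2_down": 10,
    "pattern3": 10,
    "pattern4": 10,
    "pattern5": 5,
}


@dataclass
class EnhancerTruth:
    enh_id: str
    chrom: str
    midpoint: int
    minus_summit: int
    plus_summit: int
    cluster_id: str | None = None


@dataclass
class SimulationTruth:
    seed: int
    genome_size: int
    chrom: str
    genes: list[GeneModel] = field(default_factory=list)
    transcripts: list[dict] = field(default_factory=list)
    enhancers: list[EnhancerTruth] = field(default_factory=list)
    clusters: dict[str, list[str]] = field(default_factory=dict)
    gene_labels: pd.Series | None = None  # DE set per gene
    enh_labels: pd.Series | None = None  # pattern label per enhancer
    links: list[tuple[str, str]] = field(default_factory=list)
    sample_table: pd.DataFrame | None = None
    gene_counts: pd.DataFrame | None = None  # true per-gene totals
    enh_counts: pd.DataFrame | None = None  # true per-enhancer totals


# ---------------------------------------------------------------------------
# Regulome layout


def simulate_regulome(
    n_genes: int = 300,
    n_enhancers: int = 200,
    genome_size: int = 10_000_000,
    cluster_fraction: float = 0.3,
    chrom: str = "chr1",
    seed: int = 0,
) -> SimulationTruth:
    """Lay out genes and enhancers on a toy chromosome.

    Genes do not overlap and carry 1-3 transcript TSSs; enhancers are
    intergenic, at least 1 kb from the promoter/exon exclusion mask, and
    ``cluster_fraction`` of them form chains of 3-10 members with
    consecutive midpoints within 15 kb.
    """
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, genome_size=genome_size, chrom=chrom)

    n_clustered = int(round(cluster_fraction * n_enhancers))
    cluster_sizes: list[int] = []
    while sum(cluster_sizes) < n_clustered:
        cluster_sizes.append(int(rng.integers(3, 11)))
    n_singletons = n_enhancers - sum(cluster_sizes)
    if n_singletons < 0:
        cluster_sizes.pop()
        n_singletons = n_enhancers - sum(cluster_sizes)

    # blocks: ("gene", idx) / ("cluster", size) / ("enh", idx); shuffled layout
    blocks: list[tuple[str, int]] = (
        [("gene", i) for i in range(n_genes)]
        + [("cluster", s) for s in cluster_sizes]
        + [("enh", 0) for _ in range(n_singletons)]
    )
    rng.shuffle(blocks)

    cursor = 5_000
    gene_n = enh_n = clus_n = 0
    for kind, arg in blocks:
        cursor += int(rng.integers(2_000, 6_000))  # inter-block spacer
        if kind == "gene":
            cursor, model, tx = _place_gene(rng, chrom, cursor, gene_n)
            truth.genes.append(model)
            truth.transcripts.extend(tx)
            gene_n += 1
        elif kind == "enh":
            cursor, enh = _place_enhancer(rng, chrom, cursor, enh_n)
            truth.enhancers.append(enh)
            enh_n += 1
            cursor += 16_000  # keep singletons out of chaining range
        else:  # cluster of `arg` enhancers with midpoint gaps <= 15 kb
            cid = f"truth_ec_{clus_n}"
            members = []
            for k in range(arg):
                cursor, enh = _place_enhancer(rng, chrom, cursor, enh_n)
                enh.cluster_id = cid
                truth.enhancers.append(enh)
                members.append(enh.enh_id)
                enh_n += 1
                if k < arg - 1:
                    cursor += int(rng.integers(2_000, 12_000))
            truth.clusters[cid] = members
            clus_n += 1
            cursor += 16_000
        if cursor > genome_size - 10_000:
            raise ValueError(
                f"genome of {genome_size} bp too small for "
                f"{n_genes} genes + {n_enhancers} enhancers"
            )
    return truth


def _place_gene(rng, chrom, cursor, idx):
    strand = "+" if rng.random() < 0.5 else "-"
    length = int(rng.integers(2_000, 8_000))
    start = cursor  # 1-based
    end = start + length
    n_tx = int(rng.integers(1, 4))
    gene_id = f"g{idx:04d}"
    if strand == "+":
        tss = sorted({start} | {start + int(rng.integers(200, length - 400)) for _ in range(n_tx - 1)})
    else:
        tss = sorted({end} | {end - int(rng.integers(200, length - 400)) for _ in range(n_tx - 1)})
    transcripts = []
    exons: list[GenomicInterval] = []
    for t_i, t in enumerate(tss):
        if strand == "+":
            ex1 = (t, min(t + 200, end))
            ex2 = (max(end - 300, ex1[1] + 50), end)
            tx_span = (t, end)
        else:
            ex1 = (max(t - 200, start), t)
            ex2 = (start, min(start + 300, ex1[0] - 50))
            ex2 = (ex2[0], max(ex2[1], ex2[0] + 50))
            tx_span = (start, t)
        tx_exons = sorted({ex1, ex2})
        transcripts.append(
            {
                "gene_id": gene_id,
                "transcript_id": f"{gene_id}.t{t_i}",
                "chrom": chrom,
                "strand": strand,
                "start": tx_span[0],
                "end": tx_span[1],
                "exons": tx_exons,
            }
        )
        exons.extend(GenomicInterval(chrom, s - 1, e, strand) for s, e in tx_exons)
    upstream = min(tss) if strand == "+" else max(tss)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcript_tss=sorted(set(tss)),
        upstream_tss=upstream,
        exons=exons,
        span=GenomicInterval(chrom, start - 1, end, strand),
    )
    return end + 1_000, model, transcripts  # >=1 kb clearance past the gene


def _place_enhancer(rng, chrom, cursor, idx):
    cursor += 1_000  # >=1 kb clearance from whatever precedes
    gap = int(rng.integers(100, 301))
    midpoint = cursor + gap  # arbitrary anchor
    minus_summit = midpoint - gap // 2
    plus_summit = midpoint + (gap - gap // 2)
    enh = EnhancerTruth(
        enh_id=f"e{idx:04d}",
        chrom=chrom,
        midpoint=midpoint,
        minus_summit=minus_summit,
        plus_summit=plus_summit,
    )
    return plus_summit + 30, enh


def write_gtf(truth: SimulationTruth, path: str) -> None:
    """Write the simulated gene models as a GENCODE-style GTF."""
    with open(path, "w") as fh:
        by_gene: dict[str, list[dict]] = {}
        for tx in truth.transcripts:
            by_gene.setdefault(tx["gene_id"], []).append(tx)
        for gene in truth.genes:
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{gene.span.start + 1}\t{gene.span.end}\t."
                f"\t{gene.strand}\t.\t{attrs}\n"
            )
            for tx in by_gene[gene.gene_id]:
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx["transcript_id"]}";'
                fh.write(
                    f"{tx['chrom']}\tsim\ttranscript\t{tx['start']}\t{tx['end']}\t."
                    f"\t{tx['strand']}\t.\t{tattrs}\n"
                )
                for s, e in tx["exons"]:
                    fh.write(
                        f"{tx['chrom']}\tsim\texon\t{s}\t{e}\t."
                        f"\t{tx['strand']}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# CTSS profiles

# tag-placement shapes: offset -> probability
_PROMOTER_SHAPE = {
    0: 0.55, 1: 0.08, -1: 0.08, 2: 0.05, -2: 0.05, 3: 0.03, -3: 0.03,
    4: 0.015, -4: 0.015, 5: 0.01, -5: 0.01,
}
_PROMOTER_TAIL = [o for o in range(-20, 21) if abs(o) > 5]
_ARM_SHAPE = {0: 0.7, 1: 0.1, -1: 0.1, 2: 0.05, -2: 0.05}


def _shape_arrays(shape: dict[int, float], tail: list[int] | None):
    offsets = list(shape)
    probs = list(shape.values())
    if tail:
        rest = 1.0 - sum(probs)
        offsets += tail
        probs += [rest / len(tail)] * len(tail)
    else:
        probs = [p / sum(probs) for p in probs]
    return np.array(offsets), np.array(probs)


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson NB with mean/dispersion parameterization."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _group_lfc(label: str, group: str, de_lfc: float) -> float:
    active = {"CDa": 1.0, "UCa": 1.0, "CDi": 0.3, "UCi": 0.3}
    if label == "IBD_up" or label == "pattern2_up":
        return de_lfc * active.get(group, 0.0)
    if label == "IBD_down" or label == "pattern2_down":
        return -de_lfc * active.get(group, 0.0)
    if label == "CD_spec" or label == "pattern4":
        return de_lfc if group == "CDa" else (0.3 * de_lfc if group == "CDi" else 0.0)
    if label == "UC_spec" or label == "pattern3":
        return de_lfc if group == "UCa" else (0.3 * de_lfc if group == "UCi" else 0.0)
    if label == "pattern5":
        return {"CDa": de_lfc, "UCa": -de_lfc}.get(group, 0.0)
    return 0.0


def simulate_ctss(
    truth: SimulationTruth,
    groups: dict[str, int] | None = None,
    batches: int = 2,
    nb_dispersion: float = 0.2,
    de_lfc: float = 2.0,
    link_rho: float = 0.8,
    link_fraction: float = 0.5,
    batch_sd: float = 0.25,
    gene_de: dict[str, int] | None = None,
    enh_patterns: dict[str, int] | None = None,
    base_gene_mean: float = 60.0,
    base_enh_mean: float = 12.0,
    seed: int = 0,
) -> list[CtssProfile]:
    """Simulate per-sample CTSS profiles over the planted regulome.

    Promoters produce a sharp unidirectional peak on the gene strand
    (~90% of tags within 5 bp of the summit); enhancers split their tags
    roughly 50/50 across the two divergent arms (|D| small in
    expectation).  DE features get group-dependent means (planted log2
    fold change ``de_lfc``); linked (gene, enhancer) pairs share a
    latent per-sample activity giving co-expression ~``link_rho``;
    batches act multiplicatively per feature.  Fills the truth object
    (labels, links, sample table, true count matrices) and returns the
    profiles.
    """
    rng = np.random.default_rng(seed)
    groups = dict(groups or DEFAULT_GROUPS)
    gene_de = dict(gene_de if gene_de is not None else DEFAULT_GENE_DE)
    enh_patterns = dict(
        enh_patterns if enh_patterns is not None else DEFAULT_ENH_PATTERNS
    )

    sample_ids, group_col = [], []
    for g, n in groups.items():
        for k in range(n):
            sample_ids.append(f"{g}_{k:02d}")
            group_col.append(g)
    n_samples = len(sample_ids)
    batch_col = [f"b{(i % batches) + 1}" for i in range(n_samples)]
    truth.sample_table = pd.DataFrame(
        {
            "group": group_col,
            "batch": batch_col,
            "cohort": [1 if b == "b1" else 2 for b in batch_col],
            "hospital": ["H1" if b == "b1" else "H2" for b in batch_col],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    gene_ids = [g.gene_id for g in truth.genes]
    enh_ids = [e.enh_id for e in truth.enhancers]
    truth.gene_labels = _assign_labels(rng, gene_ids, gene_de)
    truth.enh_labels = _assign_labels(rng, enh_ids, enh_patterns)

    # links: a fraction of enhancers tied to the nearest gene TSS in range
    truth.links = []
    link_of_enh: dict[str, str] = {}
    gene_pos = {g.gene_id: g.upstream_tss for g in truth.genes}
    for enh in truth.enhancers:
        if rng.random() > link_fraction:
            continue
        dists = {
            gid: abs(pos - enh.midpoint)
            for gid, pos in gene_pos.items()
            if abs(pos - enh.midpoint) <= 500_000
        }
        if not dists:
            continue
        target = min(dists, key=dists.get)
        truth.links.append((target, enh.enh_id))
        link_of_enh[enh.enh_id] = target

    # latent activities: one shared N(0,1) per link per sample
    lam = 1.5 * link_rho  # log2-sd of the shared activity
    latent = {pair: rng.normal(0.0, 1.0, n_samples) for pair in truth.links}
    gene_latent = {gid: np.zeros(n_samples) for gid in gene_ids}
    enh_latent = {eid: np.zeros(n_samples) for eid in enh_ids}
    for (gid, eid), u in latent.items():
        gene_latent[gid] = gene_latent[gid] + lam * u
        enh_latent[eid] = enh_latent[eid] + lam * u

    batch_idx = np.array([int(b[1:]) - 1 for b in batch_col])
    group_arr = np.array(group_col)

    entries: list[dict[tuple[str, int, str], int]] = [dict() for _ in range(n_samples)]
    prom_off, prom_p = _shape_arrays(_PROMOTER_SHAPE, _PROMOTER_TAIL)
    arm_off, arm_p = _shape_arrays(_ARM_SHAPE, None)

    gene_counts = np.zeros((len(gene_ids), n_samples), dtype=np.int64)
    for gi, gene in enumerate(truth.genes):
        label = truth.gene_labels[gene.gene_id]
        lfc = np.array([_group_lfc(label, g, de_lfc) for g in group_arr])
        b_off = rng.normal(0.0, batch_sd, batches)[batch_idx] if batch_sd > 0 else 0.0
        mu = base_gene_mean * np.exp2(lfc + b_off + gene_latent[gene.gene_id])
        totals = _nb_draw(rng, mu, nb_dispersion)
        gene_counts[gi] = totals
        _scatter_tags(
            rng, entries, totals, gene.chrom, gene.upstream_tss, gene.strand,
            prom_off, prom_p,
        )
    enh_counts = np.zeros((len(enh_ids), n_samples), dtype=np.int64)
    for ei, enh in enumerate(truth.enhancers):
        label = truth.enh_labels[enh.enh_id]
        lfc = np.array([_group_lfc(label, g, de_lfc) for g in group_arr])
        b_off = rng.normal(0.0, batch_sd, batches)[batch_idx] if batch_sd > 0 else 0.0
        mu = base_enh_mean * np.exp2(lfc + b_off + enh_latent[enh.enh_id])
        totals = _nb_draw(rng, mu, nb_dispersion)
        enh_counts[ei] = totals
        plus_share = rng.binomial(totals, 0.5)
        _scatter_tags(
            rng, entries, totals - plus_share, enh.chrom, enh.minus_summit, "-",
            arm_off, arm_p,
        )
        _scatter_tags(
            rng, entries, plus_share, enh.chrom, enh.plus_summit, "+",
            arm_off, arm_p,
        )

    truth.gene_counts = pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids)
    truth.enh_counts = pd.DataFrame(enh_counts, index=enh_ids, columns=sample_ids)
    return [
        CtssProfile(sample_id=sid, entries=ent)
        for sid, ent in zip(sample_ids, entries)
    ]


def _assign_labels(rng, ids: list[str], counts: dict[str, int]) -> pd.Series:
    total = sum(counts.values())
    if total > len(ids):
        raise ValueError(f"cannot plant {total} labels on {len(ids)} features")
    labels = pd.Series("none", index=ids, dtype=object)
    chosen = rng.choice(len(ids), size=total, replace=False)
    pos = 0
    for label, k in counts.items():
        for i in chosen[pos : pos + k]:
            labels.iloc[i] = label
        pos += k
    return labels


def _scatter_tags(rng, entries, totals, chrom, summit, strand, offsets, probs):
    for si, total in enumerate(totals):
        if total == 0:
            continue
        placed = rng.multinomial(int(total), probs)
        ent = entries[si]
        for off, cnt in zip(offsets, placed):
            if cnt == 0:
                continue
            pos = max(int(summit) + int(off), 1)
            key = (chrom, pos, strand)
            ent[key] = ent.get(key, 0) + int(cnt)


# ---------------------------------------------------------------------------
# GWAS panel


def simulate_gwas_panel(
    truth: SimulationTruth,
    n_snps: int = 5000,
    n_traits: int = 10,
    snps_per_trait: int = 1000,
    enriched_trait: str = "IBD_like",
    density_ratio: float = 5.0,
    ld_block: int = 20_000,
    ld_span: int = 1_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP panel with block LD; one trait enriched in upregulated regions.

    The panel mixes uniform SNPs with guaranteed coverage of the planted
    upregulated promoter/enhancer regions (3 SNPs per region, so the
    enrichment signal exists at desk scale).  LD: within blocks of
    ``ld_block`` bp, pairs closer than ``ld_span`` get R^2 decaying with
    distance (no partner beyond the block).  Trait SNPs are drawn from
    the panel; the enriched trait samples in-region SNPs with
    ``density_ratio``-fold weight.
    """
    rng = np.random.default_rng(seed)
    chrom = truth.chrom
    up_regions = upregulated_regions(truth)

    positions = sorted(
        set(rng.integers(1, truth.genome_size, size=n_snps).tolist())
    )
    for lo, hi in up_regions:
        for p in rng.integers(lo, hi + 1, size=3):
            positions.append(int(p))
    positions = sorted(set(positions))
    panel = pd.DataFrame(
        {
            "rsid": [f"rs{i:06d}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        }
    )
    in_region = np.zeros(len(panel), dtype=bool)
    region_arr = np.array(up_regions) if up_regions else np.empty((0, 2), dtype=int)
    for i, p in enumerate(positions):
        if len(region_arr) and (
            (region_arr[:, 0] <= p) & (p <= region_arr[:, 1])
        ).any():
            in_region[i] = True

    # LD pairs within blocks
    rows = []
    pos_arr = panel["pos"].to_numpy()
    block_of = pos_arr // ld_block
    for i in range(len(panel)):
        j = i + 1
        while j < len(panel) and block_of[j] == block_of[i]:
            dist = pos_arr[j] - pos_arr[i]
            if dist <= ld_span:
                r2 = float(np.clip(np.exp(-dist / (0.4 * ld_span)) + rng.normal(0, 0.05), 0, 1))
                if r2 > 0.4:
                    rows.append(
                        (chrom, int(pos_arr[i]), panel["rsid"].iloc[i],
                         chrom, int(pos_arr[j]), panel["rsid"].iloc[j], r2)
                    )
            j += 1
    ld = pd.DataFrame(
        rows, columns=["chrom_a", "pos_a", "snp_a", "chrom_b", "pos_b", "snp_b", "r2"]
    )

    trait_rows = []
    names = [enriched_trait] + [f"trait_{k}" for k in range(1, n_traits)]
    weights_uniform = np.ones(len(panel))
    weights_enriched = np.where(in_region, density_ratio, 1.0)
    for name in names:
        w = weights_enriched if name == enriched_trait else weights_uniform
        p = w / w.sum()
        take = rng.choice(len(panel), size=min(snps_per_trait, len(panel)),
                         replace=False, p=p)
        for i in take:
            trait_rows.append(
                (name, chrom, int(pos_arr[i]), panel["rsid"].iloc[i])
            )
    gwas_snps = pd.DataFrame(trait_rows, columns=["trait", "chrom", "pos", "rsid"])
    return gwas_snps, ld


def upregulated_regions(truth: SimulationTruth) -> list[tuple[int, int]]:
    """Planted upregulated promoter (-500/+100) and enhancer (+/-300)
    regions, 1-based inclusive."""
    regions = []
    up_genes = set(truth.gene_labels[truth.gene_labels == "IBD_up"].index)
    for gene in truth.genes:
        if gene.gene_id in up_genes:
            t = gene.upstream_tss
            if gene.strand == "+":
                regions.append((max(t - 500, 1), t + 100))
            else:
                regions.append((max(t - 100, 1), t + 500))
    up_enh = set(truth.enh_labels[truth.enh_labels == "pattern2_up"].index)
    for enh in truth.enhancers:
        if enh.enh_id in up_enh:
            regions.append((max(enh.midpoint - 300, 1), enh.midpoint + 300))
    return sorted(regions)


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    truth: SimulationTruth,
    noise_sd: float = 0.5,
    missing_rate: float = 0.02,
    n_organoid_reps: int = 6,
    n_monocyte_reps: int = 6,
    organoid_up_frac: float = 0.6,
    monocyte_up_frac: float = 0.5,
    response_lfc: float = 2.0,
    cohort_offset: float = 1.0,
    seed: int = 0,
) -> dict:
    """dCq matrices for biopsy, organoid and monocyte panels.

    Primers are the planted DE genes.  Biopsy dCq derives from the
    simulated gene expression (dCq = -log2 normalized expression +
    noise + cohort offset); organoid/monocyte panels carry unstimulated
    (0 h) and TNF-stimulated (4 h / 24 h) replicates whose planted
    up/down responses overlap the biopsy IBD-up labels with configurable
    fractions.  Returns matrices, labels and the planted Venn counts.
    """
    if truth.gene_counts is None:
        raise ValueError("run simulate_ctss first")
    rng = np.random.default_rng(seed)
    labels = truth.gene_labels
    primers = labels.index[labels != "none"].tolist()
    st = truth.sample_table
    biopsy_samples = st.index[st["group"].isin(["CDa", "UCa", "Ctrl"])].tolist()

    cpm = truth.gene_counts / truth.gene_counts.sum(axis=0) * 1e6
    biopsy = -np.log2(cpm.loc[primers, biopsy_samples] + 1.0)
    cohorts = st.loc[biopsy_samples, "cohort"]
    biopsy = biopsy + noise_sd * rng.normal(size=biopsy.shape)
    biopsy = biopsy.add(cohort_offset * (cohorts == 2).astype(float), axis=1)

    # a primer counts as IBD-up when its planted response is positive in
    # CDa or UCa — CD_spec/UC_spec primers qualify through their one group
    ibd_up = labels.loc[primers].isin(["IBD_up", "CD_spec", "UC_spec"]).to_numpy()
    organoid_up = _overlapping_up(rng, ibd_up, organoid_up_frac)
    monocyte_up = _overlapping_up(rng, ibd_up, monocyte_up_frac)

    organoid = _stim_panel(rng, primers, organoid_up, n_organoid_reps,
                           response_lfc, noise_sd, "org")
    monocyte = _stim_panel(rng, primers, monocyte_up, n_monocyte_reps,
                           response_lfc, noise_sd, "mono")

    for mat in (biopsy, organoid, monocyte):
        if missing_rate > 0:
            mask = rng.random(mat.shape) < missing_rate
            mat.values[mask] = np.nan

    venn_truth = {
        "ibd_up": int(ibd_up.sum()),
        "ibd_up_and_organoid_up": int((ibd_up & organoid_up).sum()),
        "ibd_up_and_monocyte_up": int((ibd_up & monocyte_up).sum()),
        "triple": int((ibd_up & organoid_up & monocyte_up).sum()),
    }
    times = ["0h"] * n_organoid_reps + ["4h"] * n_organoid_reps + ["24h"] * n_organoid_reps
    mtimes = ["0h"] * n_monocyte_reps + ["4h"] * n_monocyte_reps + ["24h"] * n_monocyte_reps
    return {
        "biopsy": biopsy,
        "organoid": organoid,
        "monocyte": monocyte,
        "biopsy_groups": st.loc[biopsy_samples, "group"],
        "organoid_times": pd.Series(times, index=organoid.columns),
        "monocyte_times": pd.Series(mtimes, index=monocyte.columns),
        "venn_truth": venn_truth,
        "biopsy_up": pd.Series(ibd_up, index=primers),
        "organoid_up": pd.Series(organoid_up, index=primers),
        "monocyte_up": pd.Series(monocyte_up, index=primers),
    }


def _overlapping_up(rng, ibd_up: np.ndarray, frac: float) -> np.ndarray:
    """Up-responder mask overlapping the IBD-up set at ~frac, with the
    complement sampled at background rate 0.3."""
    out = np.zeros(len(ibd_up), dtype=bool)
    out[ibd_up] = rng.random(int(ibd_up.sum())) < frac
    out[~ibd_up] = rng.random(int((~ibd_up).sum())) < 0.3
    return out


def _stim_panel(rng, primers, up_mask, n_reps, lfc, noise_sd, prefix):
    cols = (
        [f"{prefix}_0h_{k}" for k in range(n_reps)]
        + [f"{prefix}_4h_{k}" for k in range(n_reps)]
        + [f"{prefix}_24h_{k}" for k in range(n_reps)]
    )
    base = rng.uniform(6.0, 12.0, size=len(primers))
    dcq = np.tile(base[:, None], (1, len(cols))).astype(float)
    # TNF response: up-responders drop dCq (higher expression), others rise
    shift = np.where(up_mask, -lfc, lfc)
    dcq[:, n_reps:] += shift[:, None]
    dcq += noise_sd * rng.normal(size=dcq.shape)
    return pd.DataFrame(dcq, index=primers, columns=cols)


# ---------------------------------------------------------------------------
# Pattern-labelled enhancer counts (for the EB pattern model)


def simulate_pattern_counts(
    n_per_pattern: int = 2000,
    n_per_group: int = 20,
    base_mean: float = 20.0,
    fold: float = 4.0,
    dispersion: float = 0.1,
    pattern_counts: dict[int, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """NB count matrices drawn from each of the five condition patterns.

    Block multipliers: the first equal-mean block sits at ``base_mean``;
    the second shifts by ``fold`` up or down and the third block of
    pattern 5 continues in the same direction (``fold`` squared), a
    graded-severity profile keeping all three conditions distinct.
    ``pattern_counts`` overrides the per-pattern allocation (a realistic
    enhancer set is dominated by pattern 1).  Returns (counts, groups,
    true pattern).
    """
    from .patterns import CONDITIONS, PATTERNS

    rng = np.random.default_rng(seed)
    samples = [f"{g}_{i:02d}" for g in CONDITIONS for i in range(n_per_group)]
    groups = pd.Series(
        [g for g in CONDITIONS for _ in range(n_per_group)], index=samples
    )
    allocation = pattern_counts or {k: n_per_pattern for k in PATTERNS}
    rows, truth = [], []
    for k, blocks in PATTERNS.items():
        for _ in range(allocation.get(k, 0)):
            direction = fold if rng.random() < 0.5 else 1.0 / fold
            mult = {}
            for b_i, blk in enumerate(blocks):
                m = 1.0 if b_i == 0 else direction**b_i
                for c in blk:
                    mult[c] = m
            mu = np.array([base_mean * mult[g] for g in groups])
            rows.append(_nb_draw(rng, mu, dispersion))
            truth.append(k)
    counts = pd.DataFrame(
        np.array(rows), columns=samples,
        index=[f"pe{i:05d}" for i in range(len(rows))],
    )
    return counts, groups, pd.Series(truth, index=counts.index, name="true_pattern")


# ---------------------------------------------------------------------------
# One-call cohort


@dataclass
class SyntheticCohort:
    truth: SimulationTruth
    profiles: list[CtssProfile]
    sample_table: pd.DataFrame
    gene_counts: pd.DataFrame
    enh_counts: pd.DataFrame


def simulate_cohort(seed: int = 0, regulome_kw: dict | None = None,
                    ctss_kw: dict | None = None) -> SyntheticCohort:
    """Generate the default study cohort (regulome + CTSS profiles)."""
    truth = simulate_regulome(seed=seed, **(regulome_kw or {}))
    profiles = simulate_ctss(truth, seed=seed + 1, **(ctss_kw or {}))
    return SyntheticCohort(
        truth=truth,
        profiles=profiles,
        sample_table=truth.sample_table,
        gene_counts=truth.gene_counts,
        enh_counts=truth.enh_counts,
    )
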