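"""GWAS LD-clump construction and enrichment in regulatory regions.

GWAS SNPs are expanded with their LD partners (R^2 > 0.75 within
500 kb) into spans; overlapping spans merge transitively into clumps.
Per trait, the fraction of clumps touching promoter (-500/+100 bp
around TC summits, strand-aware) or enhancer (+/-300 bp around
midpoints) regions is stabilized by empirical-Bayes shrinkage under a
beta-binomial model fitted across traits; enrichment of the
differentially expressed subset of regions is a one-sided
hypergeometric test with BH correction across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval


@dataclass
class LdClump:
    trait: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    gwas_snps: list[str]
    proxy_snps: list[str]

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start - 1, self.end, ".")


def read_plink_ld(path: str) -> pd.DataFrame:
    """Read a whitespace-delimited PLINK .ld table.

    Needs columns CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2 (case-insensitive).
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    required = {"CHR_A", "BP_A", "SNP_A", "CHR_B", "BP_B", "SNP_B", "R2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing LD columns {sorted(missing)}")
    return df.rename(
        columns={
            "CHR_A": "chrom_a", "BP_A": "pos_a", "SNP_A": "snp_a",
            "CHR_B": "chrom_b", "BP_B": "pos_b", "SNP_B": "snp_b", "R2": "r2",
        }
    )


def ld_from_dosages(dosages: pd.DataFrame, positions: pd.Series, chrom: pd.Series,
                    window: int = 500_000) -> pd.DataFrame:
    """Pairwise R^2 as squared Pearson correlation of allele dosages.

    ``dosages`` is SNP-by-individual (0/1/2).  Only same-chromosome pairs
    within ``window`` bp are reported.
    """
    rows = []
    ids = dosages.index.to_list()
    x = dosages.to_numpy(dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if chrom.iloc[i] != chrom.iloc[j]:
                continue
            if abs(int(positions.iloc[i]) - int(positions.iloc[j])) > window:
                continue
            sx, sy = x[i].std(), x[j].std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x[i], x[j])[0, 1]
            rows.append(
                (chrom.iloc[i], int(positions.iloc[i]), ids[i],
                 chrom.iloc[j], int(positions.iloc[j]), ids[j], float(r**2))
            )
    return pd.DataFrame(
        rows, columns=["chrom_a", "pos_a", "snp_a", "chrom_b", "pos_b", "snp_b", "r2"]
    )


def build_ld_clumps(
    gwas_snps: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_threshold: float = 0.75,
    window: int = 500_000,
) -> dict[str, list[LdClump]]:
    """Expand each GWAS SNP with its LD partners; merge overlapping spans.

    ``gwas_snps`` needs columns (trait, chrom, pos, rsid).  Partnership
    requires R^2 strictly above the threshold and distance within the
    window.  A GWAS SNP absent from the LD panel becomes its own 1-bp
    clump with a warning.
    """
    partners: dict[str, list[tuple[str, int, str]]] = {}
    panel_snps: set[str] = set()
    for _, row in ld_pairs.iterrows():
        panel_snps.add(row["snp_a"])
        panel_snps.add(row["snp_b"])
        if row["r2"] <= r2_threshold:
            continue
        if row["chrom_a"] != row["chrom_b"]:
            continue
        if abs(int(row["pos_a"]) - int(row["pos_b"])) > window:
            continue
        partners.setdefault(row["snp_a"], []).append(
            (row["chrom_b"], int(row["pos_b"]), row["snp_b"])
        )
        partners.setdefault(row["snp_b"], []).append(
            (row["chrom_a"], int(row["pos_a"]), row["snp_a"])
        )
    out: dict[str, list[LdClump]] = {}
    n_missing = 0
    for trait, sub in gwas_snps.groupby("trait"):
        spans: list[tuple[str, int, int, str, list[str]]] = []
        for _, snp in sub.iterrows():
            rsid, chrom, pos = snp["rsid"], snp["chrom"], int(snp["pos"])
            if rsid not in panel_snps and rsid not in partners:
                n_missing += 1
            mates = [m for m in partners.get(rsid, []) if m[0] == chrom]
            lo = min([pos] + [p for _, p, _ in mates])
            hi = max([pos] + [p for _, p, _ in mates])
            spans.append((chrom, lo, hi, rsid, [m[2] for m in mates]))
        spans.sort()
        clumps: list[LdClump] = []
        for chrom, lo, hi, rsid, proxies in spans:
            if clumps and clumps[-1].chrom == chrom and lo <= clumps[-1].end:
                c = clumps[-1]
                c.end = max(c.end, hi)
                c.gwas_snps.append(rsid)
                c.proxy_snps.extend(proxies)
            else:
                clumps.append(LdClump(str(trait), chrom, lo, hi, [rsid], list(proxies)))
        for c in clumps:
            c.proxy_snps = sorted(set(c.proxy_snps))
        out[str(trait)] = clumps
    if n_missing:
        warnings.warn(
            f"{n_missing} GWAS SNPs absent from the LD panel became own-position clumps"
        )
    return out


# ---------------------------------------------------------------------------
# Region builders


def promoter_regions(clusters) -> list[GenomicInterval]:
    """-500/+100 bp around TC summits, strand-aware (1-based arithmetic)."""
    out = []
    for tc in clusters:
        if tc.strand == "+":
            lo, hi = tc.summit - 500, tc.summit + 100
        else:
            lo, hi = tc.summit - 100, tc.summit + 500
        out.append(GenomicInterval(tc.chrom, max(lo - 1, 0), hi, tc.strand))
    return out


def enhancer_regions(enhancers, pad: int = 300) -> list[GenomicInterval]:
    """+/-pad bp around enhancer midpoints."""
    return [
        GenomicInterval(e.chrom, max(e.midpoint - pad - 1, 0), e.midpoint + pad, ".")
        for e in enhancers
    ]


def _clump_overlaps_any(clump: LdClump, spans: list[tuple[int, int]]) -> bool:
    import bisect

    i = bisect.bisect_right(spans, (clump.end, np.iinfo(np.int64).max))
    for s, e in reversed(spans[:i]):
        if e >= clump.start:
            return True
        if clump.start - s > 10_000_000:
            break
    return False


def _spans_by_chrom(regions: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by.setdefault(r.chrom, []).append((r.start + 1, r.end))  # to 1-based inclusive
    for v in by.values():
        v.sort()
    return by


def clump_overlap_fractions(
    clumps_by_trait: dict[str, list[LdClump]], regions: list[GenomicInterval]
) -> pd.DataFrame:
    """Per trait: x = clumps overlapping >=1 region by >=1 bp, n = clumps."""
    spans = _spans_by_chrom(regions)
    rows = []
    for trait, clumps in clumps_by_trait.items():
        if not clumps:
            raise ValueError(f"trait {trait} has zero clumps")
        x = sum(
            _clump_overlaps_any(c, spans.get(c.chrom, [])) for c in clumps
        )
        rows.append((trait, int(x), len(clumps)))
    df = pd.DataFrame(rows, columns=["trait", "x", "n"]).set_index("trait")
    df["raw"] = df["x"] / df["n"]
    return df


# ---------------------------------------------------------------------------
# Beta-binomial shrinkage


@dataclass
class BetaBinomialShrinkageResults:
    alpha: float
    beta: float
    table: pd.DataFrame  # x, n, raw, shrunken

    @property
    def prior_mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def summary(self) -> str:
        return (
            "Beta-binomial EB shrinkage\n"
            f"  traits     : {len(self.table)}\n"
            f"  Beta prior : alpha={self.alpha:.4g}, beta={self.beta:.4g} "
            f"(mean {self.prior_mean:.4f})\n"
            + self.table[["x", "n", "raw", "shrunken"]].round(4).to_string()
        )


class BetaBinomialShrinkage:
    """ML beta-binomial prior across traits; posterior-mean shrinkage.

    The prior Beta(alpha, beta) is fitted by maximum likelihood to the
    (x, n) pairs (method-of-moments initialization); each trait's
    fraction shrinks to (x + alpha) / (n + alpha + beta).
    """

    def __init__(self, fractions: pd.DataFrame) -> None:
        if len(fractions) < 3:
            raise ValueError("need at least 3 traits to fit a prior")
        self.fractions = fractions[["x", "n"]].astype(int)

    @staticmethod
    def _nll(log_ab: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
        a, b = np.exp(log_ab)
        ll = (
            gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
            + betaln(x + a, n - x + b) - betaln(a, b)
        )
        return -float(ll.sum())

    def fit(self) -> BetaBinomialShrinkageResults:
        x = self.fractions["x"].to_numpy(dtype=float)
        n = self.fractions["n"].to_numpy(dtype=float)
        p = x / n
        m, v = p.mean(), p.var(ddof=1)
        if v <= 1e-12 or not (0 < m < 1):
            warnings.warn("degenerate fractions; returning raw proportions")
            table = self.fractions.copy()
            table["raw"] = p
            table["shrunken"] = p
            return BetaBinomialShrinkageResults(np.nan, np.nan, table)
        # method-of-moments start
        common = m * (1 - m) / v - 1
        a0, b0 = max(m * common, 0.1), max((1 - m) * common, 0.1)
        res = optimize.minimize(
            self._nll, np.log([a0, b0]), args=(x, n), method="Nelder-Mead"
        )
        a, b = np.exp(res.x)
        table = self.fractions.copy()
        table["raw"] = p
        table["shrunken"] = (x + a) / (n + a + b)
        return BetaBinomialShrinkageResults(float(a), float(b), table)


def eb_shrink_fractions(fractions: pd.DataFrame) -> BetaBinomialShrinkageResults:
    """Functional wrapper over :class:`BetaBinomialShrinkage`."""
    return BetaBinomialShrinkage(fractions).fit()


# ---------------------------------------------------------------------------
# Clump enrichment


def clump_enrichment_test(
    de_ids: set[str],
    universe_ids: set[str],
    overlap_ids_by_trait: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of DE regions in trait clumps.

    ``overlap_ids_by_trait`` maps each trait to the universe region ids
    overlapping its clumps.  Upper-tail p of |DE regions among the
    overlappers| given the universe; BH across traits.
    """
    if not de_ids <= universe_ids:
        raise ValueError("DE set must be a subset of the universe")
    big_n = len(universe_ids)
    n_de = len(de_ids)
    rows = []
    for trait, overlap in overlap_ids_by_trait.items():
        overlap = overlap & universe_ids
        k = len(overlap & de_ids)
        big_k = len(overlap)
        if n_de == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_de))
        rows.append((trait, k, big_k, p))
    table = pd.DataFrame(
        rows, columns=["trait", "de_overlap", "universe_overlap", "p"]
    ).set_index("trait")
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def regions_overlapping_clumps(
    region_ids: list[str],
    regions: list[GenomicInterval],
    clumps: list[LdClump],
) -> set[str]:
    """Ids of regions overlapping any clump of one trait by >=1 bp."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for c in clumps:
        spans.setdefault(c.chrom, []).append((c.start, c.end))
    for v in spans.values():
        v.sort()
    hit: set[str] = set()
    import bisect

    for rid, r in zip(region_ids, regions):
        chrom_spans = spans.get(r.chrom)
        if not chrom_spans:
            continue
        lo, hi = r.start + 1, r.end  # 1-based inclusive
        i = bisect.bisect_right(chrom_spans, (hi, np.iinfo(np.int64).max))
        for s, e in reversed(chrom_spans[:i]):
            if e >= lo:
                hit.add(rid)
                break
    return hit
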