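"""Enhancer-TSS linkage by co-expression across samples.

Counts are RLE-normalized (median-of-ratios size factors) and log2
transformed with a pseudocount of 0.25; every (TSS, enhancer) pair whose
TC summit and enhancer midpoint lie within +/-500 kb is tested for
Pearson correlation, p-values are BH-corrected over all tested pairs and
a link is kept when the correlation is positive at FDR < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (relative log expression).

    The reference is the per-feature geometric mean across samples;
    features with a zero anywhere are excluded from the reference.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with all-positive counts; cannot form reference")
    logx = np.log(x[positive])
    log_ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rle_log_normalize(counts: pd.DataFrame, pseudocount: float = 0.25) -> pd.DataFrame:
    """RLE-normalized log2 counts-per-million with a 0.25 pseudocount.

    Per-sample normalization factors are the median-of-ratios size
    factors divided by library size and rescaled to geometric mean 1
    (depth-invariant, as in edgeR's RLE norm factors); values are
    log2(count / effective library size * 1e6 + 0.25).  Scaling all
    counts of one sample leaves every normalized value unchanged.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"all-zero samples: {lib.index[lib == 0].tolist()}")
    g = rle_size_factors(counts) / lib
    g = g / np.exp(np.log(g).mean())
    effective = lib * g
    return np.log2(counts / effective * 1e6 + pseudocount)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n-2 df."""
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if n < 3:
        return r, np.nan
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_links(
    tss_matrix: pd.DataFrame,
    enh_matrix: pd.DataFrame,
    tss_coords: pd.DataFrame,
    enh_coords: pd.DataFrame,
    window: int = 500_000,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test all in-window (TSS, enhancer) pairs for positive co-expression.

    ``tss_coords`` needs columns (chrom, summit) indexed by tc_id;
    ``enh_coords`` columns (chrom, midpoint) indexed by enh_id.  Both
    matrices must be normalized on the same samples.  Returns the link
    table with distance, r, p, fdr and the kept flag.
    """
    if list(tss_matrix.columns) != list(enh_matrix.columns):
        raise ValueError("TSS and enhancer matrices must share the same samples")
    rows = []
    tss_by_chrom: dict[str, pd.DataFrame] = dict(tuple(tss_coords.groupby("chrom")))
    for enh_id, (chrom, midpoint) in enh_coords[["chrom", "midpoint"]].iterrows():
        near = tss_by_chrom.get(chrom)
        if near is None:
            continue
        close = near[(near["summit"] - midpoint).abs() <= window]
        y = enh_matrix.loc[enh_id].to_numpy(dtype=float)
        for tc_id, summit in close["summit"].items():
            if tc_id not in tss_matrix.index:
                continue
            x = tss_matrix.loc[tc_id].to_numpy(dtype=float)
            r, p = _pearson_with_p(x, y)
            if np.isnan(r):
                continue  # constant feature: correlation undefined, pair skipped
            rows.append((tc_id, enh_id, int(abs(summit - midpoint)), r, p))
    table = pd.DataFrame(rows, columns=["tc_id", "enh_id", "distance", "r", "p"])
    if len(table):
        table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["kept"] = (table["r"] > 0) & (table["fdr"] < fdr_threshold)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["kept"] = pd.Series(dtype=bool)
    return table


def linked_fraction_by_set(links: pd.DataFrame, de_sets: pd.Series) -> pd.Series:
    """Fraction of TSSs in each DE set with at least one kept link."""
    kept_tss = set(links.loc[links["kept"], "tc_id"])
    out = {}
    for label, members in de_sets.groupby(de_sets):
        ids = members.index
        out[label] = float(np.mean([tc in kept_tss for tc in ids])) if len(ids) else np.nan
    return pd.Series(out, name="linked_fraction")
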