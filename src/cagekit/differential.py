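"""Differential expression: NB-GLM contrasts, DE set logic, size factors
and the generic region-overlap enrichment statistic.

The negative-binomial fit is a contract: any standard NB log-linear fit
with batch blocking qualifies.  Here each feature is fitted with a
statsmodels GLM (NegativeBinomial family, log link) on a design of
group and batch indicators.  Tagwise dispersions are maximum-likelihood
estimates at the fitted means, shrunk in log space toward a
mean-dispersion trend before the final fit; contrasts are tested by
Wald z statistics and BH-corrected.

Two contrasts drive the set logic:

* ``IBD``    — average of CDa and UCa versus Ctrl;
* ``CDvsUC`` — CDa versus UCa (positive log2FC = higher in CDa).

Features enter ``IBD_up``/``IBD_down`` or ``CD_spec``/``UC_spec`` when
|log2FC| > 1 at FDR < 0.05 in the relevant contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .linkage import rle_size_factors

CONTRASTS = ("IBD", "CDvsUC")


def _design_matrix(
    sample_table: pd.DataFrame,
    groups: tuple[str, ...] = ("CDa", "UCa", "Ctrl"),
    batch_col: str = "batch",
    extra_covariates: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intercept + group indicators (Ctrl reference) + batch blocks."""
    sub = sample_table[sample_table["group"].isin(groups)]
    for g in groups:
        if (sub["group"] == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    cols = {"intercept": np.ones(len(sub))}
    coef_index: dict[str, int] = {"intercept": 0}
    for g in groups:
        if g == "Ctrl":
            continue
        coef_index[g] = len(cols)
        cols[f"group_{g}"] = (sub["group"] == g).astype(float).to_numpy()
    if batch_col in sub.columns and sub[batch_col].nunique() > 1:
        levels = sorted(sub[batch_col].unique())
        for level in levels[1:]:
            cols[f"batch_{level}"] = (sub[batch_col] == level).astype(float).to_numpy()
    for cov in extra_covariates:
        cols[f"cov_{cov}"] = pd.to_numeric(sub[cov]).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=sub.index)
    return design, coef_index


def _contrast_vector(contrast: str, coef_index: dict[str, int], n_coef: int) -> np.ndarray:
    c = np.zeros(n_coef)
    if contrast == "IBD":
        c[coef_index["CDa"]] = 0.5
        c[coef_index["UCa"]] = 0.5
    elif contrast == "CDvsUC":
        c[coef_index["CDa"]] = 1.0
        c[coef_index["UCa"]] = -1.0
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    return c


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    size = 1.0 / alpha
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Tagwise ML dispersion at fixed fitted means (alpha in NB2 form)."""
    res = optimize.minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(np.log(1e-6), np.log(20.0)),
        method="bounded",
    )
    return float(np.exp(res.x))


@dataclass
class NBDifferentialResults:
    """Per-feature contrast estimates with BH-corrected p-values."""

    table: pd.DataFrame  # log2fc, p, fdr, mean_count, dispersion
    contrast: str
    design_columns: list[str]

    def summary(self, fdr: float = 0.05, lfc: float = 1.0) -> str:
        sig = (self.table["fdr"] < fdr) & (self.table["log2fc"].abs() > lfc)
        up = int((sig & (self.table["log2fc"] > 0)).sum())
        down = int((sig & (self.table["log2fc"] < 0)).sum())
        lines = [
            f"NB differential expression, contrast {self.contrast}",
            f"  features tested : {len(self.table)}",
            f"  design          : {' + '.join(self.design_columns)}",
            f"  |log2FC| > {lfc:g} & FDR < {fdr:g}: {up} up, {down} down",
        ]
        return "\n".join(lines)


class NBDifferentialModel:
    """NB log-linear model of a count matrix with group + batch design.

    Parameters
    ----------
    counts : feature-by-sample count matrix.
    sample_table : sample metadata with ``group`` (CDa/UCa/Ctrl kept) and
        optionally ``batch``; indexed by sample id.
    tagwise_weight : weight of the tagwise dispersion estimate against
        the fitted mean-dispersion trend (0 = pure trend, 1 = pure
        tagwise).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_table: pd.DataFrame,
        groups: tuple[str, ...] = ("CDa", "UCa", "Ctrl"),
        batch_col: str = "batch",
        extra_covariates: tuple[str, ...] = (),
        tagwise_weight: float = 0.25,
    ) -> None:
        self.design, self._coef_index = _design_matrix(
            sample_table, groups, batch_col, extra_covariates
        )
        self.counts = counts[self.design.index]
        self.tagwise_weight = float(tagwise_weight)
        self._dispersions: pd.Series | None = None

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, sample_table: pd.DataFrame, **kw):
        return cls(counts, sample_table, **kw)

    # -- dispersion -----------------------------------------------------
    def _fit_dispersions(self) -> pd.Series:
        if self._dispersions is not None:
            return self._dispersions
        X = self.design.to_numpy()
        tagwise = np.full(len(self.counts), np.nan)
        means = self.counts.mean(axis=1).to_numpy(dtype=float)
        for i, (_fid, row) in enumerate(self.counts.iterrows()):
            y = row.to_numpy(dtype=float)
            if y.sum() == 0:
                continue
            mu = _fit_glm_mu(y, X, alpha=0.1)
            tagwise[i] = _estimate_dispersion(y, mu)
        ok = np.isfinite(tagwise) & (means > 0)
        if ok.sum() >= 10:
            fit = lowess(
                np.log(np.maximum(tagwise[ok], 1e-6)),
                np.log(means[ok]),
                frac=0.8,
                return_sorted=True,
            )
            trend = np.interp(np.log(np.maximum(means, 1e-8)), fit[:, 0], fit[:, 1])
        else:  # too few features for a trend: shrink to the global median
            trend = np.full(len(means), np.log(np.nanmedian(tagwise[ok])) if ok.any() else np.log(0.1))
        w = self.tagwise_weight
        shrunk = np.exp(
            w * np.log(np.maximum(np.nan_to_num(tagwise, nan=np.exp(trend[0])), 1e-6))
            + (1 - w) * trend
        )
        self._dispersions = pd.Series(
            np.clip(shrunk, 1e-6, 20.0), index=self.counts.index, name="dispersion"
        )
        return self._dispersions

    # -- fitting --------------------------------------------------------
    def fit(self, contrast: str = "IBD") -> NBDifferentialResults:
        dispersions = self._fit_dispersions()
        X = self.design.to_numpy()
        cvec = _contrast_vector(contrast, self._coef_index, X.shape[1])
        log2fc = np.zeros(len(self.counts))
        pvals = np.ones(len(self.counts))
        for i, (fid, row) in enumerate(self.counts.iterrows()):
            y = row.to_numpy(dtype=float)
            if y.sum() == 0:
                continue  # all-zero feature: skipped, fdr forced to 1
            alpha = float(dispersions.loc[fid])
            model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha))
            try:
                res = model.fit(maxiter=200)
            except Exception:
                continue
            est = float(cvec @ res.params)
            var = float(cvec @ res.cov_params() @ cvec)
            if var <= 0 or not np.isfinite(var):
                continue
            z = est / np.sqrt(var)
            log2fc[i] = est / np.log(2)
            pvals[i] = 2 * stats.norm.sf(abs(z))
        fdr = multipletests(pvals, method="fdr_bh")[1]
        all_zero = self.counts.sum(axis=1).to_numpy() == 0
        fdr[all_zero] = 1.0
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p": pvals,
                "fdr": fdr,
                "mean_count": self.counts.mean(axis=1),
                "dispersion": dispersions,
            },
            index=self.counts.index,
        )
        return NBDifferentialResults(table, contrast, list(self.design.columns))


def _fit_glm_mu(y: np.ndarray, X: np.ndarray, alpha: float) -> np.ndarray:
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha))
    try:
        return np.maximum(model.fit(maxiter=200).fittedvalues, 1e-8)
    except Exception:
        return np.maximum(
            sm.GLM(y, X, family=sm.families.Poisson()).fit().fittedvalues, 1e-8
        )


def nb_differential_test(
    counts: pd.DataFrame, sample_table: pd.DataFrame, contrast: str, **kw
) -> pd.DataFrame:
    """Functional wrapper: fit the NB model and return the result table."""
    return NBDifferentialModel(counts, sample_table, **kw).fit(contrast).table


# ---------------------------------------------------------------------------
# DE set logic


def define_de_sets(
    ibd_table: pd.DataFrame,
    cduc_table: pd.DataFrame,
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Assign IBD_up / IBD_down / CD_spec / UC_spec / none per feature.

    A pure threshold function of the two contrast tables: |log2FC| > lfc
    and FDR < fdr in the relevant contrast, the sign deciding direction.
    The IBD and CD/UC memberships are recorded independently; ``set``
    reports IBD membership first, CD/UC-specific otherwise.
    """
    if not ibd_table.index.equals(cduc_table.index):
        raise ValueError("contrast tables must cover the same features")
    ibd_sig = (ibd_table["fdr"] < fdr) & (ibd_table["log2fc"].abs() > lfc)
    cduc_sig = (cduc_table["fdr"] < fdr) & (cduc_table["log2fc"].abs() > lfc)
    out = pd.DataFrame(index=ibd_table.index)
    out["logfc_ibd"] = ibd_table["log2fc"]
    out["fdr_ibd"] = ibd_table["fdr"]
    out["logfc_cduc"] = cduc_table["log2fc"]
    out["fdr_cduc"] = cduc_table["fdr"]
    out["ibd_set"] = np.select(
        [ibd_sig & (ibd_table["log2fc"] > 0), ibd_sig & (ibd_table["log2fc"] < 0)],
        ["IBD_up", "IBD_down"],
        default="none",
    )
    out["cduc_set"] = np.select(
        [cduc_sig & (cduc_table["log2fc"] > 0), cduc_sig & (cduc_table["log2fc"] < 0)],
        ["CD_spec", "UC_spec"],
        default="none",
    )
    out["set"] = np.where(out["ibd_set"] != "none", out["ibd_set"], out["cduc_set"])
    return out


def tss_size_factors(tss_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors computed on TSS counts.

    Intended to normalize enhancer matrices from the same samples: TSS
    signal is orders of magnitude stronger, so its median ratios are far
    less noisy than those of the sparse enhancer counts.
    """
    return rle_size_factors(tss_counts)


# ---------------------------------------------------------------------------
# Region-overlap enrichment


def overlap_enrichment_from_counts(
    a: int, c: int, b: int, d: int, continuity: bool = False
) -> tuple[float, float]:
    """log2 odds of overlap in interest vs background + Fisher p.

    a = interest regions overlapping the peaks, c = interest not
    overlapping, b/d likewise for the background.  Enrichment is
    log2((a/(a+c)) / (b/(b+d))); the p-value is a two-sided Fisher exact
    test on the 2x2 table.
    """
    p = float(stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")[1])
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a + c, b + d) == 0 or a == 0 or b == 0:
        return float("nan"), p
    enrichment = float(np.log2((a / (a + c)) / (b / (b + d))))
    return enrichment, p


def _count_overlapping(regions, peaks) -> int:
    peak_list = sorted((p.chrom, p.start, p.end) for p in peaks)
    import bisect

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peak_list:
        by_chrom.setdefault(chrom, []).append((s, e))
    max_len = {c: max(e - s for s, e in v) for c, v in by_chrom.items()}
    n = 0
    for r in regions:
        spans = by_chrom.get(r.chrom)
        if not spans:
            continue
        i = bisect.bisect_right(spans, (r.end, np.iinfo(np.int64).max))
        hit = False
        for s, e in reversed(spans[:i]):
            if e > r.start and s < r.end:
                hit = True
                break
            if r.start - s > max_len[r.chrom]:
                break
        n += hit
    return n


def region_overlap_enrichment(
    regions_of_interest,
    background_regions,
    annotation_peaks,
    continuity: bool = False,
) -> tuple[float, float]:
    """Overlap enrichment of interest vs background regions in a peak set.

    Accepts lists of :class:`~cagekit.io.GenomicInterval` (>=1 bp overlap
    counts) or plain id sets (membership overlap).
    """
    if regions_of_interest and not hasattr(next(iter(regions_of_interest)), "chrom"):
        interest, background, members = (
            set(regions_of_interest),
            set(background_regions),
            set(annotation_peaks),
        )
        a = len(interest & members)
        c = len(interest - members)
        b = len(background & members)
        d = len(background - members)
    else:
        a = _count_overlapping(regions_of_interest, annotation_peaks)
        c = len(regions_of_interest) - a
        b = _count_overlapping(background_regions, annotation_peaks)
        d = len(background_regions) - b
    return overlap_enrichment_from_counts(a, c, b, d, continuity=continuity)


def region_overlap_enrichment_table(
    regions_of_interest, background_regions, peak_sets: dict
) -> pd.DataFrame:
    """Enrichment across several peak sets with BH correction."""
    rows = []
    for name, peaks in peak_sets.items():
        enr, p = region_overlap_enrichment(regions_of_interest, background_regions, peaks)
        rows.append((name, enr, p))
    table = pd.DataFrame(rows, columns=["peak_set", "log2_enrichment", "p"]).set_index(
        "peak_set"
    )
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
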