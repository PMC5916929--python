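"""Microfluidic qPCR processing: Cq -> dCq -> batch-adjusted ddCq.

dCq values (already normalized to the per-batch reference genes, which
are an input) are batch-adjusted with a linear model per primer (group
covariates retained, batch coefficients removed), then rescaled per
primer so the lowest-expressed sample sits at zero:

    x = 2^(-dCq);  ddCq = log2(x / min(x))

Downstream, per-primer inflammatory / TNF-alpha responses are median
log2 ratios against the control (or unstimulated) average, and a primer
is labeled upregulated in a sample group when that median is strictly
positive; the organoid/biopsy/monocyte label overlaps are reported as
Venn counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import BaggingRegressor
from sklearn.impute import KNNImputer
from sklearn.tree import DecisionTreeRegressor


def ddcq_transform(dcq: pd.DataFrame) -> pd.DataFrame:
    """Per primer (row): x = 2^(-dCq); ddCq = log2(x / min x).

    The minimum is taken over non-missing samples; the per-primer
    minimum of the output is exactly 0.  All-missing primers are dropped
    with a warning.
    """
    all_missing = dcq.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing primers")
    dcq = dcq.loc[~all_missing]
    x = np.power(2.0, -dcq)
    return np.log2(x.div(x.min(axis=1), axis=0))


def qc_filter_impute(
    matrix: pd.DataFrame,
    max_missing: float = 0.10,
    method: str = "bagged_trees",
    seed: int = 0,
) -> pd.DataFrame:
    """Drop samples/primers with > max_missing NA; impute the rest.

    Imputation regresses each primer with missing values on the
    complete primers with an ensemble of bagged regression trees
    (``method="knn"`` falls back to k-nearest-neighbour imputation).
    """
    out = matrix.copy()
    bad_primers = out.isna().mean(axis=1) > max_missing
    out = out.loc[~bad_primers]
    bad_samples = out.isna().mean(axis=0) > max_missing
    out = out.loc[:, ~bad_samples]
    if out.empty:
        raise ValueError("QC filtering left an empty matrix")
    if not out.isna().any().any():
        return out
    if method == "knn":
        imputed = KNNImputer(n_neighbors=5).fit_transform(out.T.to_numpy())
        return pd.DataFrame(imputed.T, index=out.index, columns=out.columns)
    if method != "bagged_trees":
        raise ValueError(f"unknown imputation method {method!r}")
    complete = out.index[~out.isna().any(axis=1)]
    if len(complete) == 0:
        raise ValueError("no complete primers available for tree imputation")
    predictors = out.loc[complete].T.to_numpy()  # samples x complete primers
    for primer in out.index[out.isna().any(axis=1)]:
        y = out.loc[primer]
        missing = y.isna().to_numpy()
        reg = BaggingRegressor(
            DecisionTreeRegressor(random_state=seed),
            n_estimators=25,
            random_state=seed,
        )
        reg.fit(predictors[~missing], y.to_numpy()[~missing])
        out.loc[primer, missing] = reg.predict(predictors[missing])
    return out


def batch_adjust(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    group_labels: pd.Series,
    robust: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove additive batch effects per primer, keeping group effects.

    Fits value ~ group + batch per primer (robust Huber regression by
    default) and subtracts the centered batch component.  Returns the
    adjusted matrix and the per-primer batch corrections applied to each
    batch level (external data measured outside the batches, e.g.
    organoids, can be shifted by the mean of these corrections).
    """
    samples = matrix.columns
    batch = batch_labels.reindex(samples).astype(str)
    group = group_labels.reindex(samples).astype(str)
    if batch.nunique() == 1:
        zero = pd.DataFrame(0.0, index=matrix.index, columns=sorted(batch.unique()))
        return matrix.copy(), zero
    cross = pd.crosstab(batch, group)
    if (cross > 0).sum(axis=1).min() == 1 and batch.nunique() == group.nunique():
        raise ValueError("batch is confounded with group; cannot adjust")
    group_dummies = pd.get_dummies(group, prefix="g", drop_first=True, dtype=float)
    batch_dummies = pd.get_dummies(batch, prefix="b", drop_first=False, dtype=float)
    # sum-to-zero batch coding so the batch component is centered
    batch_centered = batch_dummies - batch_dummies.mean(axis=0)
    batch_cols = batch_centered.columns[1:]
    X = pd.concat(
        [pd.Series(1.0, index=samples, name="intercept"), group_dummies,
         batch_centered[batch_cols]],
        axis=1,
    ).to_numpy(dtype=float)
    n_batch = len(batch_cols)
    adjusted = matrix.copy().astype(float)
    levels = sorted(batch.unique())
    corrections = pd.DataFrame(0.0, index=matrix.index, columns=levels)
    for primer, row in matrix.iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        if robust:
            fit = sm.RLM(y[ok], X[ok], M=sm.robust.norms.HuberT()).fit()
        else:
            fit = sm.OLS(y[ok], X[ok]).fit()
        coefs = fit.params[-n_batch:]
        batch_component = batch_centered[batch_cols].to_numpy() @ coefs
        adjusted.loc[primer] = y - batch_component
        # per-level correction (what was subtracted from that batch)
        for level in levels:
            sel = (batch == level).to_numpy()
            corrections.loc[primer, level] = -float(batch_component[sel].mean())
    return adjusted, corrections


def apply_mean_correction(matrix: pd.DataFrame, corrections: pd.DataFrame) -> pd.DataFrame:
    """Shift external data by the mean of the per-batch corrections."""
    shared = matrix.index.intersection(corrections.index)
    shift = corrections.loc[shared].mean(axis=1)
    out = matrix.copy().astype(float)
    out.loc[shared] = out.loc[shared].add(shift, axis=0)
    return out


# ---------------------------------------------------------------------------
# Organoid / biopsy / monocyte comparison


def _log2_response(values: pd.Series, reference_mean: float) -> pd.Series:
    """log2(value / reference mean); non-positive ratios become missing."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = values / reference_mean
        resp = np.log2(ratio.where(ratio > 0))
    return resp


def median_response_labels(
    biopsy: pd.DataFrame,
    organoid: pd.DataFrame,
    monocyte: pd.DataFrame,
    biopsy_groups: pd.Series,
    organoid_times: pd.Series,
    monocyte_times: pd.Series,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label primers up/down per sample group; count the Venn overlaps.

    Responses per primer: biopsy CDa/UCa subjects against the mean of
    all Ctrl; organoid and monocyte TNF-stimulated (4 h / 24 h) samples
    against the mean of the unstimulated (0 h) samples.  A group label
    is "up" when the median response is strictly positive.  Primers with
    a missing median in any group are discarded.  Venn counts: IBD-up
    (up in CDa or UCa), its overlaps with organoid-up (4 h or 24 h) and
    monocyte-up, and the triple overlap.
    """
    group_specs: list[tuple[str, pd.DataFrame, pd.Series, str, str]] = [
        ("CDa", biopsy, biopsy_groups, "CDa", "Ctrl"),
        ("UCa", biopsy, biopsy_groups, "UCa", "Ctrl"),
        ("organoid_4h", organoid, organoid_times, "4h", "0h"),
        ("organoid_24h", organoid, organoid_times, "24h", "0h"),
        ("monocyte_4h", monocyte, monocyte_times, "4h", "0h"),
        ("monocyte_24h", monocyte, monocyte_times, "24h", "0h"),
    ]
    primers = biopsy.index.intersection(organoid.index).intersection(monocyte.index)
    medians = pd.DataFrame(index=primers, columns=[g for g, *_ in group_specs],
                           dtype=float)
    for name, mat, labels, target, ref in group_specs:
        labels = labels.reindex(mat.columns)
        target_cols = mat.columns[(labels == target).to_numpy()]
        ref_cols = mat.columns[(labels == ref).to_numpy()]
        for primer in primers:
            ref_mean = mat.loc[primer, ref_cols].mean()
            if not np.isfinite(ref_mean) or ref_mean <= 0:
                medians.loc[primer, name] = np.nan
                continue
            resp = _log2_response(mat.loc[primer, target_cols], ref_mean)
            medians.loc[primer, name] = resp.median()
    analyzable = medians.dropna()
    labels = analyzable > 0
    ibd_up = labels["CDa"] | labels["UCa"]
    organoid_up = labels["organoid_4h"] | labels["organoid_24h"]
    monocyte_up = labels["monocyte_4h"] | labels["monocyte_24h"]
    venn = {
        "analyzable_primers": int(len(analyzable)),
        "ibd_up": int(ibd_up.sum()),
        "ibd_up_and_organoid_up": int((ibd_up & organoid_up).sum()),
        "ibd_up_and_monocyte_up": int((ibd_up & monocyte_up).sum()),
        "triple": int((ibd_up & organoid_up & monocyte_up).sum()),
    }
    table = labels.copy()
    table.columns = [f"up_{c}" for c in table.columns]
    table.insert(0, "ibd_up", ibd_up)
    return pd.concat([analyzable.add_prefix("median_"), table], axis=1), venn
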