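"""Five-pattern empirical-Bayes classifier for enhancer counts.

With three conditions (CDa, UCa, Ctrl) there are five ways to partition
the condition means:

1. CDa = UCa = Ctrl      (no differential expression)
2. CDa = UCa != Ctrl     (shared IBD response)
3. CDa = Ctrl != UCa     (UCa-specific)
4. UCa = Ctrl != CDa     (CDa-specific)
5. CDa != UCa != Ctrl    (all different)

Counts for enhancer g in sample i follow a negative binomial with
success probability q and size r_gi = r_g * s_i, where s_i is the
sample size factor (derived from TSS counts, not the sparse enhancer
counts themselves) and r_g comes from a method-of-moments fit.  Within a
block of conditions sharing a mean, a single q is drawn from a
Beta(alpha, beta) hyperprior, so the block marginal likelihood is
beta-negative-binomial:

    f(block) = B(alpha + sum r_gi, beta + sum x_gi) / B(alpha, beta)
               (up to a factor constant across patterns)

The mixture over the five patterns (mixing proportions + shared
hyperparameters) is fitted by EM on the marginal likelihood; each
enhancer gets a posterior over patterns.  Enhancers are labeled at a
posterior cutoff of 0.9: IBD_up/IBD_down from pattern 2 with the sign
of both active groups against Ctrl, CDa_spec from pattern 4 and
UCa_spec from pattern 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln, logsumexp

CONDITIONS = ("CDa", "UCa", "Ctrl")

# each pattern is a partition of the conditions into equal-mean blocks
PATTERNS: dict[int, tuple[frozenset, ...]] = {
    1: (frozenset({"CDa", "UCa", "Ctrl"}),),
    2: (frozenset({"CDa", "UCa"}), frozenset({"Ctrl"})),
    3: (frozenset({"CDa", "Ctrl"}), frozenset({"UCa"})),
    4: (frozenset({"UCa", "Ctrl"}), frozenset({"CDa"})),
    5: (frozenset({"CDa"}), frozenset({"UCa"}), frozenset({"Ctrl"})),
}


@dataclass
class EnhancerPatternResults:
    """Posterior pattern memberships and labels per enhancer."""

    posteriors: pd.DataFrame  # columns pattern_1..pattern_5
    map_pattern: pd.Series
    labels: pd.Series  # IBD_up / IBD_down / CDa_spec / UCa_spec / none
    group_means: pd.DataFrame  # normalized condition means
    alpha: float
    beta: float
    mixture: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = True

    def summary(self) -> str:
        counts = self.labels.value_counts()
        lines = [
            "Five-pattern EB enhancer model",
            f"  enhancers      : {len(self.posteriors)}",
            f"  Beta hyperprior: alpha={self.alpha:.4g}, beta={self.beta:.4g}",
            "  mixture        : "
            + ", ".join(f"P{k}={p:.3f}" for k, p in zip(PATTERNS, self.mixture)),
            f"  EM iterations  : {len(self.loglik_trace)}"
            + ("" if self.converged else " (not converged)"),
        ]
        for label in ("IBD_up", "IBD_down", "CDa_spec", "UCa_spec", "none"):
            lines.append(f"  {label:<9}: {int(counts.get(label, 0))}")
        return "\n".join(lines)


class EnhancerPatternModel:
    """EB mixture over the five condition-mean patterns.

    Parameters
    ----------
    counts : enhancer-by-sample raw count matrix.
    groups : per-sample condition labels (CDa/UCa/Ctrl), aligned with
        the matrix columns.
    size_factors : per-sample size factors; pass factors derived from
        TSS counts of the same samples.  Defaults to all ones.

    The analysis assumes a single batch; run per batch when the cohort
    has batch structure.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: pd.Series,
        size_factors: pd.Series | None = None,
    ) -> None:
        groups = groups.reindex(counts.columns)
        keep_samples = groups.isin(CONDITIONS)
        self.counts = counts.loc[:, keep_samples.to_numpy()]
        self.groups = groups[keep_samples]
        for cond in CONDITIONS:
            if (self.groups == cond).sum() < 2:
                raise ValueError(f"condition {cond} has fewer than 2 samples")
        if size_factors is None:
            size_factors = pd.Series(1.0, index=self.counts.columns)
        self.size_factors = size_factors.reindex(self.counts.columns).astype(float)
        nonzero = self.counts.sum(axis=1) > 0
        if not nonzero.all():
            warnings.warn(f"dropping {(~nonzero).sum()} all-zero enhancers")
            self.counts = self.counts.loc[nonzero]

    # -- internals ------------------------------------------------------
    def _prepare(self):
        x = self.counts.to_numpy(dtype=float)
        s = self.size_factors.to_numpy(dtype=float)
        z = x / s[None, :]
        m = z.mean(axis=1)
        # within-condition pooled variance: the between-condition component
        # would inflate v for differential enhancers and shrink r towards 0
        cond_masks = [(self.groups == c).to_numpy() for c in CONDITIONS]
        num = sum(z[:, msk].var(axis=1, ddof=1) * (msk.sum() - 1) for msk in cond_masks)
        v = num / sum(msk.sum() - 1 for msk in cond_masks)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(v > m, m / v, 0.999)
        q = np.clip(q, 1e-4, 0.999)
        r_g = m * q / (1.0 - q)
        r_g = np.clip(r_g, 1e-3, 1e6)
        r = r_g[:, None] * s[None, :]  # per-gene per-sample NB size
        cond_idx = {c: (self.groups == c).to_numpy() for c in CONDITIONS}
        subsets = sorted({blk for p in PATTERNS.values() for blk in p}, key=sorted)
        sums = {}
        for blk in subsets:
            sel = np.zeros(x.shape[1], dtype=bool)
            for c in blk:
                sel |= cond_idx[c]
            sums[blk] = (r[:, sel].sum(axis=1), x[:, sel].sum(axis=1))
        means = pd.DataFrame(
            {c: z[:, cond_idx[c]].mean(axis=1) for c in CONDITIONS},
            index=self.counts.index,
        )
        return sums, means, q

    @staticmethod
    def _pattern_logf(sums, log_ab: np.ndarray) -> np.ndarray:
        """(n_genes, 5) pattern log-marginals at hyperparameters exp(log_ab)."""
        a, b = np.exp(log_ab)
        cols = []
        for blocks in PATTERNS.values():
            acc = 0.0
            for blk in blocks:
                rsum, xsum = sums[blk]
                acc = acc + betaln(a + rsum, b + xsum)
            cols.append(acc - len(blocks) * betaln(a, b))
        return np.column_stack(cols)

    # -- fitting --------------------------------------------------------
    def fit(
        self,
        maxiter: int = 100,
        tol: float = 1e-6,
        posterior_cutoff: float = 0.9,
        alpha0: float | None = None,
        beta0: float | None = None,
    ) -> EnhancerPatternResults:
        sums, means, q_hat = self._prepare()
        n = len(self.counts)
        if alpha0 is None or beta0 is None:
            # method-of-moments Beta fit to the per-enhancer q estimates;
            # a poor start here lets the all-different pattern absorb the
            # equal-mean features (a local EM optimum)
            m, v = float(np.mean(q_hat)), float(np.var(q_hat))
            if 0 < m < 1 and 0 < v < m * (1 - m):
                common = m * (1 - m) / v - 1
                alpha0 = max(m * common, 0.01)
                beta0 = max((1 - m) * common, 0.01)
            else:
                alpha0, beta0 = 1.0, 1.0
        log_ab = np.log([alpha0, beta0])
        mix = np.full(len(PATTERNS), 1.0 / len(PATTERNS))
        trace: list[float] = []
        converged = False
        post = np.full((n, len(PATTERNS)), 1.0 / len(PATTERNS))
        for _ in range(maxiter):
            logf = self._pattern_logf(sums, log_ab)
            joint = logf + np.log(mix)[None, :]
            norm = logsumexp(joint, axis=1)
            post = np.exp(joint - norm[:, None])
            loglik = float(norm.sum())
            trace.append(loglik)
            # M-step: mixing proportions in closed form, hyperparameters
            # by warm-started numerical maximization (never decreases).
            mix = np.maximum(post.mean(axis=0), 1e-12)
            mix /= mix.sum()

            def neg_q(lab, _post=post):
                return -float((_post * self._pattern_logf(sums, lab)).sum())

            res = optimize.minimize(neg_q, log_ab, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-4, "maxiter": 200})
            if res.fun <= neg_q(log_ab):
                log_ab = res.x
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1):
                converged = True
                break
        if not converged:
            warnings.warn("EM did not converge; reporting last iterate")
        posteriors = pd.DataFrame(
            post, index=self.counts.index, columns=[f"pattern_{k}" for k in PATTERNS]
        )
        map_pattern = pd.Series(
            posteriors.to_numpy().argmax(axis=1) + 1,
            index=posteriors.index,
            name="map_pattern",
        )
        labels = _assign_labels(posteriors, means, posterior_cutoff)
        alpha, beta = np.exp(log_ab)
        return EnhancerPatternResults(
            posteriors=posteriors,
            map_pattern=map_pattern,
            labels=labels,
            group_means=means,
            alpha=float(alpha),
            beta=float(beta),
            mixture=mix,
            loglik_trace=trace,
            converged=converged,
        )


def _assign_labels(
    posteriors: pd.DataFrame, means: pd.DataFrame, cutoff: float
) -> pd.Series:
    p2 = posteriors["pattern_2"].to_numpy()
    p3 = posteriors["pattern_3"].to_numpy()
    p4 = posteriors["pattern_4"].to_numpy()
    up = (means["CDa"] > means["Ctrl"]).to_numpy() & (means["UCa"] > means["Ctrl"]).to_numpy()
    down = (means["CDa"] < means["Ctrl"]).to_numpy() & (means["UCa"] < means["Ctrl"]).to_numpy()
    labels = np.select(
        [
            (p2 > cutoff) & up,
            (p2 > cutoff) & down,
            p4 > cutoff,
            p3 > cutoff,
        ],
        ["IBD_up", "IBD_down", "CDa_spec", "UCa_spec"],
        default="none",
    )
    return pd.Series(labels, index=posteriors.index, name="label")


def eb_pattern_classify(
    enh_counts: pd.DataFrame,
    size_factors: pd.Series | None,
    groups: pd.Series,
    posterior: float = 0.9,
    iterations: int = 100,
) -> EnhancerPatternResults:
    """Functional wrapper over :class:`EnhancerPatternModel`."""
    model = EnhancerPatternModel(enh_counts, groups, size_factors)
    return model.fit(maxiter=iterations, posterior_cutoff=posterior)
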