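"""Count-matrix container, normalisation and the negative-binomial exact test.

The null model for a gene is a pair of moment-matched negative binomial
distributions, one for the replicate-sum count of each condition.  The exact
test conditions on the total count ``k_A + k_B`` and sums the probabilities of
every apportionment of that total which is no more likely than the observed
one (the probability-mass ordering definition of a two-sided p-value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: floor applied to moment dispersion estimates (keeps the NB well defined)
PHI_FLOOR = 1e-8
#: totals above this are enumerated on a pruned support window
PRUNE_TOTAL = 50_000
#: per-tail probability mass discarded when pruning
PRUNE_MASS = 1e-13
#: log-scale tolerance for probability ties in the two-sided ordering
TIE_LOG_TOL = 1e-9


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes x samples, with a two-class condition label.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.  All entries
        must be non-negative integers.
    conditions
        Series mapping each sample name to one of exactly two condition
        labels, aligned with the columns of ``counts``.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.floor(vals)):
            bad = np.argwhere((vals < 0) | (vals != np.floor(vals)))[0]
            raise ValueError(
                f"counts must be non-negative integers; offending entry at gene "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        if list(self.conditions.index) != list(self.counts.columns):
            raise ValueError("conditions must be indexed by the sample columns, in order")
        labels = self.labels
        if len(labels) != 2:
            raise ValueError(f"exactly two condition labels required, got {list(labels)}")

    @property
    def labels(self) -> tuple:
        """The two condition labels, in order of first appearance."""
        return tuple(pd.unique(self.conditions))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def samples_of(self, label) -> np.ndarray:
        """Boolean column mask for one condition."""
        return (self.conditions == label).to_numpy()

    def subset(self, gene_mask) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_mask], self.conditions)


def filter_low_counts(cm: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Remove genes whose mean count across all samples is <= ``threshold``.

    Culling genes averaging one count or less per replicate reduces the mass
    of zero-count genes whose discrete p-values are uninformative.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = cm.counts.mean(axis=1)
    keep = means > threshold
    if not keep.any():
        warnings.warn("filter_low_counts removed every gene", stacklevel=2)
    logger.info("filter_low_counts: %d of %d genes retained", int(keep.sum()), cm.n_genes)
    return cm.subset(keep)


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-count-ratios size factors.

    For each sample j, ``s_j`` is the median over zero-free genes of the ratio
    of the gene's count in sample j to the gene's geometric mean across
    samples.  Genes with any zero count are excluded from the reference.
    """
    k = cm.counts.to_numpy(dtype=float)
    zero_free = np.all(k > 0, axis=1)
    if not zero_free.any():
        raise ValueError(
            "size factors undefined: every gene has a zero count in at least one sample"
        )
    logk = np.log(k[zero_free])
    log_ratios = logk - logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(s, index=cm.counts.columns, name="size_factor")


@dataclass
class GeneNullModel:
    """Per-gene NB null model and the moments of the condition-sum counts.

    ``mu`` is the pooled common-scale mean, ``phi`` the overdispersion in
    ``Var(Y) = E(Y) + phi E(Y)^2``.  ``mu_sum_a``/``var_sum_a`` (and the B
    analogues) are the moment-matched mean and variance of the sum of raw
    counts over the replicates of each condition.  Genes with zero total count
    are flagged ``degenerate`` and receive p = 1 downstream.
    """

    gene_ids: pd.Index
    mu: np.ndarray
    phi: np.ndarray
    mu_sum_a: np.ndarray
    var_sum_a: np.ndarray
    mu_sum_b: np.ndarray
    var_sum_b: np.ndarray
    degenerate: np.ndarray

    def __len__(self) -> int:
        return len(self.mu)

    @classmethod
    def from_params(
        cls,
        mu: np.ndarray,
        phi: np.ndarray,
        size_factors: np.ndarray,
        in_a: np.ndarray,
        gene_ids: pd.Index | None = None,
    ) -> "GeneNullModel":
        """Build condition-sum moments from per-gene (mu, phi) and size factors.

        The sum over replicates j of NB(s_j mu, phi) has mean
        ``sum_j s_j mu`` and variance ``sum_j (s_j mu + phi (s_j mu)^2)``.
        """
        mu = np.asarray(mu, dtype=float)
        phi = np.asarray(phi, dtype=float)
        s = np.asarray(size_factors, dtype=float)
        in_a = np.asarray(in_a, dtype=bool)
        if np.any(phi < 0):
            raise ValueError("phi must be >= 0")
        sums = {}
        for key, mask in (("a", in_a), ("b", ~in_a)):
            sm = mu[:, None] * s[mask][None, :]
            sums["mu_" + key] = sm.sum(axis=1)
            sums["var_" + key] = (sm + phi[:, None] * sm**2).sum(axis=1)
        if gene_ids is None:
            gene_ids = pd.RangeIndex(len(mu))
        return cls(
            gene_ids=gene_ids,
            mu=mu,
            phi=phi,
            mu_sum_a=sums["mu_a"],
            var_sum_a=sums["var_a"],
            mu_sum_b=sums["mu_b"],
            var_sum_b=sums["var_b"],
            degenerate=(mu <= 0),
        )


def _dispersion_trend(mu: np.ndarray, phi_raw: np.ndarray) -> np.ndarray:
    """Locally weighted regression of raw moment dispersions on log mean."""
    ok = mu > 0
    trend = np.zeros_like(phi_raw)
    if ok.sum() < 10:
        return trend
    x = np.log(mu[ok])
    span = float(np.ptp(x))
    fitted = lowess(
        phi_raw[ok], x, frac=0.3, it=2,
        delta=0.005 * span if span > 0 else 0.0,
        return_sorted=False,
    )
    trend[ok] = np.maximum(fitted, 0.0)
    return trend


def estimate_null_model(
    cm: CountMatrix, size_factors: pd.Series, trend: bool = True
) -> GeneNullModel:
    """Method-of-moments NB parameters on common-scale counts.

    The per-gene mean is the mean of ``K_ij / s_j`` pooled over all samples of
    both conditions.  The variance is the pooled within-condition sample
    variance (sums of squares about each condition's own mean, divided by
    n - 2), so differential expression does not inflate the dispersion; the
    dispersion then solves the common-scale mean-variance relation
    ``Var(K/s) = mu * E(1/s) + phi mu^2`` and is floored at ``PHI_FLOOR``.  With ``trend=True`` a lowess mean-dispersion trend is
    fitted and the per-gene maximum of raw and trend values is used, which
    makes low-information estimates conservative in the same direction as the
    information-sharing estimators used by the established NB packages.
    """
    n = cm.counts.shape[1]
    if min((cm.conditions == lab).sum() for lab in cm.labels) < 2:
        raise ValueError("at least two samples per condition required to estimate variance")
    k = cm.counts.to_numpy(dtype=float)
    s = size_factors.to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    q = k / s[None, :]
    mu = q.mean(axis=1)
    ss = np.zeros(len(mu))
    for lab in cm.labels:
        qx = q[:, cm.samples_of(lab)]
        ss += ((qx - qx.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = ss / (n - 2)
    inv_s_mean = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (v - mu * inv_s_mean) / mu**2
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, 0.0)
    if trend:
        phi = np.maximum(phi_raw, _dispersion_trend(mu, phi_raw))
    else:
        phi = phi_raw
    phi = np.maximum(phi, PHI_FLOOR)
    in_a = cm.samples_of(cm.labels[0])
    model = GeneNullModel.from_params(mu, phi, s, in_a, gene_ids=cm.gene_ids)
    model.degenerate = k.sum(axis=1) == 0
    return model


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of the moment-matched NB (Poisson when var <= mean).

    Non-integer size parameters are handled through the gamma function.
    """
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if var <= mean * (1.0 + 1e-12):
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = mean * mean / (var - mean)
    log_p = np.log(r) - np.log(r + mean)
    log_q = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1.0) + r * log_p + k * log_q


def _marginal_bounds(mean: float, var: float) -> tuple[int, int]:
    if mean <= 0:
        return 0, 0
    if var <= mean * (1.0 + 1e-12):
        dist = poisson(mean)
    else:
        r = mean * mean / (var - mean)
        dist = nbinom(r, r / (r + mean))
    return int(dist.ppf(PRUNE_MASS)), int(dist.isf(PRUNE_MASS))


def _conditional_window(
    model: GeneNullModel, i: int, k_total: int, ensure: int | None = None
) -> tuple[int, np.ndarray]:
    """Normalized log conditional pmf of the condition-A sum on a support window.

    Returns ``(a0, logp)`` with ``logp[j]`` the log probability of observing
    ``a0 + j`` counts in condition A given the total ``k_total``.  For totals
    up to ``PRUNE_TOTAL`` the full support 0..k_total is used; above that the
    support is pruned to a window carrying all but < 2*PRUNE_MASS of the mass.
    """
    lo, hi = 0, k_total
    if k_total > PRUNE_TOTAL:
        lo_a, hi_a = _marginal_bounds(model.mu_sum_a[i], model.var_sum_a[i])
        lo_b, hi_b = _marginal_bounds(model.mu_sum_b[i], model.var_sum_b[i])
        lo = max(0, lo_a, k_total - hi_b)
        hi = min(k_total, hi_a, k_total - lo_b)
        if lo > hi:  # inconsistent windows (observation far in both tails)
            lo, hi = 0, k_total
        else:
            logger.debug("pruned support for k_total=%d to [%d, %d]", k_total, lo, hi)
    if ensure is not None:
        lo, hi = min(lo, ensure), max(hi, ensure)
    a = np.arange(lo, hi + 1)
    logw = _nb_logpmf(a, model.mu_sum_a[i], model.var_sum_a[i]) + _nb_logpmf(
        k_total - a, model.mu_sum_b[i], model.var_sum_b[i]
    )
    return lo, logw - logsumexp(logw)


def null_conditional_distribution(
    model: GeneNullModel, i: int, k_total: int
) -> np.ndarray:
    """P_K(a), a = 0..k_total: the conditional null law of the condition-A sum.

    ``P_K(a)`` is proportional to ``pi(a, k_total - a)``, the product of the
    two condition-sum NB pmfs, normalized over all apportionments of the
    total.  Computed in log space; sums to 1 within 1e-10.
    """
    if k_total < 0:
        raise ValueError("k_total must be >= 0")
    if k_total == 0:
        return np.ones(1)
    a0, logp = _conditional_window(model, i, k_total)
    out = np.zeros(k_total + 1)
    out[a0 : a0 + len(logp)] = np.exp(logp)
    return out


def exact_test_p(model: GeneNullModel, i: int, k_a: int, k_b: int) -> float:
    """Two-sided exact conditional p-value for gene ``i``.

    Sums ``P_K(a)`` over every apportionment ``(a, k_total - a)`` whose null
    probability is less than or equal to that of the observed ``(k_a, k_b)``.
    An observation at the mode returns 1 (the discrete "flagpole").
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be >= 0")
    if model.degenerate[i]:
        return 1.0
    k_total = k_a + k_b
    if k_total == 0:
        return 1.0
    a0, logp = _conditional_window(model, i, k_total, ensure=k_a)
    obs = logp[k_a - a0]
    qualifying = logp[logp <= obs + TIE_LOG_TOL]
    return float(min(1.0, np.exp(logsumexp(qualifying))))


def exact_test(
    cm: CountMatrix, model: GeneNullModel, size_factors: pd.Series
) -> pd.DataFrame:
    """Per-gene exact test table: id, baseMeanA, baseMeanB, foldChange, pval.

    Base means are means of size-factor-normalized counts per condition; the
    fold change ``baseMeanB / baseMeanA`` is NaN when condition A has mean 0.
    """
    table = _base_mean_table(cm, size_factors)
    in_a = cm.samples_of(cm.labels[0])
    raw = cm.counts.to_numpy()
    k_a = raw[:, in_a].sum(axis=1)
    k_b = raw[:, ~in_a].sum(axis=1)
    table["pval"] = [
        exact_test_p(model, i, int(k_a[i]), int(k_b[i])) for i in range(len(model))
    ]
    return table


def _base_mean_table(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    q = cm.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    in_a = cm.samples_of(cm.labels[0])
    base_a = q[:, in_a].mean(axis=1)
    base_b = q[:, ~in_a].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(base_a > 0, base_b / base_a, np.nan)
    return pd.DataFrame(
        {"baseMeanA": base_a, "baseMeanB": base_b, "foldChange": fold},
        index=cm.gene_ids,
    )
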