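"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use a different computational route from the
package: scipy pmfs summed in plain (linear-scale) float arithmetic for the
exact test, and closed-form interval arithmetic for the randomized p-value
distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyfitde.count_model import CountMatrix, GeneNullModel


def _oracle_pmf(k, mean, var):
    """Moment-matched NB (or Poisson) pmf via scipy, linear scale."""
    k = np.asarray(k)
    if mean <= 0:
        return np.where(k == 0, 1.0, 0.0)
    if var <= mean * (1.0 + 1e-12):
        return stats.poisson.pmf(k, mean)
    r = mean * mean / (var - mean)
    return stats.nbinom.pmf(k, r, r / (r + mean))


def oracle_exact_p(mu_a, var_a, mu_b, var_b, k_a, k_b):
    """Brute-force enumeration of the two-sided conditional p-value.

    Sums pi(a, k-a) over all apportionments with probability <= the observed
    one (relative tie tolerance 1e-9, matching the package's convention).
    """
    k = k_a + k_b
    a = np.arange(k + 1)
    w = _oracle_pmf(a, mu_a, var_a) * _oracle_pmf(k - a, mu_b, var_b)
    w = w / w.sum()
    return min(1.0, float(w[w <= w[k_a] * (1.0 + 1e-9)].sum()))


def model_from_moments(mu_a, var_a, mu_b, var_b) -> GeneNullModel:
    """Single-gene null model with explicitly given condition-sum moments."""
    return GeneNullModel(
        gene_ids=pd.RangeIndex(1),
        mu=np.array([1.0]),
        phi=np.array([0.0]),
        mu_sum_a=np.array([float(mu_a)]),
        var_sum_a=np.array([float(var_a)]),
        mu_sum_b=np.array([float(mu_b)]),
        var_sum_b=np.array([float(var_b)]),
        degenerate=np.array([False]),
    )


def make_count_matrix(counts, conditions, gene_ids=None) -> CountMatrix:
    counts = np.atleast_2d(np.asarray(counts))
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    cols = [f"s{j + 1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=cols)
    return CountMatrix(df, pd.Series(list(conditions), index=df.columns))


@pytest.fixture
def exact_oracle():
    return oracle_exact_p


@pytest.fixture
def make_model():
    return model_from_moments


@pytest.fixture
def binomial_model():
    """Poisson sums with equal effective sizes: conditional is Binomial(k, 1/2)."""
    return model_from_moments(2.0, 2.0, 2.0, 2.0)


@pytest.fixture
def cm_factory():
    return make_count_matrix


@pytest.fixture
def small_cm():
    """4 genes x (2 + 2) samples with simple structure."""
    return make_count_matrix(
        [[10, 12, 9, 11], [0, 0, 0, 0], [100, 110, 20, 25], [5, 4, 6, 5]],
        "AABB",
    )
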