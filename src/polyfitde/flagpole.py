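"""Randomized "squared-off" p-values for discrete conditional nulls.

The exact conditional test returns p = 1 whenever the observation lands on
the mode of its discrete null distribution, producing a spike ("flagpole") at
the right-hand end of the p-value histogram.  Replacing the discrete p-value
by

    p = 2 * min(F(k-1) + U * P(k), 1 - F(k-1) - U * P(k)),    U ~ Uniform[0,1]

makes the p-value exactly Uniform[0,1] under the discrete null: the quantity
``F(k-1) + U * P(k)`` is a uniform draw from the cumulative slot of the
observed outcome, and the two-sided value is twice the smaller one-sided
tail.  One independent U is drawn per gene, so results are reproducible only
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_model import CountMatrix, GeneNullModel, _base_mean_table, _conditional_window


@dataclass(frozen=True)
class DiscreteNull:
    """Probability mass and cumulative vectors of a discrete null on 0..k_max."""

    pmf: np.ndarray
    cdf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        if np.any(pmf < 0):
            raise ValueError("pmf entries must be >= 0")
        if abs(pmf.sum() - 1.0) > 1e-10:
            raise ValueError("pmf must sum to 1 within 1e-10")
        object.__setattr__(self, "pmf", pmf)
        if self.cdf is None:
            object.__setattr__(self, "cdf", np.cumsum(pmf))

    @property
    def k_max(self) -> int:
        return len(self.pmf) - 1


@dataclass(frozen=True)
class PValueSet:
    """A p-value vector with a provenance flag.

    ``kind`` is one of ``nominal`` (discrete exact test), ``smoothed``
    (flagpole-randomized) or ``corrected`` (histogram-corrected).
    """

    p: np.ndarray
    kind: str = "nominal"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "p", p)
        if self.kind not in ("nominal", "smoothed", "corrected"):
            raise ValueError(f"unknown provenance kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.p)


def randomized_p(null: DiscreteNull, k: int, u: float) -> float:
    """Squared-off two-sided p-value for observing ``k`` under ``null``.

    With ``L = F(k-1) + u * P(k)`` the value is ``2 * min(L, 1 - L)``,
    always in [0, 1].
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("U must lie in [0, 1]")
    if not 0 <= k <= null.k_max:
        raise ValueError(f"k={k} outside support 0..{null.k_max}")
    f_km1 = float(null.cdf[k - 1]) if k > 0 else 0.0
    lower = f_km1 + u * float(null.pmf[k])
    return float(np.clip(2.0 * min(lower, 1.0 - lower), 0.0, 1.0))


def smoothed_exact_test(
    cm: CountMatrix,
    model: GeneNullModel,
    size_factors: pd.Series,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Exact test table with flagpole-randomized p-values.

    One uniform draw is consumed per gene, in gene order, so a fixed seed
    yields a bitwise-identical table.  Degenerate (zero-count) genes receive
    ``2 * min(U, 1 - U)``, a uniform draw, in place of the conventional p = 1
    of the discrete test.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.uniform(size=cm.n_genes)
    table = _base_mean_table(cm, size_factors)
    in_a = cm.samples_of(cm.labels[0])
    raw = cm.counts.to_numpy()
    k_a = raw[:, in_a].sum(axis=1)
    k_b = raw[:, ~in_a].sum(axis=1)
    pvals = np.empty(cm.n_genes)
    for i in range(cm.n_genes):
        k_total = int(k_a[i] + k_b[i])
        if model.degenerate[i] or k_total == 0:
            pvals[i] = 2.0 * min(u[i], 1.0 - u[i])
            continue
        a0, logp = _conditional_window(model, i, k_total, ensure=int(k_a[i]))
        w = np.exp(logp)
        idx = int(k_a[i]) - a0
        lower = w[:idx].sum() + u[i] * w[idx]
        pvals[i] = np.clip(2.0 * min(lower, 1.0 - lower), 0.0, 1.0)
    table["pval"] = pvals
    return table
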