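"""Scoring of ranked differential-expression calls against simulation truth.

The realized ("true") FDR at rank r is FP / (FP + TP) over the first r genes
of a ranking, computed from the known truth labels; the estimated FDR is the
q-value a method reports at that rank.  At full calling the true FDR equals
the null fraction of the gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import PolyfitFit
from .synthetic import SyntheticTruth


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion table at one significance cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pvals, is_de, alpha: float) -> ConfusionCounts:
    """Counts of true/false positives/negatives calling every p <= alpha."""
    p = np.asarray(pvals, dtype=float)
    de = np.asarray(is_de, dtype=bool)
    called = p <= alpha
    return ConfusionCounts(
        tp=int((called & de).sum()),
        fp=int((called & ~de).sum()),
        tn=int((~called & ~de).sum()),
        fn=int((~called & de).sum()),
    )


def _is_de_lookup(truth) -> pd.Series:
    if isinstance(truth, SyntheticTruth):
        return pd.Series(truth.is_de, index=truth.gene_ids)
    return pd.Series(truth)


def rank_genes(table: pd.DataFrame, by: str = "pval") -> pd.Index:
    """Gene ids ordered by ascending ``by`` column; ties keep input order."""
    order = np.argsort(table[by].to_numpy(), kind="stable")
    return table.index[order]


def true_fdr_curve(ranking, truth) -> pd.DataFrame:
    """Cumulative FP / (FP + TP) along a ranking of all genes.

    ``ranking`` must be a permutation of the truth's gene ids; ties in the
    underlying scores are assumed already broken by input order.
    """
    is_de = _is_de_lookup(truth)
    ranking = pd.Index(ranking)
    if set(ranking) != set(is_de.index) or len(ranking) != len(is_de):
        raise ValueError("ranking is not a permutation of the truth's gene set")
    de_ranked = is_de.loc[ranking].to_numpy(dtype=bool)
    ranks = np.arange(1, len(ranking) + 1)
    fp = np.cumsum(~de_ranked)
    return pd.DataFrame(
        {"rank": ranks, "gene": ranking, "true_fdr": fp / ranks}
    ).set_index("rank")


def percent_de_estimate(fit: PolyfitFit) -> float:
    """Estimated percentage of DE genes, 100 * (1 - pi0_hat).

    Negative when pi0_hat exceeds 1; reported with a warning, never clipped.
    """
    value = 100.0 * (1.0 - fit.pi0_hat)
    if value < 0:
        warnings.warn(
            f"pi0_hat = {fit.pi0_hat:.4f} > 1 gives a negative percent-DE estimate",
            stacklevel=2,
        )
    return value


def compare_methods(results, truth, zoom_rank: int | None = None) -> pd.DataFrame:
    """Long-format true/estimated FDR table for several methods.

    ``results`` is an iterable of ``(name, ranking, est_q)`` with ``est_q``
    aligned to the ranking.  ``zoom_rank`` truncates every series to its
    first ``zoom_rank`` genes (the expanded view around the significant end).
    """
    frames = []
    gene_set = None
    for name, ranking, est_q in results:
        curve = true_fdr_curve(ranking, truth)
        if gene_set is None:
            gene_set = set(curve["gene"])
        elif set(curve["gene"]) != gene_set:
            raise ValueError(f"method {name!r} covers a different gene set")
        curve = curve.assign(method=name, est_fdr=np.asarray(est_q, dtype=float))
        if zoom_rank is not None:
            curve = curve.iloc[:zoom_rank]
        frames.append(curve.reset_index())
    return pd.concat(frames, ignore_index=True)[
        ["method", "rank", "gene", "true_fdr", "est_fdr"]
    ]


def plot_fdr_curves(table: pd.DataFrame, path: str) -> None:
    """True (solid) and estimated (dashed) FDR curves per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, sub in table.groupby("method"):
        line, = ax.plot(sub["rank"], sub["true_fdr"], label=f"{name} (true)")
        ax.plot(sub["rank"], sub["est_fdr"], ls="--", color=line.get_color(),
                label=f"{name} (estimated)")
    ax.set_xlabel("genes called")
    ax.set_ylabel("FDR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
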