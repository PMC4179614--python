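"""End-to-end conveniences: count table -> corrected q-values, and full
simulation studies with truth labels attached.

These are the programmatic equivalents of chaining the ``test`` and
``correct`` CLI subcommands, and of a complete ``simulate -> test ->
correct`` benchmark run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import count_model, flagpole, synthetic
from .correction import HistogramSpec, PolyfitFit, run_polyfit


@dataclass
class AnalysisResult:
    """Test + correction output for one dataset."""

    table: pd.DataFrame  # id-indexed: baseMeanA/B, foldChange, pval, p_corr, q_corr, q_bh
    fit: PolyfitFit
    size_factors: pd.Series
    model: count_model.GeneNullModel
    counts: count_model.CountMatrix  # after low-count culling


def analyze(
    cm: count_model.CountMatrix,
    seed: int = 0,
    smooth: bool = True,
    trend: bool = True,
    min_mean: float | None = 1.0,
    spec: HistogramSpec | None = None,
    model: count_model.GeneNullModel | None = None,
) -> AnalysisResult:
    """Run culling, normalisation, the exact test and the histogram correction.

    With ``smooth=True`` (default) the flagpole-randomized p-values are used;
    the seed controls the per-gene uniform draws.  A pre-built ``model`` (e.g.
    from known simulation parameters) bypasses estimation.
    """
    if min_mean is not None:
        cm = count_model.filter_low_counts(cm, min_mean)
    sf = count_model.estimate_size_factors(cm)
    if model is None:
        model = count_model.estimate_null_model(cm, sf, trend=trend)
    if smooth:
        table = flagpole.smoothed_exact_test(cm, model, sf, np.random.default_rng(seed))
    else:
        table = count_model.exact_test(cm, model, sf)
    fit = run_polyfit(table["pval"].to_numpy(), spec=spec)
    table = table.assign(p_corr=fit.p_corr, q_corr=fit.q_corr, q_bh=fit.q_bh)
    return AnalysisResult(table=table, fit=fit, size_factors=sf, model=model, counts=cm)


@dataclass
class StudyResult:
    """One synthetic benchmark run: analysis output aligned with truth."""

    analysis: AnalysisResult
    truth: synthetic.SyntheticTruth
    is_de: np.ndarray  # truth labels restricted to the genes that survived culling

    @property
    def fit(self) -> PolyfitFit:
        return self.analysis.fit

    @property
    def table(self) -> pd.DataFrame:
        return self.analysis.table


def simulate_and_analyze(
    t: int = 20_000,
    n: int = 4,
    frac_de: float = 0.15,
    family: str = "nb",
    seed: int = 0,
    params: synthetic.GeneParamTable | None = None,
    smooth: bool = True,
    trend: bool = True,
    min_mean: float | None = 1.0,
) -> StudyResult:
    """Simulate a two-class dataset and push it through the full pipeline.

    The simulation and analysis consume independent random streams derived
    from ``seed``, so the same data can be re-analysed under a different
    analysis seed.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = synthetic.sample_params(t, rng)
    cfg = synthetic.SimulationConfig(t=t, n=n, frac_de=frac_de, family=family, seed=seed)
    cm, truth = synthetic.simulate_counts(params, cfg, rng)
    analysis = analyze(
        cm, seed=seed + 1, smooth=smooth, trend=trend, min_mean=min_mean
    )
    de_lookup = pd.Series(truth.is_de, index=truth.gene_ids)
    is_de = de_lookup.loc[analysis.table.index].to_numpy(dtype=bool)
    return StudyResult(analysis=analysis, truth=truth, is_de=is_de)
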