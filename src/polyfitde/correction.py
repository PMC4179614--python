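"""Histogram-based p-value correction by quadratic tail extrapolation.

An adapted Storey-Tibshirani procedure for nominal p-value distributions
that are not uniform under the null.  A quadratic density ``f_lambda`` is
fitted to the p-value histogram over [lambda, 1] for lambda = 0, 0.01, ...;
each fit yields a null-fraction estimate

    pi0(lambda) = integral_0^1 max(f_lambda, 0) dx      (density scale).

As lambda scans past the left-hand peak of alternative-hypothesis p-values
the estimates stabilize, so the optimal lambda is the one whose pi0 value is
closest to the mode of a kernel density estimate of all pi0(lambda) values.
Corrected p-values and q-values are ratios of integrals of the optimal
(floored-at-zero) quadratic:

    p_corr = I(p) / I(1),     q_corr = N * I(p) / #{p_i <= p},

with ``I(x) = integral_0^x max(f, 0)``.  ``q_corr(1) = pi0_hat``: calling
every gene yields an FDR equal to the null fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .flagpole import PValueSet

logger = logging.getLogger(__name__)


class TailTooShortError(ValueError):
    """Raised when fewer than the minimum number of histogram bins remain."""


class DegenerateFitError(ValueError):
    """Raised when the fitted density integrates to zero."""


@dataclass(frozen=True)
class HistogramSpec:
    """Equal-width histogram on [0, 1]; heights are densities."""

    bin_count: int = 100

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.bin_count + 1)

    @property
    def width(self) -> float:
        return 1.0 / self.bin_count


@dataclass(frozen=True)
class QuadraticFit:
    """f(x) = c0 + c1 x + c2 x^2 fitted to the histogram tail [lam, 1]."""

    coef: tuple  # (c0, c1, c2)
    lam: float
    sse: float
    n_bins: int


@dataclass
class PolyfitFit:
    """Full output of the correction: lambda scan, pi0, corrected p and q."""

    lambda_grid: np.ndarray
    pi0_values: np.ndarray
    lambda_opt: float
    pi0_hat: float
    fit_opt: QuadraticFit
    p_corr: np.ndarray
    q_corr: np.ndarray
    q_bh: np.ndarray
    pvals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.pvals)


def _as_pvalue_array(pvals) -> np.ndarray:
    if isinstance(pvals, PValueSet):
        p = pvals.p
    else:
        p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d vector")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def fit_tail_quadratic(pvals, lam: float, spec: HistogramSpec | None = None) -> QuadraticFit:
    """Least-squares quadratic through (bin midpoint, density) pairs on [lam, 1].

    The model is linear in its coefficients, so the minimizer of the sum of
    squared residuals is the closed-form linear least-squares solution.
    Requires at least 4 bins wholly inside [lam, 1].
    """
    p = _as_pvalue_array(pvals)
    spec = spec or HistogramSpec()
    heights, edges = np.histogram(p, bins=spec.bin_count, range=(0.0, 1.0), density=True)
    sel = edges[:-1] >= lam - 1e-9
    if sel.sum() < 4:
        raise TailTooShortError(
            f"only {int(sel.sum())} bins inside [{lam}, 1]; at least 4 required"
        )
    mids = (edges[:-1] + edges[1:])[sel] / 2.0
    y = heights[sel]
    design = np.vander(mids, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((design @ coef - y) ** 2))
    return QuadraticFit(coef=tuple(coef), lam=lam, sse=sse, n_bins=int(sel.sum()))


def _positive_breakpoints(coef) -> list[float]:
    """Roots of the quadratic strictly inside (0, 1)."""
    c0, c1, c2 = coef
    roots: list[float] = []
    if c2 != 0.0:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc > 0.0:
            sq = np.sqrt(disc)
            roots = sorted([(-c1 - sq) / (2.0 * c2), (-c1 + sq) / (2.0 * c2)])
    elif c1 != 0.0:
        roots = [-c0 / c1]
    return [float(r) for r in roots if 0.0 < r < 1.0]


def floored_quadratic_integral(coef, x) -> np.ndarray | float:
    """``I(x) = integral_0^x max(c0 + c1 t + c2 t^2, 0) dt`` for x in [0, 1].

    Evaluated analytically on the sign-partitioned intervals.
    """
    c0, c1, c2 = coef

    def anti(t):
        return c0 * t + c1 * t * t / 2.0 + c2 * t**3 / 3.0

    pts = np.array([0.0] + _positive_breakpoints(coef) + [1.0])
    mids = (pts[:-1] + pts[1:]) / 2.0
    positive = (c0 + c1 * mids + c2 * mids**2) > 0.0
    seg_full = np.where(positive, anti(pts[1:]) - anti(pts[:-1]), 0.0)
    cum = np.concatenate([[0.0], np.cumsum(seg_full)])

    x_arr = np.asarray(x, dtype=float)
    idx = np.clip(np.searchsorted(pts, x_arr, side="right") - 1, 0, len(pts) - 2)
    partial = np.where(positive[idx], anti(x_arr) - anti(pts[idx]), 0.0)
    out = cum[idx] + partial
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(x) else out


def pi0_of_lambda(fit: QuadraticFit) -> float:
    """Null-fraction estimate from one tail fit: area under the floored quadratic."""
    return float(floored_quadratic_integral(fit.coef, 1.0))


def _silverman_bandwidth(vals: np.ndarray) -> float:
    """Silverman's rule of thumb, h = 0.9 min(sd, IQR/1.34) n^(-1/5).

    The IQR alternative makes the bandwidth robust to the wild pi0 estimates
    produced by very short tails (lambda near 1), which would otherwise
    inflate a plain-sd bandwidth and wash out the stable mode.
    """
    sd = vals.std(ddof=1)
    iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(vals) ** (-0.2)


def select_lambda_opt(
    lambdas: np.ndarray, pi0_values: np.ndarray
) -> tuple[float, float]:
    """Pick the lambda whose pi0 estimate is nearest the KDE mode of all estimates.

    A Gaussian kernel density with Silverman's rule-of-thumb bandwidth is
    evaluated on a 512-point grid; ties are broken toward the smallest
    lambda.  Requires at least 5 valid grid points.

    Fits over very short tails (lambda near 1) can extrapolate to physically
    impossible null fractions (far above 1 or at 0); estimates outside
    [0, 1.5] are excluded from the density sample so they cannot drag the
    mode or inflate the bandwidth, but remain in the scan diagnostics.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    vals = np.asarray(pi0_values, dtype=float)
    if len(vals) < 5:
        raise TailTooShortError("tail too short to fit: fewer than 5 valid lambda points")
    order = np.argsort(lambdas, kind="stable")
    lambdas, vals = lambdas[order], vals[order]
    plausible = (vals >= 0.0) & (vals <= 1.5)
    if plausible.sum() >= 5:
        lambdas, vals = lambdas[plausible], vals[plausible]
    if np.ptp(vals) < 1e-12:
        return float(lambdas[0]), float(vals[0])
    try:
        h = _silverman_bandwidth(vals)
        kde = gaussian_kde(vals, bw_method=h / vals.std(ddof=1))
        grid = np.linspace(vals.min() - 3.0 * h, vals.max() + 3.0 * h, 512)
        mode = float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate spread
        mode = float(np.median(vals))
    i = int(np.argmin(np.abs(vals - mode)))  # argmin takes the smallest lambda on ties
    return float(lambdas[i]), float(vals[i])


def corrected_p(p, fit: QuadraticFit) -> np.ndarray | float:
    """Corrected p-value: ratio of floored-quadratic integrals I(p) / I(1)."""
    total = floored_quadratic_integral(fit.coef, 1.0)
    if total <= 0.0:
        raise DegenerateFitError(
            "fitted density integrates to zero; inspect the diagnostic plots"
        )
    out = np.clip(np.asarray(floored_quadratic_integral(fit.coef, p)) / total, 0.0, 1.0)
    return float(out) if np.isscalar(p) else out


def corrected_q(p, fit: QuadraticFit, pvals) -> np.ndarray | float:
    """Corrected q-value: estimated false calls over observed calls at p.

    ``q = N * I(p) / #{p_i <= p}``, capped at 1.  The count uses "<=" so the
    divisor is at least 1 at the smallest p-value.
    """
    all_p = np.sort(_as_pvalue_array(pvals))
    n = len(all_p)
    counts = np.searchsorted(all_p, np.asarray(p, dtype=float), side="right")
    false_calls = n * np.asarray(floored_quadratic_integral(fit.coef, p))
    q = np.minimum(false_calls / np.maximum(counts, 1), 1.0)
    return float(q) if np.isscalar(p) else q


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted p-values are scaled by N/rank, made monotone from the largest
    rank down, and capped at 1.
    """
    p = _as_pvalue_array(pvals)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def run_polyfit(
    pvals,
    spec: HistogramSpec | None = None,
    lambda_step: float = 0.01,
) -> PolyfitFit:
    """Full correction pipeline: lambda scan, mode selection, corrected p and q.

    Scans lambda from 0 towards 1 in steps of ``lambda_step``, skipping grid
    points with fewer than 4 usable bins.  ``pi0_hat`` outside [0, 1] is
    reported as-is with a warning, never clipped.
    """
    p = _as_pvalue_array(pvals)
    spec = spec or HistogramSpec()
    if len(p) < 1000:
        warnings.warn(
            f"only {len(p)} p-values; the tail fit is unreliable below ~1000",
            stacklevel=2,
        )
    grid = np.arange(0.0, 1.0, lambda_step)
    lambdas, pi0s = [], []
    for lam in grid:
        try:
            fit = fit_tail_quadratic(p, float(lam), spec)
        except TailTooShortError:
            continue
        lambdas.append(float(lam))
        pi0s.append(pi0_of_lambda(fit))
    lambdas = np.asarray(lambdas)
    pi0s = np.asarray(pi0s)
    lambda_opt, pi0_hat = select_lambda_opt(lambdas, pi0s)
    if not 0.0 <= pi0_hat <= 1.0:
        warnings.warn(
            f"pi0_hat = {pi0_hat:.4f} lies outside [0, 1]; inspect the diagnostic "
            "plots before trusting corrected values",
            stacklevel=2,
        )
    fit_opt = fit_tail_quadratic(p, lambda_opt, spec)
    logger.info("lambda_opt = %.2f, pi0_hat = %.4f", lambda_opt, pi0_hat)
    return PolyfitFit(
        lambda_grid=lambdas,
        pi0_values=pi0s,
        lambda_opt=lambda_opt,
        pi0_hat=pi0_hat,
        fit_opt=fit_opt,
        p_corr=corrected_p(p, fit_opt),
        q_corr=corrected_q(p, fit_opt, p),
        q_bh=bh_adjust(corrected_p(p, fit_opt)),
        pvals=p,
    )


def plot_diagnostics(fit: PolyfitFit, path: str, spec: HistogramSpec | None = None) -> None:
    """Write the four diagnostic panels to ``path``.

    (A) pi0(lambda) with the selected point, (B) KDE of the pi0 estimates,
    (C) original histogram with the fitted quadratic, (D) corrected histogram
    with the (flat) image of the quadratic under the correction map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = spec or HistogramSpec()
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    ax.plot(fit.lambda_grid, fit.pi0_values, "o", ms=3, color="0.4")
    ax.plot([fit.lambda_opt], [fit.pi0_hat], "o", color="red")
    ax.axhline(fit.pi0_hat, ls=":", color="black")
    ax.set_xlabel(r"$\lambda$")
    ax.set_ylabel(r"$\hat\pi_0(\lambda)$")

    ax = axes[0, 1]
    vals = fit.pi0_values
    if np.ptp(vals) > 1e-12:
        h = _silverman_bandwidth(vals)
        kde = gaussian_kde(vals, bw_method=h / vals.std(ddof=1))
        grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, 512)
        ax.plot(grid, kde(grid), color="0.2")
    ax.axvline(fit.pi0_hat, ls=":", color="red")
    ax.set_xlabel(r"$\hat\pi_0$")
    ax.set_ylabel("density")

    x = np.linspace(0, 1, 400)
    f_x = np.maximum(np.polyval(fit.fit_opt.coef[::-1], x), 0.0)
    ax = axes[1, 0]
    ax.hist(fit.pvals, bins=spec.bin_count, range=(0, 1), density=True, color="0.8")
    ax.plot(x[x < fit.lambda_opt], f_x[x < fit.lambda_opt], color="black")
    ax.plot(x[x >= fit.lambda_opt], f_x[x >= fit.lambda_opt], color="red")
    ax.set_xlabel("p")
    ax.set_ylabel("density")
    ax.set_title("original p-values")

    ax = axes[1, 1]
    ax.hist(fit.p_corr, bins=spec.bin_count, range=(0, 1), density=True, color="0.8")
    img_x = corrected_p(x, fit.fit_opt)
    flat = np.full_like(x, fit.pi0_hat)
    ax.plot(img_x[x < fit.lambda_opt], flat[x < fit.lambda_opt], color="black")
    ax.plot(img_x[x >= fit.lambda_opt], flat[x >= fit.lambda_opt], color="red")
    ax.set_xlabel(r"$p_{corr}$")
    ax.set_ylabel("density")
    ax.set_title("corrected p-values")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
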