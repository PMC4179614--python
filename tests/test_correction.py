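"""Quadratic tail fitting, pi0 estimation, corrected p- and q-values, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyfitde.correction import (
    DegenerateFitError,
    HistogramSpec,
    QuadraticFit,
    TailTooShortError,
    bh_adjust,
    corrected_p,
    corrected_q,
    fit_tail_quadratic,
    floored_quadratic_integral,
    pi0_of_lambda,
    run_polyfit,
    select_lambda_opt,
)


def quad(c0, c1, c2, lam=0.0) -> QuadraticFit:
    return QuadraticFit(coef=(c0, c1, c2), lam=lam, sse=0.0, n_bins=100)


def pvals_with_exact_histogram(a, b, c):
    """p-values whose 100-bin histogram lies exactly on a quadratic.

    Places ``a + b(2j+1) + c(2j+1)^2`` p-values at the midpoint of bin j, so
    the density at midpoint m is exactly (100/N)(a + 200b m + 40000c m^2).
    """
    counts = [a + b * (2 * j + 1) + c * (2 * j + 1) ** 2 for j in range(100)]
    n = sum(counts)
    mids = (np.arange(100) + 0.5) / 100.0
    p = np.repeat(mids, counts)
    coef = (100.0 * a / n, 20000.0 * b / n, 4.0e6 * c / n)
    return p, coef


class TestFitTailQuadratic:
    def test_exact_quadratic_recovered(self):
        p, coef = pvals_with_exact_histogram(50, 1, 1)
        fit = fit_tail_quadratic(p, 0.0)
        assert np.allclose(fit.coef, coef, atol=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-15)

    def test_flat_histogram_gives_unit_density(self):
        p, _ = pvals_with_exact_histogram(10, 0, 0)
        fit = fit_tail_quadratic(p, 0.3)
        assert np.allclose(fit.coef, (1.0, 0.0, 0.0), atol=1e-9)
        assert pi0_of_lambda(fit) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_sample_integral_unbiased(self):
        # single-draw sampling sd of the extrapolated integral is ~0.027,
        # so test the mean of 10 independent fits at the same precision
        rng = np.random.default_rng(0)
        vals = [
            pi0_of_lambda(fit_tail_quadratic(rng.uniform(size=100_000), 0.5))
            for _ in range(10)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.03)

    def test_short_tail_rejected(self):
        with pytest.raises(TailTooShortError):
            fit_tail_quadratic(np.linspace(0, 1, 500), 0.97)

    def test_only_tail_bins_used(self):
        # perturbing p-values left of lambda must not change the fit
        p, _ = pvals_with_exact_histogram(10, 1, 0)
        fit1 = fit_tail_quadratic(p, 0.5)
        p2 = np.where(p < 0.45, p / 10.0, p)
        fit2 = fit_tail_quadratic(p2, 0.5)
        assert np.allclose(fit1.coef, fit2.coef, atol=1e-12)


class TestFlooredIntegral:
    def test_matches_quadrature(self):
        rng = np.random.default_rng(4)
        x_grid = np.linspace(0, 1, 100_001)
        for _ in range(25):
            coef = tuple(rng.uniform(-3, 3, 3))
            f = np.maximum(np.polynomial.polynomial.polyval(x_grid, coef), 0.0)
            for x in (0.2, 0.5, 1.0):
                idx = x_grid <= x
                expected = np.trapezoid(f[idx], x_grid[idx])
                assert floored_quadratic_integral(coef, x) == pytest.approx(
                    expected, abs=1e-6
                )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        c0=st.floats(-3, 3), c1=st.floats(-3, 3), c2=st.floats(-3, 3),
        x1=st.floats(0, 1), x2=st.floats(0, 1),
    )
    def test_monotone_and_nonnegative(self, c0, c1, c2, x1, x2):
        lo, hi = sorted((x1, x2))
        coef = (c0, c1, c2)
        i_lo = floored_quadratic_integral(coef, lo)
        i_hi = floored_quadratic_integral(coef, hi)
        assert 0.0 <= i_lo <= i_hi + 1e-12


class TestPi0OfLambda:
    def test_flat_unit_density(self):
        assert pi0_of_lambda(quad(1.0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_linear_density_2x(self):
        assert pi0_of_lambda(quad(0.0, 2.0, 0.0)) == pytest.approx(1.0)

    def test_flat_085(self):
        assert pi0_of_lambda(quad(0.85, 0.0, 0.0)) == pytest.approx(0.85)

    def test_negative_part_floored(self):
        # f = x - 0.5: only [0.5, 1] contributes, integral 0.125
        assert pi0_of_lambda(quad(-0.5, 1.0, 0.0)) == pytest.approx(0.125)


class TestSelectLambdaOpt:
    def test_constant_values_return_smallest_lambda(self):
        lams = np.arange(0, 0.1, 0.01)
        lam, pi0 = select_lambda_opt(lams, np.full(10, 0.9))
        assert lam == 0.0 and pi0 == 0.9

    def test_mode_of_contaminated_cluster(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([0.85 + rng.uniform(-0.005, 0.005, 60), np.full(5, 0.3)])
        lams = np.arange(len(vals)) * 0.01
        _, pi0 = select_lambda_opt(lams, vals)
        assert abs(pi0 - 0.85) < 0.01

    def test_wild_estimates_cannot_drag_mode(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [0.88 + rng.uniform(-0.01, 0.01, 50), [5.0, 42.0, 158.0, -3.0]]
        )
        lams = np.arange(len(vals)) * 0.01
        _, pi0 = select_lambda_opt(lams, vals)
        assert abs(pi0 - 0.88) < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(TailTooShortError, match="tail too short"):
            select_lambda_opt(np.array([0.0, 0.1]), np.array([0.9, 0.9]))


class TestCorrectedP:
    def test_constant_density_is_identity(self):
        p = np.linspace(0, 1, 11)
        for c in (0.2, 1.0, 3.0):
            assert np.allclose(corrected_p(p, quad(c, 0, 0)), p)

    def test_linear_density_hand_value(self):
        assert corrected_p(0.5, quad(0.0, 1.0, 0.0)) == pytest.approx(0.25)

    def test_endpoints_fixed(self):
        fit = quad(0.3, 1.0, -0.5)
        assert corrected_p(0.0, fit) == 0.0
        assert corrected_p(1.0, fit) == pytest.approx(1.0)

    def test_monotone_surjective(self):
        fit = quad(-0.2, 0.5, 1.0)  # negative near 0: floored region
        p = np.linspace(0, 1, 201)
        out = corrected_p(p, fit)
        assert np.all(np.diff(out) >= -1e-12)
        assert out[0] == 0.0 and out[-1] == pytest.approx(1.0)

    def test_zero_integral_raises(self):
        with pytest.raises(DegenerateFitError):
            corrected_p(0.5, quad(-1.0, 0.0, 0.0))


class TestCorrectedQ:
    def test_zero_density_gives_zero(self):
        pvals = np.linspace(0.01, 1, 100)
        assert corrected_q(0.3, quad(-0.5, 1.0, 0.0), pvals) == 0.0

    def test_hand_example(self):
        # f = 0.85, N = 1000, 200 p-values <= 0.01
        pvals = np.concatenate([np.full(200, 0.005), np.full(800, 0.5)])
        q = corrected_q(0.01, quad(0.85, 0, 0), pvals)
        assert q == pytest.approx(0.85 * 1000 * 0.01 / 200)

    def test_full_calling_returns_pi0(self):
        pvals = np.linspace(0, 1, 500)
        assert corrected_q(1.0, quad(0.85, 0, 0), pvals) == pytest.approx(0.85)


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_bounds_and_dominance(self, p):
        q = bh_adjust(p)
        assert np.all((0 <= q) & (q <= 1))
        assert np.all(q >= np.asarray(p) - 1e-15)


class TestRunPolyfit:
    def test_uniform_null_recovers_pi0_one(self):
        rng = np.random.default_rng(10)
        fit = run_polyfit(rng.uniform(size=100_000))
        assert 0.95 <= fit.pi0_hat <= 1.05
        # corrected p-values stay uniform
        from scipy.stats import kstest

        assert kstest(fit.p_corr, "uniform").statistic < 0.01

    def test_beta_mixture_recovers_pi0(self):
        rng = np.random.default_rng(12)
        n = 50_000
        n_alt = int(0.15 * n)
        p = np.concatenate(
            [rng.uniform(size=n - n_alt), rng.beta(0.05, 1.0, size=n_alt)]
        )
        fit = run_polyfit(p)
        assert abs(fit.pi0_hat - 0.85) < 0.05

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        p = rng.beta(0.3, 1.0, size=5000)
        perm = rng.permutation(len(p))
        fit1 = run_polyfit(p)
        fit2 = run_polyfit(p[perm])
        assert fit1.pi0_hat == fit2.pi0_hat
        assert np.allclose(fit1.p_corr[perm], fit2.p_corr)
        assert np.allclose(fit1.q_corr[perm], fit2.q_corr)
        assert np.allclose(fit1.q_bh[perm], fit2.q_bh)

    def test_few_pvalues_warns(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning, match="unreliable"):
            run_polyfit(rng.uniform(size=200))

    def test_q_corr_at_one_equals_pi0(self):
        rng = np.random.default_rng(15)
        p = np.concatenate([rng.uniform(size=9000), rng.beta(0.1, 1, size=1000), [1.0]])
        fit = run_polyfit(p)
        assert fit.q_corr[-1] == pytest.approx(min(fit.pi0_hat, 1.0), abs=1e-9)

    def test_histogram_spec_integrates_to_one(self):
        spec = HistogramSpec(bin_count=50)
        rng = np.random.default_rng(16)
        h, e = np.histogram(rng.uniform(size=2000), bins=spec.bin_count,
                            range=(0, 1), density=True)
        assert np.sum(h * np.diff(e)) == pytest.approx(1.0, abs=1e-9)
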