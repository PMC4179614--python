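# Methods

## The problem

Two-class RNA-seq differential-expression tests built on negative-binomial
(NB) count models have two well-known pathologies. First, the test statistic
— the total count of one condition, conditioned on the combined total — is
discrete, so the two-sided exact p-value equals 1 whenever the observation
lands on the mode of the conditional null distribution, producing a spike
("flagpole") at p = 1 in the p-value histogram. Second, because the NB
parameters must be estimated from a handful of replicates, the null p-value
distribution is not uniform even after the spike is removed; it is typically
skewed towards 1. Benjamini–Hochberg q-values computed from such p-values
misestimate the false discovery rate (FDR), and no direct estimate of the
null fraction π₀ is available.

`polyfitde` implements the full chain: an exact conditional NB test, a
randomized p-value that is exactly uniform under the discrete null, and a
polynomial-fit adaptation of the Storey–Tibshirani procedure that estimates
π₀ from the right tail of the (non-uniform) p-value histogram and converts
p-values to corrected p- and q-values. A synthetic-data generator with known
truth labels and a true-FDR evaluation harness complete the package.

## Exact conditional test

Counts K_ij for gene i, sample j are modelled as NB with mean s_j·μ_i and
overdispersion φ_i, where Var(Y) = E(Y) + φ·E(Y)². Size factors s_j are
median-of-count-ratios: the median over zero-free genes of the ratio of a
gene's count to its geometric mean across samples.

Per gene, μ is the mean of common-scale counts K_ij/s_j pooled over all
samples; the variance is the pooled within-condition sample variance (sums
of squares about each condition's own mean, divided by n − 2), so
differential expression between the conditions does not inflate the
dispersion estimate. The dispersion solves Var(K/s) = μ·E(1/s) + φμ² and is
floored at 1e-8. Optionally (default on), a lowess trend of raw dispersion
on log mean is fitted and the per-gene maximum of raw and trend values
taken. This mirrors the "maximum" sharing mode of the established NB
packages: per-gene moment estimates from 3–10 replicates are very noisy, and
taking the maximum deliberately errs conservative. The resulting
right-skewed null p-value histogram is exactly the regime the histogram
correction is designed for, and the skew disappears when true parameters are
supplied (verified by the uniformity tests).

A sum of NB replicates with unequal size factors is not NB; each condition's
replicate-sum is therefore moment-matched to a single NB with mean
Σ_j s_j μ and variance Σ_j (s_j μ + φ(s_j μ)²), falling back to Poisson when
the variance does not exceed the mean. With equal size factors the matched
distribution is exact (a sum of iid NB sharing the success probability is
NB). The conditional null of the condition-A sum a given total k is

    P_K(a) ∝ pmf_A(a) · pmf_B(k − a),  a = 0..k,

evaluated in log space (gamma-function pmfs, so non-integer size parameters
are fine). The two-sided p-value sums P_K(a) over all apportionments whose
probability is ≤ the observed one. Probability ties are detected with a
relative tolerance of 1e-9; without a tolerance, exactly symmetric models
tie only up to float rounding and results would depend on summation order.
For totals up to 50,000 the support is enumerated in full; beyond that the
support window is pruned where either marginal carries < 1e-13 per-tail
mass, and the window is re-normalized (truncation error < 1e-12).
Zero-total genes are flagged degenerate and given p = 1.

## Flagpole removal

For an observed value k of a discrete statistic K with pmf P and cdf F, the
randomized two-sided p-value is

    p = 2 · min(F(k−1) + U·P(k), 1 − F(k−1) − U·P(k)),  U ~ Uniform[0,1].

F(k−1) + U·P(k) is a uniform draw from the cumulative slot of the observed
outcome, hence exactly Uniform[0,1] under the null; the two-sided value is
twice the smaller tail. Note this is a different two-sided convention than
the probability-ordering sum of the exact test — both are standard, and both
are implemented exactly as defined; they are not unified. One independent U
is drawn per gene, so a seed must be fixed for reproducible output (exposed
everywhere as `--seed`/`seed`). Degenerate genes receive 2·min(U, 1−U), a
uniform draw, rather than a constant 1 that would re-introduce a spike.

## Histogram correction

With 100 equal bins on [0,1] (matching the 0.01 pitch of the λ grid;
configurable) and heights on the density scale:

1. For λ = 0, 0.01, …, a quadratic f_λ(x) = c₀ + c₁x + c₂x² is fitted by
   least squares to the (bin midpoint, density) pairs of bins wholly inside
   [λ, 1]. The model is linear in its coefficients, so the closed-form
   linear least-squares solution minimizes the same sum-of-squares objective
   an iterative optimizer would. Grid points with fewer than 4 usable bins
   are skipped. Each fit yields π̂₀(λ) = ∫₀¹ max(f_λ, 0) dx, evaluated
   analytically on the sign-partitioned intervals (the floor at zero
   guarantees corrected p-values in [0,1] and monotone).
2. λ_opt is the grid point whose π̂₀(λ) is closest to the mode of a Gaussian
   kernel density estimate of the π̂₀(λ) sample (512-point grid; smallest λ
   on ties). The bandwidth is Silverman's rule of thumb,
   h = 0.9·min(sd, IQR/1.34)·n^(−1/5). Two robustness details matter in
   practice: the IQR branch of Silverman's rule (not a plain-sd variant),
   and exclusion of physically impossible π̂₀ values (outside [0, 1.5],
   produced by near-degenerate fits as λ → 1) from the mode-finding sample.
   Without these, a handful of wild tail fits can inflate the bandwidth and
   drag the mode off the stable plateau. Excluded values remain in the
   diagnostics.
3. Corrected values, with I(x) = ∫₀ˣ max(f_λopt, 0) and N p-values:
   p_corr = I(p)/I(1); q_corr = N·I(p)/#{p_i ≤ p}, capped at 1. The count
   uses ≤ so the divisor is at least 1 at the smallest p-value (a strict <
   is not computable there). q_corr is reported raw, without monotonicity
   enforcement; a Benjamini–Hochberg pass over p_corr (q_bh) is provided
   alongside. At p = 1, q_corr = π̂₀: calling everything yields an FDR equal
   to the null fraction.

π̂₀ > 1 is possible in principle; it is reported as-is with a warning and
never silently clipped (100·(1−π̂₀) then goes negative). The four
diagnostic panels (π̂₀ vs λ; π̂₀ density; original histogram with fitted
quadratic; corrected histogram with its flat image) are available from
`plot_diagnostics` / `correct --plots`.

Rejected variants: cubic and rational fitting functions, and fitting over
[λ, 0.9] without flagpole removal, are deliberately out of scope.

## Synthetic data

Control counts are drawn per gene × replicate from the chosen family with
mean Λ_j·μ_i and overdispersion φ_i; treatment counts use mean θ_i·Λ'_j·μ_i
with unchanged φ_i and an independent second set of library factors.
Library factors model sequencing-depth variation, log₂Λ ~ N(0,1), shared
across genes within a replicate; the geometric mean of total counts then
converges to Σμ_i (defaults: 1e7). A fraction of genes (regulated count =
round(frac·t) forced even, rounding half-up then decrementing if odd) is
split into equal up- and down-regulated subsets with θ = 2 + Exp(1) and
θ = (2 + Exp(1))⁻¹, so every regulated gene changes by at least a factor
of 2 and the mean up-factor is 3.

Families: NB, and Poisson–inverse-Gaussian (PIG) — Y | Z ~ Poisson(mZ) with
Z inverse-Gaussian of mean 1 and shape 1/φ, giving Var(Y) = m + φm², the
same first two moments as the NB at heavier-tailed shape. φ = 0 genes fall
back to Poisson in both families. Genes are independent; inter-gene
correlation is intentionally not modelled.

When no estimated parameter table is supplied, a meta-sampler provides one:
log-normal means (sdlog 2 in natural log, spanning roughly four orders of
magnitude, rescaled to sum exactly to the target total) and
gamma-distributed overdispersions (shape 1.2, scale 0.15, mean 0.18 —
typical of bulk human replicate data). This emulates the marginal
mean/dispersion profile of a deep human RNA-seq experiment; it does not
emulate mean-dependent dispersion trends, inter-gene correlation, partially
regulated genes (every simulated gene is either null or ≥2-fold regulated),
or any mapping/annotation artefacts. Results on this generator therefore
demonstrate correctness of the procedure under its own model assumptions,
not performance on arbitrary real data, where the null/alternative split
can be genuinely ambiguous.

## Evaluation

The "true FDR" at rank r of a ranking is FP/(FP+TP) over the first r genes,
computed from truth labels; ties in p-values are broken by input order
(stable sort) for determinism. At full calling the curve ends at the null
fraction of the gene set exactly. The percent-DE estimate is 100·(1−π̂₀).
`compare_methods` assembles long-format true/estimated FDR tables for any
set of rankings (e.g. externally produced p-values read from a file), with
an optional zoomed cut at a configurable rank.

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` run transcriptome-scale studies
at t = 20,000 genes, 4 vs 4 replicates, 15% DE (10 and 5 independent seeds
respectively); one run takes roughly 10 s. Under those conditions π̂₀ is
recovered within 0.85 ± 0.07 on every seed (observed spread ≈ 0.87–0.90 —
the mild overestimate at high DE fractions is expected: the quadratic
cannot capture the small left-hand spike of the null histogram, and weakly
regulated genes leak density into the tail), and the corrected null-gene
p-values are closer to uniform than the nominal ones on every seed.
Flagpole uniformity is checked on 10,000 null genes with known parameters
and equal library factors, making the conditional null exact so that the
randomization is the only thing under test. Generator moments are verified
within 3 standard errors at 1e5 draws, with the standard error of the
sample variance estimated from the empirical fourth moment.

## Known limitations

- Exact numerical parity with any specific NB package's p-values is not
  attempted; dispersion estimation differs in detail from each of them.
- The correction assumes the null histogram is well approximated by a
  quadratic on [λ_opt, 1] and extrapolates it to [0, λ_opt]; a pronounced
  left-hand null spike is attributed to signal, which can overstate
  significance at very low DE fractions.
- Multi-group designs, GLM-style tests and TMM normalization are out of
  scope; the method is two-class by construction.
- q_corr is not monotone in p by construction; use q_bh when monotonicity
  is required.
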