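# polyfitde

Two-class differential-expression analysis for RNA-seq count tables, with
honest false-discovery-rate estimates when the null p-value distribution is
not uniform.

Given a genes × samples table of integer read counts under two conditions,
the package:

1. culls low-count genes (mean ≤ 1 count per sample) and normalizes with
   median-of-count-ratios size factors;
2. tests each gene with an **exact conditional negative-binomial test**: the
   condition-A replicate-sum count, conditioned on the combined total k,
   with two-sided p-value
   `p = Σ_{π(a, k−a) ≤ π(k_A, k_B)} π(a, k−a) / Σ_a π(a, k−a)`,
   where π is the product of moment-matched NB pmfs for the two condition
   sums (`Var(Y) = E(Y) + φ E(Y)²`);
3. removes the discrete-distribution spike at p = 1 with the **randomized
   p-value** `p = 2·min(F(k−1) + U·P(k), 1 − F(k−1) − U·P(k))`,
   `U ~ Uniform[0,1]`, which is exactly uniform under the discrete null;
4. corrects the remaining non-uniformity with a polynomial-fit adaptation of
   the Storey–Tibshirani procedure ("Polyfit"): a quadratic f_λ is fitted to
   the p-value histogram over [λ, 1] for λ = 0, 0.01, …, the stable λ is
   picked at the mode of a kernel density of the π̂₀(λ) = ∫₀¹ max(f_λ,0)
   estimates, and corrected values follow as
   `p_corr = ∫₀ᵖ f / ∫₀¹ f` and `q_corr = N·∫₀ᵖ f / #{p_i ≤ p}`,
   along with Benjamini–Hochberg q-values of p_corr. The fitted area is a
   direct estimate of the null fraction π₀ (and hence of the percentage of
   DE genes, 100·(1 − π̂₀)).

A synthetic-data generator (negative-binomial and Poisson–inverse-Gaussian
overdispersed counts, log-normal library-size factors, known ≥2-fold
regulation labels) and a true-FDR evaluation harness are included, so every
estimate the package reports can be benchmarked against known truth.

Intended users: bioinformaticians analysing two-class bulk or single-cell
count tables who want a π₀ estimate and FDR curves that track the realized
FP/(FP+TP), and methods developers who need a self-contained, seedable
overdispersed-count benchmark.

## Worked example

Simulate 5,000 genes with 15% truly regulated, analyse, and score against
the truth:

```sh
polyfit-de simulate --genes 5000 --reps 4 --frac-de 0.15 \
    --target-total 2e6 --seed 11 --out-prefix demo
polyfit-de test demo_counts.tsv \
    --conditions control,control,control,control,treatment,treatment,treatment,treatment \
    --seed 1 --out results.tsv
polyfit-de correct results.tsv --out corrected.tsv
polyfit-de evaluate corrected.tsv demo_truth.tsv --out curves.tsv
```

which prints

```
wrote demo_counts.tsv, demo_truth.tsv
wrote results.tsv (4908 genes)
pi0_hat=0.8953 lambda_opt=0.14
estimated percent DE = 10.47
wrote curves.tsv
```

4,908 of 5,000 genes survive the low-count cull. The correction estimates
that 89.5% of genes are null (true value here: 85%; a mild overestimate at
high DE fractions is characteristic of the quadratic extrapolation), i.e.
about 10.5% differentially expressed. `corrected.tsv` carries per-gene
columns `baseMeanA, baseMeanB, foldChange, pval, p_corr, q_corr, q_bh` under
`#` header lines recording `pi0_hat` and `lambda_opt`. The evaluation table
confirms the q-values track the realized FDR: at rank 100 the true FDR is
0.00 against an estimated 0.009; at rank 600 it is 0.22 against an estimated
0.25.

The same pipeline is available programmatically:

```python
from polyfitde import simulate_and_analyze
res = simulate_and_analyze(t=20_000, n=4, frac_de=0.15, seed=0)
print(res.fit.pi0_hat)          # ~0.88
print(res.table[["pval", "p_corr", "q_corr"]].head())
```

Externally produced p-values (one per line) can be corrected directly with
`polyfit-de correct pvalues.txt --out corrected.tsv`, and
`correct --plots panels.png` writes the four diagnostic panels (π̂₀ vs λ,
π̂₀ density, original and corrected histograms with the fitted quadratic).

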