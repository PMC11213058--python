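# Methods

This document states the statistical model each module implements, the
parameter defaults with their rationale, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## Expression layers

Input is a gene × context matrix of TPM (transcripts per million). When
starting from counts, `compute_tpm` divides by transcript length in kb,
scales to 1e6 per context, and every TPM matrix is additionally passed
through `rescale_context` so each context column sums to exactly 1e6 —
this guards against upstream matrices that were filtered after
normalisation.

- **Absolute expression** `A = log2(TPM + 1)` (for atlas-style inputs the
  TPM value is the per-context median over samples). The +1 keeps zeros at
  zero and compresses high values on the familiar log2 scale.
- **Relative expression** `R_gc = A_gc / Σ_c' A_gc'`. Rows with zero total
  have undefined R; they are flagged (`r_defined`) rather than filled, and
  downstream consumers decide (the scan fills 0 only where a value is
  required).

**Quantile bins.** Genes unexpressed in a context form bin 1; expressed
genes are split into deciles of their rank, `bin = ceil(rank·10/n)`, with
tied blocks assigned by their mean rank so ties never straddle a
boundary. "Top decile" always means bin 11.

**QC.** Contexts need ≥ 100 samples (atlas default); genes restricted to
protein-coding; silent genes (zero everywhere) dropped; every removal
logged.

**TMM.** Trimmed mean of M-values follows the reference algorithm
exactly: log-ratio trim 0.3, sum trim 0.05, inverse-variance weights
(asymptotic binomial variance), reference column = the one whose upper
quartile is closest to the mean upper quartile, factors normalised to
geometric mean 1. Verified against edgeR's `calcNormFactors` to 6
decimals; those values are frozen as test fixtures.

**Pseudobulk.** Cell-level counts are summed per cell type; the absolute
layer is counts-per-million rescaled to exactly 1e6 per cell type (keeping
the column-sum invariant), while the cell-specificity layer is computed
from TMM-scaled shares, which is where composition correction matters.
Outlier cells are flagged at median + 5 MAD of library size.

## Gene lists

- **Clumping.** Greedy by ascending p: take the best remaining variant if
  p ≤ 5e-8, remove neighbours within ±250 kb on the same chromosome with
  r² ≥ 0.5 *and* p < 0.01 (the membership threshold; less-associated
  neighbours are left to seed other loci). Verified against an exhaustive
  reference on random instances.
- **Nearest gene.** Distance 0 inside a gene body, otherwise distance to
  the nearer boundary; ties broken by gene id for determinism.
- **PoPS.** Top 1% of scored genes, `ceil(0.01·n)`, ties broken by id.
- **Controls.** All protein-coding genes, a curated gold-standard list, or
  genes with Open Targets L2G ≥ 0.8 (inclusive).

## Disease-gene scan (expression side)

Per (context × list × layer), disease genes are compared against all other
genes on the layer's values (log2 of R for the relative layer, restricted
to expressed genes) with:

1. **Welch one-sided t-test** (disease > control).
2. **Two-sample Anderson–Darling** (Scholz–Stephens `A²akN` with midrank
   ties, standardised). The asymptotic p comes from a quadratic fit of
   the standardised statistic to the published critical values between
   levels 0.25 and 0.001, extrapolated linearly in log p beyond the table
   — p-values are never floored at 0.001. Statistic verified against an
   independent implementation to 1e-10.
3. **Permutation test** of the mean difference: exact enumeration whenever
   `C(n, k) ≤ 10,000`, otherwise Monte-Carlo with the add-one estimator
   `(b+1)/(m+1)`.

A context is **disease-relevant** when every test is below
`0.05 / (n_contexts × n_lists × n_tests)` — an intersection over tests,
stricter than any single test. Triangulation reports the Pearson
correlation of −log10(min p) profiles between test families; a sensitivity
mode repeats the scan with the top 1% most-expressed genes removed.

## GWAS enrichment (reverse side)

SNPs map to genes over strand-aware windows (35 kb upstream, 10 kb
downstream — asymmetric because regulatory elements concentrate upstream),
clipped at position 1; the MHC (chr6:25–35 Mb) loses its variants and any
overlapping gene window. The gene statistic is `T = Σ χ²₁(pᵢ)` with null
variance `2m + 4 Σ_{i<j} ρ²ᵢⱼ` (Brown's approximation for correlated
chi-squares; the coefficient 4 is forced by the r² = 1 limit, where two
duplicate SNPs must reproduce the single-SNP p exactly). T is referred to
a moment-matched scaled chi-square and the gene Z is the probit of the
resulting p. The competitive test regresses Z on top-decile membership
with gene length and SNP count (raw and logged) as covariates; one-sided
t on the membership coefficient; sets smaller than 10 genes are reported
as NA with a reason rather than tested.

## Variance partitioning

Per gene, expression across samples follows a linear mixed model with one
crossed random intercept per categorical predictor and fixed effects for
continuous predictors. Fractions are
`σ²_j / (Σ σ² + σ²_fixed + σ²_resid)`, where `σ²_fixed` is the variance of
the fitted fixed-effect predictor, so continuous predictors receive a
share; fractions are non-negative and sum to 1 for converged genes.

The REML fitter proposes both an EM update and an average-information
(Newton-type) update each iteration and keeps the one with the higher
restricted likelihood; variance components are clipped at zero and pinned
to zero below 1e-10·var(y). Plain EM alone crawls (thousands of
iterations) when a component sits on the zero boundary; the AI step
converges there in tens of iterations. Convergence: |Δ restricted
log-likelihood| < 1e-6, max 200 iterations; non-converged genes are
reported NaN and excluded from group comparisons.

Before fitting, predictor pairs whose squared first canonical correlation
(on one-hot/centred encodings) reaches 0.75 are pruned, keeping the member
with larger mean variance explained over a pilot subset of 20 genes.
Disease-versus-control differences in fractions use the two-sided
Mann–Whitney test.

Note on recovery summaries: averaging per-gene *fractions* carries a
Jensen (ratio) bias — with 10 tissue levels at n = 200 samples the mean
tissue fraction sits ≈ 0.03 below truth even though the underlying
variance components are unbiased. Recovery statistics therefore use the
mean absolute error across predictors of the gene-averaged fractions.

## Drug-development odds

A gene is labelled 1 if it appears in ≥ 1 drug-development program.
Expression within a disease-relevant tissue is converted to quantile
scores (average ranks, `ceil(rank·Q/n)`, ties share a score; Q = 10 and
100 both reported — quantile coding makes the odds ratio invariant to
monotone transforms of expression). Logistic regression of the label on
the score gives the OR per one-quantile increase with Wald 95% CI; plain
Newton/IRLS, falling back to Firth (Jeffreys-prior) penalisation when the
fit diverges (|β| > 30, a separation signature), so complete separation
still yields finite estimates. Fits require ≥ 20 genes and both label
classes; verified against statsmodels GLM.

## Literature queries

Tissue–disease PubMed queries use two templates —
`<tissue> [Mesh] AND <disease> [Mesh]` and
`<tissue> [Title/Abstract] AND <disease> [Title/Abstract]` — rendered for
the Cartesian product of term lists. Counting goes through an injectable
fetcher (recorded TSV offline; any HTTP client live); duplicate queries
are memoised, failures become NA rows, and no statistic is computed on
counts — they are descriptive evidence only.

## Synthetic data: what it emulates, and what it does not

Defaults are study-scale stand-ins, not copies of public datasets:

| parameter | default | rationale |
| --- | --- | --- |
| `n_genes` | 2000 | stands in for the protein-coding genome at desk scale |
| `n_contexts` | 20 | a tissue-panel-sized atlas |
| `baseline_mean`, `baseline_sd` | 3.0, 2.0 | log2 TPM baselines spanning silent to highly expressed |
| `context_sd` | 0.5 | moderate context-to-context wobble around baseline |
| `n_disease_genes`, `shift` | 150, 1.0 | typical prioritised-list size; conservative +1 log2 elevation |
| `dropout` | 0.3 | zeros applied *before* rescaling so zero-handling is exercised |
| `ld_block_size`, `ld_rho` | 20, 0.8 | AR(1) LD blocks with realistic short-range decay |
| `noncentrality` | 7.0 | mean Z in disease-gene windows, comfortably genome-wide significant |
| `vp_sigma2` | (0.5, 0.2, 0.3) | tissue/donor/residual variance truth |
| `drug_alpha`, `drug_beta` | −1.0, 0.2 | ≈27% base inclusion, OR e^0.2 ≈ 1.22 per decile |

Emulated: planted expression elevation with dropout, blockwise LD with
localised GWAS signal, crossed random-effect structure, logistic
label-expression coupling, negative-binomial single-cell counts with
planted markers and donor effects. **Not** emulated: realistic gene-length
and GC biases, expression correlation between neighbouring genes,
population LD beyond AR(1) blocks, sample-size imbalance across
tissues, pleiotropy across diseases, or any real gene/variant identifiers.
Conclusions about real tissues cannot be drawn from the synthetic runs;
they validate the machinery, not the biology.

All generators derive their streams from
`SeedSequence([seed, salt])` with a distinct salt per generator, so stages
are independently reproducible under one seed.

## Numerical choices

- AD p-values: quadratic interpolation of the critical-value table in the
  standardised statistic, linear log-p extrapolation outside it; no floor.
- SNP p-values are clipped at 1e-300 before the χ² transform (with a
  warning); gene p-values clipped to [1e-300, 1].
- Permutation exactness threshold `C(n,k) ≤ 10,000` balances exactness
  against runtime; Monte-Carlo p uses the add-one estimator, never 0.
- Ties everywhere resolve by average rank (binning, quantile scores, AD
  midranks); ordering ties break by gene/variant id for determinism.
- REML: see above (AI + EM hybrid, boundary pinning, 1e-6 tolerance).
- OLS in the competitive test drops constant or collinear covariates with
  a warning instead of failing.
- Output TSVs are written with `%.10g` floats so reruns are byte-stable.

## Limitations

- The gene statistic uses Brown's two-moment approximation, not the exact
  distribution of a correlated chi-square sum; extreme-tail gene p-values
  are approximate.
- The AD asymptotic p is an interpolation; for tiny samples the
  permutation mode is the honest choice.
- The competitive test's OLS inference assumes homoskedastic residuals
  across genes, as in standard MAGMA-style property analyses.
- Variance-fraction point estimates are per-gene noisy at n = 200; only
  averages over many genes are interpretable (and carry the ratio bias
  noted above).
- PubMed counts are reported without multiplicity or denominator
  adjustment; they support narrative review only.
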