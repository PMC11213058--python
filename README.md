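# exprland

Where are disease genes expressed? `exprland` implements a statistical
framework for locating the tissues and cell types in which
GWAS-prioritised disease genes are preferentially active, and for the
reverse question — whether the genes most expressed in a context carry
excess GWAS signal. It also quantifies how expression level relates to a
gene's odds of being a drug-development target.

## The scientific problem

Genome-wide association studies deliver lists of likely causal genes per
disease (nearest-to-hit genes, fine-mapped genes, genes prioritised by
similarity scores such as PoPS). Turning those lists into biology requires
knowing *where* the genes act. `exprland` tests, for every
tissue/cell-type context in an expression atlas, whether disease genes are
expressed higher than matched control genes — on two complementary layers:

- **Absolute expression** `A = log2(median TPM + 1)`: how much a gene is
  expressed in a context.
- **Relative expression** `R = A / Σ_contexts A`: how specific the gene's
  expression is to that context (0–1; 1 means exclusive).

Three tests per (context × gene-list × layer) triangulate the answer: a
one-sided Welch t-test, a two-sample Anderson–Darling test (sensitive to
shifts anywhere in the distribution, with uncapped asymptotic p-values),
and an exact/Monte-Carlo permutation test of the mean difference.
Disease-relevant contexts are those significant in **every** test at the
Bonferroni level `0.05 / (n_contexts × n_lists × n_tests)`.

The reverse arm assigns GWAS SNPs to genes over strand-aware windows
(35 kb upstream / 10 kb downstream, MHC excluded), forms a gene-level
association statistic by summing SNP chi-squares moment-matched against
local LD, and runs a MAGMA-style competitive regression of gene Z-scores
on top-decile expression-set membership plus length/SNP-count covariates.

Supporting modules cover TPM/TMM/quantile normalisation and pseudobulk
aggregation, LD clumping and gene-list construction, per-gene variance
partitioning across predictors (tissue, donor, …) with a crossed
random-intercepts REML fit, logistic odds of drug-program inclusion per
expression quantile, PubMed query construction, fully synthetic data
generators with known ground truth, and a pipeline CLI.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes oracle comparisons (scipy's Anderson–Darling, edgeR's
TMM factors frozen as fixtures, statsmodels logistic regression, exhaustive
enumeration for permutations and clumping) alongside property-based and
calibration tests.

## Worked example

Generate a synthetic atlas with a planted disease-gene elevation and scan
for the responsible context:

```python
from exprland.synthetic_data import SyntheticConfig, synth_expression
from exprland.gwas_to_expression import ScanConfig, run_scan, select_relevant_tissues

cfg = SyntheticConfig(seed=42)
profile, truth = synth_expression(cfg)
print("planted target context:", truth["target_contexts"][0])

res = run_scan(profile, [set(truth["disease_genes"])],
               ScanConfig(metrics=("absolute", "relative"), tests=("t", "AD")))
top = res.sort_values("p_value").head(5)
print(top[["context", "metric", "test", "p_value"]].to_string(index=False))

relevant = select_relevant_tissues(res, n_contexts=20, n_lists=1, n_tests=2)
print("relevant tissues:", relevant)
```

Output:

```
planted target context: context_03
   context   metric test      p_value
context_03 relative   AD 3.859307e-12
context_03 relative    t 1.105359e-06
context_03 absolute   AD 3.974544e-04
context_03 absolute    t 4.923810e-04
context_02 relative    t 1.268232e-01
relevant tissues: ['context_03']
```

The planted context is recovered on both layers, most strongly on relative
expression — the layer that normalises away each gene's baseline level.

The same end to end, via the CLI:

```bash
exprland run --seed 42 --outdir demo
# run complete -> demo
ls demo
# drug_odds.tsv  enrichment_results.tsv  expression_tpm.tsv  exprland.log
# manifest.json  scan_neglog10p_wide.tsv  scan_results.tsv  truth.json
# variance_fractions.tsv
```

Reruns with the same seed are byte-identical; `manifest.json` records the
config hash, seed and package version.

## Layout

- `src/exprland/expression_core.py` — TPM, QC, A/R layers, quantile bins,
  TMM, pseudobulk.
- `src/exprland/gene_sets.py` — GTF parsing, clumping, nearest-gene,
  PoPS top-1%, control lists.
- `src/exprland/gwas_to_expression.py` — the disease-gene scan (t, AD,
  permutation; sensitivity and triangulation).
- `src/exprland/expression_to_gwas.py` — SNP→gene windows, gene
  statistics, competitive enrichment.
- `src/exprland/variance_partition.py` — REML variance fractions and
  group comparison.
- `src/exprland/drug_development.py` — expression-quantile odds of
  drug-program inclusion.
- `src/exprland/literature_search.py` — PubMed query templates and
  counting with an injectable fetcher.
- `src/exprland/synthetic_data.py` — ground-truth generators.
- `src/exprland/pipeline.py`, `src/exprland/cli.py` — orchestration and
  the `exprland` command.

See `docs/methods.md` for the statistical model, parameter defaults and
numerical choices.
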