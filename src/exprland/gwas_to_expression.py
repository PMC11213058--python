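"""Per-context comparison of disease-gene vs control-gene expression.

For every context (tissue or cell type), disease-gene expression — absolute
``log2(TPM+1)`` or relative specificity — is compared against the control
genes expressed in that context with three tests:

* a one-sided Welch t-test (alternative: disease genes are *higher*);
* the two-sample Anderson–Darling test, which is sensitive to differences
  in the distribution tails, with midrank tie correction;
* an empirical permutation test of the mean difference, used where sample
  non-independence (e.g. few donors behind many cell types) invalidates the
  t-test's assumptions.

The module also handles Bonferroni multiplicity, the "top expressed genes
excluded" sensitivity re-test, relevant-tissue selection for the drug arm,
and triangulation correlations between testing approaches.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression_core import ExpressionProfile, top_fraction_genes

logger = logging.getLogger(__name__)

__all__ = [
    "t_test_higher",
    "anderson_darling_2sample",
    "permutation_test",
    "run_scan",
    "sensitivity_exclude_top",
    "select_relevant_tissues",
    "triangulate",
    "metric_values",
    "results_to_wide",
]


# ---------------------------------------------------------------------------
# Two-sample tests


def t_test_higher(disease_vals, control_vals) -> tuple[float, float]:
    """Welch t-test with the one-sided alternative disease > control."""
    x = np.asarray(disease_vals, dtype=float)
    y = np.asarray(control_vals, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            warnings.warn("zero variance in both groups with equal means; p = 0.5")
            return 0.0, 0.5
    res = sps.ttest_ind(x, y, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def _ad_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised 2-sample Anderson–Darling statistic with midrank ties.

    The tie-adjusted rank statistic A²ₐ of Scholz & Stephens, standardised by
    its exact null mean (k−1) and variance so the value is comparable across
    sample sizes.
    """
    k = 2
    samples = [np.sort(np.asarray(x, dtype=float)), np.sort(np.asarray(y, dtype=float))]
    n = np.array([len(s) for s in samples])
    N = int(n.sum())
    pooled = np.sort(np.concatenate(samples))
    z, counts = np.unique(pooled, return_counts=True)
    L = len(z)
    if L < 2:
        return float("nan")
    lj = counts.astype(float)
    # B_j: midrank cumulative count of the pooled sample at each distinct value
    Bj = np.cumsum(lj) - lj / 2.0
    a2 = 0.0
    for i, s in enumerate(samples):
        # count of sample i strictly below each z plus half the ties at z
        below = np.searchsorted(s, z, side="left").astype(float)
        at = (np.searchsorted(s, z, side="right") - below).astype(float)
        Mij = below + at / 2.0
        num = (N * Mij - n[i] * Bj) ** 2
        den = Bj * (N - Bj) - N * lj / 4.0
        inner = np.where(den > 0, lj / N * num / den, 0.0)
        a2 += inner.sum() / n[i]
    a2 *= (N - 1) / N
    # exact null variance of A2kN (Scholz & Stephens)
    H = float((1.0 / n).sum())
    h = float(np.sum(1.0 / np.arange(1, N)))
    i_idx = np.arange(1, N - 1, dtype=float)
    inner_tail = np.cumsum(1.0 / np.arange(1, N)[::-1])[::-1]  # sum_{j=i}^{N-1} 1/j
    g = float(np.sum(inner_tail[1:] / (N - i_idx)))  # sum_i 1/(N-i) * sum_{j>i} 1/j
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k ** 2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k ** 2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k ** 2 - 4 * h * k
    var = (a * N ** 3 + b * N ** 2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    if var <= 0:
        return float("nan")
    return float((a2 - (k - 1)) / math.sqrt(var))


# critical-value coefficients (k-sample AD, m = k-1) at the tabulated levels
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, -0.154])


def _ad_pvalue_asymptotic(tm: float, k: int = 2) -> float:
    """Interpolated (and smoothly extrapolated) tail probability for the
    standardised statistic, from the tabulated critical points."""
    m = k - 1
    crit = _AD_B0 + _AD_B1 / math.sqrt(m) + _AD_B2 / m
    coef = np.polyfit(crit, np.log(_AD_SIG), 2)
    logp = np.polyval(coef, tm)
    if tm > crit[-1]:
        # beyond the table keep the tail monotone: linear continuation of the
        # fitted curve's slope at the last tabulated point
        slope = 2 * coef[0] * crit[-1] + coef[1]
        logp = np.polyval(coef, crit[-1]) + slope * (tm - crit[-1])
    return float(min(1.0, math.exp(max(logp, -700.0))))


def anderson_darling_2sample(x, y, mode: str = "asymptotic",
                             n_perm: int = 1000,
                             rng: np.random.Generator | None = None
                             ) -> tuple[float, float]:
    """Two-sample Anderson–Darling test (midrank tie correction).

    Returns the standardised statistic and a p-value, either from the
    asymptotic interpolation of the tabulated null percentiles or from a
    label-permutation null (``mode="permutation"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return 0.0, 1.0
    tm = _ad_statistic(x, y)
    if mode == "permutation":
        rng = rng or np.random.default_rng()
        nx = len(x)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _ad_statistic(perm[:nx], perm[nx:]) >= tm:
                count += 1
        return tm, (1 + count) / (n_perm + 1)
    return tm, _ad_pvalue_asymptotic(tm)


def permutation_test(values: pd.Series, disease_set, n_perm: int = 10_000,
                     seed: int | np.random.Generator | None = None,
                     statistic: str = "mean_diff",
                     exact_limit: int = 10_000) -> float:
    """Empirical p-value that the disease genes' mean expression is higher.

    Gene labels are permuted; the Monte-Carlo p-value uses the
    (1 + #{perm ≥ obs}) / (n_perm + 1) convention.  When the number of
    distinct disease/control splits is at most ``exact_limit`` the test
    enumerates them all and the p-value is exact.
    """
    if statistic != "mean_diff":
        raise ValueError("only the mean-difference statistic is supported")
    disease_set = set(disease_set)
    if not disease_set:
        raise ValueError("disease set is empty")
    is_disease = values.index.isin(disease_set)
    k = int(is_disease.sum())
    if k == 0:
        raise ValueError("no disease gene has a measured value")
    v = values.to_numpy(dtype=float)
    n = len(v)
    if k == n:
        raise ValueError("disease set covers every measured gene")
    total = v.sum()

    def mean_diff(subset_sum: float) -> float:
        return subset_sum / k - (total - subset_sum) / (n - k)

    obs = mean_diff(v[is_disease].sum())
    n_splits = math.comb(n, k)
    if n_splits <= exact_limit:
        count = sum(1 for idx in combinations(range(n), k)
                    if mean_diff(v[list(idx)].sum()) >= obs - 1e-12)
        return count / n_splits
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    # mean_diff is monotone in the subset sum: permute and sum the first k
    draws = np.empty(n_perm)
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)[:, :k]
        draws[done:done + b] = v[order].sum(axis=1)
        done += b
    count = int(np.sum([mean_diff(s) >= obs - 1e-12 for s in draws]))
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Scan orchestration


def metric_values(profile: ExpressionProfile, context, metric: str,
                  log2_relative: bool = True) -> pd.Series:
    """Per-gene values of a metric in one context, restricted to genes
    expressed there.

    Relative expression is log2-transformed by default (genes expressed in
    the context have R > 0, so the transform is finite).
    """
    expressed = profile.expressed_mask[context]
    if metric == "absolute":
        return profile.A.loc[expressed, context]
    if metric == "relative":
        r = profile.R.loc[expressed, context]
        r = r.dropna()
        return np.log2(r) if log2_relative else r
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class ScanConfig:
    metrics: tuple[str, ...] = ("absolute", "relative")
    tests: tuple[str, ...] = ("t", "AD")
    n_perm: int = 10_000
    log2_relative: bool = True
    alpha: float = 0.05


def run_scan(profile: ExpressionProfile, gene_lists, config: ScanConfig | None = None,
             seed: int | None = None, control_genes=None) -> pd.DataFrame:
    """Test every (context × gene list × metric × test) combination.

    Controls default to all genes expressed in the context minus the disease
    genes; pass ``control_genes`` to override (e.g. gold-standard or L2G
    controls).  Returns one row per combination with the statistic, p-value
    and a Bonferroni flag at alpha / n_rows.
    """
    config = config or ScanConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for context in profile.context_ids:
        for gl in gene_lists:
            dset = gl.as_set() if hasattr(gl, "as_set") else set(gl)
            lname = getattr(gl, "name", "genes")
            for metric in config.metrics:
                vals = metric_values(profile, context, metric,
                                     config.log2_relative)
                is_d = vals.index.isin(dset)
                x = vals[is_d].to_numpy()
                if control_genes is not None:
                    ctl = set(control_genes) - dset
                    y = vals[vals.index.isin(ctl)].to_numpy()
                else:
                    y = vals[~is_d].to_numpy()
                for test in config.tests:
                    row = {"context": context, "gene_list": lname,
                           "metric": metric, "test": test,
                           "n_disease": len(x), "n_control": len(y)}
                    if len(x) < 2 or len(y) < 2:
                        row.update(statistic=np.nan, p_value=np.nan,
                                   reason="fewer than 2 genes in a group")
                    else:
                        if test == "t":
                            stat, p = t_test_higher(x, y)
                        elif test == "AD":
                            stat, p = anderson_darling_2sample(x, y)
                        elif test == "permutation":
                            p = permutation_test(vals, dset,
                                                 n_perm=config.n_perm, seed=rng)
                            stat = float(x.mean() - y.mean())
                        else:
                            raise ValueError(f"unknown test {test!r}")
                        row.update(statistic=stat, p_value=p, reason="")
                    rows.append(row)
    res = pd.DataFrame(rows)
    n_tests = res["p_value"].notna().sum()
    res["significant_bonferroni"] = res["p_value"] < config.alpha / max(n_tests, 1)
    res["neg_log10_p"] = -np.log10(res["p_value"].clip(lower=1e-300))
    return res


def sensitivity_exclude_top(profile: ExpressionProfile, context,
                            fraction: float = 0.10,
                            metric: str = "absolute") -> ExpressionProfile:
    """Profile with the top-`fraction` genes of a context's metric removed.

    Used to re-test significant contexts and check that results are not
    driven by a handful of extremely expressed genes.
    """
    vals = profile.metric(metric)[context].fillna(0.0)
    drop = top_fraction_genes(vals, fraction)
    keep = [g for g in profile.gene_ids if g not in drop]
    return ExpressionProfile(profile.tpm.loc[keep])


def select_relevant_tissues(results: pd.DataFrame, n_contexts: int,
                            n_lists: int, n_tests: int,
                            alpha: float = 0.05,
                            metric: str | None = None) -> list:
    """Contexts where *every* performed test clears the Bonferroni threshold.

    The threshold is alpha / (n_contexts * n_lists * n_tests); a context
    qualifies only if all its (gene list × test) p-values, for the chosen
    metric(s), fall below it.
    """
    thr = alpha / (n_contexts * n_lists * n_tests)
    sub = results if metric is None else results[results["metric"] == metric]
    relevant = []
    for context, grp in sub.groupby("context", sort=False):
        p = grp["p_value"]
        if p.notna().all() and (p < thr).all():
            relevant.append(context)
    return relevant


def triangulate(results_by_approach: dict[str, pd.DataFrame],
                by: tuple[str, ...] = ("context", "metric")) -> pd.DataFrame:
    """Pearson correlation of −log10 p between testing approaches.

    Each input table needs the ``by`` columns plus ``p_value``; rows are
    matched on ``by`` and a correlation computed per approach pair (NaN with
    a warning when fewer than 3 rows match).
    """
    keys = list(by)
    merged = None
    for name, df in results_by_approach.items():
        part = df.groupby(keys, sort=False)["p_value"].min().rename(name)
        merged = part.to_frame() if merged is None else merged.join(part, how="inner")
    rows = []
    names = list(results_by_approach)
    for a, b in combinations(names, 2):
        sub = merged[[a, b]].dropna()
        if len(sub) < 3:
            warnings.warn(f"fewer than 3 matched rows for {a} vs {b}")
            r = np.nan
        else:
            la, lb = -np.log10(sub[a].clip(lower=1e-300)), \
                     -np.log10(sub[b].clip(lower=1e-300))
            r = float(np.corrcoef(la, lb)[0, 1]) if la.std() > 0 and lb.std() > 0 \
                else np.nan
        rows.append({"approach_a": a, "approach_b": b, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def results_to_wide(results: pd.DataFrame) -> pd.DataFrame:
    """Contexts × (gene_list, metric, test) matrix of −log10 p for heatmaps."""
    return results.pivot_table(index="context",
                               columns=["gene_list", "metric", "test"],
                               values="neg_log10_p")
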