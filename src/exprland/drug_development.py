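"""Odds of drug-development inclusion as a function of expression quantile.

Disease genes (the union of the nearest-gene, fine-mapped and PoPS lists)
are labelled 1 when they appear in at least one drug-development program.
Within each disease-relevant tissue, the genes' absolute or relative
expression is binned into quantiles (10 and 100 are both used), and a
logistic regression of the inclusion label on the quantile score estimates
the odds ratio per one-quantile increase with its Wald 95% CI.  Quantile
coding makes the OR invariant to any strictly monotone transform of the
expression values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression_core import ExpressionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "OddsResult",
    "label_genes",
    "expression_odds",
    "run_drug_scan",
    "read_program_table",
]

Z975 = 1.959963984540054


@dataclass
class OddsResult:
    tissue: str
    metric: str
    n_quantiles: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_genes: int
    n_included: int
    firth: bool = False
    reason: str = ""


def read_program_table(path, gene_col: str = "gene",
                       indication_col: str = "indication") -> pd.DataFrame:
    """Drug-program table with one row per (gene, indication) pair."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={gene_col: "gene", indication_col: "indication"})
    return df.drop_duplicates(subset=["gene", "indication"])


def label_genes(disease_genes, program_table: pd.DataFrame) -> pd.Series:
    """1 if a gene appears in at least one drug-development program, else 0.

    ``disease_genes`` is the deduplicated union of the three disease lists.
    """
    genes = list(dict.fromkeys(disease_genes))
    in_programs = set(program_table["gene"])
    labels = pd.Series([1 if g in in_programs else 0 for g in genes],
                       index=pd.Index(genes, name="gene_id"), dtype=int)
    if labels.sum() == 0:
        warnings.warn("no disease gene appears in any drug program; all labels 0")
    logger.info("label_genes: %d / %d disease genes included in programs",
                int(labels.sum()), len(labels))
    return labels


def quantile_scores(values: pd.Series, n_quantiles: int) -> pd.Series:
    """Rank-based quantile score 1..Q (tie blocks share a score)."""
    ranks = rankdata(values.to_numpy(), method="average")
    q = np.ceil(ranks * n_quantiles / len(values)).astype(int)
    return pd.Series(np.clip(q, 1, n_quantiles), index=values.index)


def _logistic_irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """Plain Newton/IRLS logistic fit of y on [1, x]; returns (beta, se, ok)."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-12:
            break
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(XtWX)
            return beta, np.sqrt(np.diag(cov)), True
        if np.max(np.abs(beta)) > 30:  # diverging: separation
            break
    return beta, np.full(2, np.nan), False


def _firth_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-prior penalised logistic fit (handles complete separation)."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtWX = X.T @ (X * w[:, None])
        XtWX_inv = np.linalg.inv(XtWX)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], XtWX_inv,
                      X * np.sqrt(w)[:, None])
        grad = X.T @ (y - mu + h * (0.5 - mu))
        step = XtWX_inv @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def expression_odds(labels: pd.Series, expression: pd.Series,
                    n_quantiles: int = 10, metric: str = "absolute",
                    tissue: str = "") -> OddsResult:
    """OR per one-quantile increase of expression for program inclusion."""
    common = labels.index.intersection(expression.index)
    y = labels.loc[common].to_numpy(dtype=float)
    if len(common) < 20:
        return OddsResult(tissue, metric, n_quantiles, np.nan, np.nan, np.nan,
                          np.nan, len(common), int(y.sum()),
                          reason="fewer than 20 genes")
    if y.sum() == 0 or y.sum() == len(y):
        return OddsResult(tissue, metric, n_quantiles, np.nan, np.nan, np.nan,
                          np.nan, len(common), int(y.sum()),
                          reason="labels all identical")
    score = quantile_scores(expression.loc[common], n_quantiles).to_numpy(float)
    beta, se, ok = _logistic_irls(score, y)
    firth = False
    if not ok or not np.isfinite(se[1]):
        warnings.warn(f"logistic fit unstable for {tissue}/{metric}; "
                      "applying Firth penalisation")
        beta, se = _firth_logistic(score, y)
        firth = True
    from scipy.stats import norm
    orr = float(np.exp(beta[1]))
    lo = float(np.exp(beta[1] - Z975 * se[1]))
    hi = float(np.exp(beta[1] + Z975 * se[1]))
    p = float(2 * norm.sf(abs(beta[1] / se[1])))
    return OddsResult(tissue, metric, n_quantiles, orr, lo, hi, p,
                      len(common), int(y.sum()), firth=firth)


def run_drug_scan(profile: ExpressionProfile, relevant_tissues,
                  labels: pd.Series, metrics=("absolute", "relative"),
                  quantile_grids=(10, 100)) -> pd.DataFrame:
    """One OddsResult per (relevant tissue × metric × quantile grid)."""
    if not list(relevant_tissues):
        logger.info("run_drug_scan: no relevant tissues; returning empty table")
        return pd.DataFrame(columns=[
            "tissue", "metric", "n_quantiles", "odds_ratio", "ci_low",
            "ci_high", "p_value", "n_genes", "n_included", "firth", "reason",
            "both_metrics_significant"])
    rows = []
    for tissue in relevant_tissues:
        for metric in metrics:
            vals = profile.metric(metric)[tissue].dropna()
            for nq in quantile_grids:
                res = expression_odds(labels, vals, n_quantiles=nq,
                                      metric=metric, tissue=tissue)
                rows.append(vars(res))
    df = pd.DataFrame(rows)
    sig = df[df["p_value"] < 0.05].groupby(["tissue", "n_quantiles"])["metric"] \
        .nunique()
    both = {(t, q) for (t, q), n in sig.items() if n == len(metrics)}
    df["both_metrics_significant"] = [
        (t, q) in both for t, q in zip(df["tissue"], df["n_quantiles"])]
    return df
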