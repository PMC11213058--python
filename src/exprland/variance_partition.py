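"""Per-gene decomposition of expression variance across predictors.

For each gene, log-scale expression across samples is modelled with a linear
mixed model: every categorical predictor (tissue, donor, batch, collection
method, ...) enters as a crossed random intercept and every continuous
predictor (age, ...) as a fixed effect.  Variance components are estimated by
restricted maximum likelihood and reported as fractions

    fraction_j = sigma2_j / (sum_k sigma2_k + sigma2_fixed + sigma2_resid)

where ``sigma2_fixed`` is the sample variance of the fixed-effect linear
predictor, so continuous predictors also receive a share.  Fractions are
non-negative and sum to one for every converged gene.

Before fitting, redundant predictors are pruned: for any pair whose squared
first canonical correlation reaches the threshold (0.75 by default), the
member explaining less variance over a pilot gene subset is dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "VariancePartitionResult",
    "prune_predictors",
    "variance_fractions",
    "partition_all",
    "compare_fraction_groups",
]


@dataclass
class VariancePartitionResult:
    """Per-gene variance fractions (columns: predictors + 'residual')."""

    fractions: pd.DataFrame
    converged: pd.Series


def _one_hot(series: pd.Series) -> np.ndarray:
    levels = pd.unique(series)
    return (series.to_numpy()[:, None] == levels[None, :]).astype(float)


def _encode(meta: pd.DataFrame, predictor: str) -> np.ndarray:
    col = meta[predictor]
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 10:
        v = col.to_numpy(dtype=float)[:, None]
        return v - v.mean()
    return _one_hot(col.astype(str))


def _canonical_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared first canonical correlation between two encoded predictors."""
    def _whiten(x):
        x = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        keep = s > 1e-10 * (s[0] if len(s) else 1.0)
        return u[:, keep]
    ua, ub = _whiten(a), _whiten(b)
    if ua.shape[1] == 0 or ub.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(ua.T @ ub, compute_uv=False)
    return float(min(s[0] ** 2, 1.0))


def prune_predictors(metadata: pd.DataFrame, expression: pd.DataFrame | None = None,
                     predictors: list[str] | None = None,
                     r2_threshold: float = 0.75,
                     n_pilot_genes: int = 20,
                     seed: int | None = 0) -> list[str]:
    """Drop one predictor of every pair associated above ``r2_threshold``.

    Association between predictors is the squared first canonical correlation
    of their encodings (categoricals one-hot).  The member kept is the one
    with the larger mean variance explained over a pilot subset of genes
    (simple per-predictor R² from a fixed-effects fit); without expression
    data the earlier-listed predictor wins.  Decisions are logged.
    """
    preds = list(predictors or metadata.columns)
    if len(preds) < 2:
        return preds
    enc = {p: _encode(metadata, p) for p in preds}
    score = {p: 0.0 for p in preds}
    if expression is not None:
        rng = np.random.default_rng(seed)
        genes = expression.index.to_numpy()
        pilot = genes if len(genes) <= n_pilot_genes else \
            rng.choice(genes, n_pilot_genes, replace=False)
        for p in preds:
            x = enc[p] - enc[p].mean(axis=0)
            q, _ = np.linalg.qr(x)
            r2s = []
            for g in pilot:
                y = expression.loc[g].to_numpy(dtype=float)
                y = y - y.mean()
                tot = float(y @ y)
                if tot == 0:
                    continue
                proj = q.T @ y
                r2s.append(float(proj @ proj) / tot)
            score[p] = float(np.mean(r2s)) if r2s else 0.0
    else:
        # fall back to listing order: earlier predictors preferred
        score = {p: -i for i, p in enumerate(preds)}

    retained = list(preds)
    dropped = True
    while dropped:
        dropped = False
        pairs = [(a, b) for i, a in enumerate(retained)
                 for b in retained[i + 1:]]
        worst, worst_r2 = None, r2_threshold
        for a, b in pairs:
            r2 = _canonical_r2(enc[a], enc[b])
            if r2 >= worst_r2:
                loser = b if score[a] >= score[b] else a
                worst, worst_r2 = (a, b, loser), r2
        if worst:
            a, b, loser = worst
            logger.info("prune_predictors: dropping %s (r2=%.3f with %s)",
                        loser, worst_r2, a if loser == b else b)
            retained.remove(loser)
            dropped = True
    if len(retained) == 0:
        raise ValueError("all predictors are mutually collinear")
    return retained


# ---------------------------------------------------------------------------
# REML for crossed random intercepts


def _reml_pieces(y: np.ndarray, X: np.ndarray, ZZt: list[np.ndarray],
                 s2: np.ndarray, s2e: float):
    """(ll, P, Py) at the given variance components, or None if V singular."""
    n = len(y)
    V = s2e * np.eye(n)
    for s, zz in zip(s2, ZZt):
        V += s * zz
    try:
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        XtVinvX = XtVinv @ X
        XtVinvX_inv = np.linalg.inv(XtVinvX)
    except np.linalg.LinAlgError:
        return None
    P = Vinv - XtVinv.T @ XtVinvX_inv @ XtVinv
    Py = P @ y
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XtVinvX)
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, P, Py


def _reml_fit(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
              tol: float = 1e-6, max_iter: int = 200) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """REML for y = X b + sum_j Z_j u_j + e with u_j ~ N(0, s2_j I).

    Average-information (AI) steps with an EM fallback: both candidate
    updates are evaluated each iteration and the one with the higher
    restricted likelihood is taken, so ascent is monotone while boundary
    components (variances shrinking to zero, where plain EM crawls) converge
    quickly.  Returns (s2 per component, s2_resid, fixed effects, converged).
    """
    n = len(y)
    q = [Z.shape[1] for Z in Z_list]
    var_y = float(np.var(y)) or 1.0
    floor = 1e-12 * var_y
    s2 = np.full(len(Z_list), var_y / (len(Z_list) + 1))
    s2e = var_y / (len(Z_list) + 1)
    ZZt = [Z @ Z.T for Z in Z_list]
    G = ZZt + [np.eye(n)]
    converged = False
    cur = _reml_pieces(y, X, ZZt, s2, s2e)
    for _ in range(max_iter):
        if cur is None:
            break
        ll, P, Py = cur
        # EM candidate (guaranteed ascent, stays non-negative)
        em_s2 = np.empty_like(s2)
        for j, (Z, zz) in enumerate(zip(Z_list, ZZt)):
            u_hat = s2[j] * (Z.T @ Py)
            trace_term = s2[j] * q[j] - s2[j] ** 2 * float(np.trace(Z.T @ P @ Z))
            em_s2[j] = max((float(u_hat @ u_hat) + trace_term) / q[j], 0.0)
        e_hat = s2e * Py
        em_s2e = max((float(e_hat @ e_hat)
                      + s2e * n - s2e ** 2 * float(np.trace(P))) / n, floor)
        cand = [(np.clip(em_s2, 0.0, None), em_s2e)]
        # AI candidate: theta + AI^{-1} score, clipped at the boundary
        theta = np.append(s2, s2e)
        v = [g @ Py for g in G]
        score = np.array([-0.5 * (float(np.sum(P * g)) - float(Py @ g @ Py))
                          for g in G])
        AI = 0.5 * np.array([[float(vk @ P @ vl) for vl in v] for vk in v])
        try:
            step = np.linalg.solve(AI, score)
            ai_theta = np.clip(theta + step, 0.0, None)
            ai_theta[-1] = max(ai_theta[-1], floor)
            cand.append((ai_theta[:-1], float(ai_theta[-1])))
        except np.linalg.LinAlgError:
            pass
        best = None
        for cs2, cs2e in cand:
            pieces = _reml_pieces(y, X, ZZt, cs2, cs2e)
            if pieces is not None and (best is None or pieces[0] > best[0][0]):
                best = (pieces, cs2, cs2e)
        if best is None:
            break
        cur, s2, s2e = best
        s2 = np.where(s2 < 1e-10 * var_y, 0.0, s2)
        if abs(cur[0] - ll) < tol:
            converged = True
            break
    V = s2e * np.eye(n)
    for s, zz in zip(s2, ZZt):
        V += s * zz
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    return s2, s2e, beta, converged


def variance_fractions(y: pd.Series, metadata: pd.DataFrame,
                       predictors: list[str] | None = None,
                       tol: float = 1e-6, max_iter: int = 200) -> pd.Series:
    """Variance fractions of one gene's expression across the predictors.

    Categorical predictors become random intercepts, continuous ones fixed
    effects; the fixed-effect contribution is the variance of its fitted
    linear predictor.  Returns a Series over predictors plus ``residual``
    (NaN everywhere when REML does not converge).
    """
    preds = list(predictors or metadata.columns)
    meta = metadata.loc[y.index]
    keep_rows = meta[preds].notna().all(axis=1) & y.notna()
    yv = y[keep_rows].to_numpy(dtype=float)
    meta = meta[keep_rows]
    cat, cont = [], []
    for p in preds:
        col = meta[p]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 10:
            cont.append(p)
        elif col.nunique() < 2:
            warnings.warn(f"predictor {p} has a single level; dropped for this gene")
        else:
            cat.append(p)
    X_cols = [np.ones(len(yv))]
    for p in cont:
        v = meta[p].to_numpy(dtype=float)
        X_cols.append(v - v.mean())
    X = np.column_stack(X_cols)
    Z_list = [_one_hot(meta[p].astype(str)) for p in cat]
    out_index = preds + ["residual"]
    if not Z_list:
        warnings.warn("no categorical predictor; fixed-effects decomposition only")
    s2, s2e, beta, converged = _reml_fit(yv, X, Z_list, tol=tol, max_iter=max_iter)
    if not converged:
        return pd.Series(np.nan, index=out_index)
    fixed_pred = X[:, 1:] @ beta[1:] if X.shape[1] > 1 else np.zeros(len(yv))
    # apportion the fixed variance among continuous predictors by their
    # marginal fitted variance (single continuous predictor: exact)
    fix_parts = {}
    for i, p in enumerate(cont):
        fix_parts[p] = float(np.var(X[:, 1 + i] * beta[1 + i]))
    s2_fixed = float(np.var(fixed_pred))
    total = float(np.sum(s2)) + s2_fixed + s2e
    frac = {}
    for p, s in zip(cat, s2):
        frac[p] = s / total
    scale = s2_fixed / sum(fix_parts.values()) if fix_parts and \
        sum(fix_parts.values()) > 0 else 0.0
    for p in cont:
        frac[p] = fix_parts[p] * scale / total
    frac["residual"] = s2e / total
    out = pd.Series(frac).reindex(out_index).fillna(0.0)
    out["residual"] = frac["residual"]
    return out


def partition_all(expression: pd.DataFrame, metadata: pd.DataFrame,
                  predictors: list[str] | None = None,
                  tol: float = 1e-6, max_iter: int = 200
                  ) -> VariancePartitionResult:
    """Variance fractions for every gene (rows of ``expression``)."""
    rows = {}
    conv = {}
    for g in expression.index:
        fr = variance_fractions(expression.loc[g], metadata, predictors,
                                tol=tol, max_iter=max_iter)
        rows[g] = fr
        conv[g] = not fr.isna().any()
    fractions = pd.DataFrame(rows).T
    return VariancePartitionResult(fractions=fractions,
                                   converged=pd.Series(conv))


def compare_fraction_groups(result: VariancePartitionResult,
                            disease_genes, control_genes,
                            min_group: int = 10) -> pd.DataFrame:
    """Mann–Whitney comparison of per-predictor fractions, disease vs control."""
    fr = result.fractions[result.converged]
    d = fr.loc[fr.index.intersection(pd.Index(set(disease_genes)))]
    c = fr.loc[fr.index.intersection(pd.Index(set(control_genes)))]
    rows = []
    for pred in fr.columns:
        row = {"predictor": pred, "n_disease": len(d), "n_control": len(c)}
        if len(d) < min_group or len(c) < min_group:
            row.update(statistic=np.nan, p_value=np.nan,
                       median_difference=np.nan,
                       reason="group below minimum size")
        else:
            stat, p = sps.mannwhitneyu(d[pred], c[pred], alternative="two-sided")
            row.update(statistic=float(stat), p_value=float(p),
                       median_difference=float(d[pred].median() - c[pred].median()),
                       reason="")
        rows.append(row)
    return pd.DataFrame(rows)
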