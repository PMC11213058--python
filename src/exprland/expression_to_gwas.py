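"""Competitive enrichment of GWAS signal in highly expressed gene sets.

This is the reverse arm of the framework: instead of asking where disease
genes are expressed, it asks whether the genes most expressed in a context
(the top decile of absolute or relative expression) carry more GWAS signal
than the rest of the genome.

Pipeline: SNPs are assigned to genes over strand-aware windows (35 kb
upstream, 10 kb downstream by default; MHC excluded), a per-gene association
statistic is formed by summing the SNP chi-squares and moment-matching the
null against the local LD structure, the gene p-value is probit-transformed
into a Z-score, and each top-decile set is tested with the competitive
regression  Z = β0 + I·βp + C·βk + ε,  where I indicates set membership and
C holds gene-level covariates (length and SNP count, raw and logged).  The
one-sided p on βp asks whether set genes are more associated than the
background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression_core import ExpressionProfile, quantile_bins
from .gene_sets import GeneAnnotation, LDMatrix, SummaryStats, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "SNPGeneMap",
    "GeneSetTestResult",
    "map_snps_to_genes",
    "gene_statistic",
    "competitive_test",
    "run_enrichment",
]

MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 35_000_000


@dataclass
class SNPGeneMap:
    """Variant membership per gene window."""

    members: dict[str, list[str]]  # gene_id -> variant ids
    windows: pd.DataFrame  # gene_id -> (chrom, win_start, win_end)
    mhc_excluded: bool


@dataclass
class GeneSetTestResult:
    set_name: str
    beta: float
    se: float
    p_value: float
    n_set: int
    n_background: int
    reason: str = ""


def map_snps_to_genes(stats: SummaryStats, annotation: GeneAnnotation,
                      up_bp: int = 35_000, down_bp: int = 10_000,
                      exclude_mhc: bool = True,
                      mhc_region: tuple[str, int, int] = (MHC_CHROM, MHC_START, MHC_END),
                      ) -> SNPGeneMap:
    """Assign variants to strand-aware gene windows.

    The upstream extension is applied on the 5' side of the gene per its
    strand; window starts are clipped at 1.  With ``exclude_mhc`` the MHC
    (chr6:25–35 Mb by default) loses both its variants and any gene whose
    window overlaps it.
    """
    ann = annotation.table
    plus = ann["strand"] != "-"
    win_start = np.where(plus, ann["start"] - up_bp, ann["start"] - down_bp)
    win_end = np.where(plus, ann["end"] + down_bp, ann["end"] + up_bp)
    windows = pd.DataFrame({
        "chrom": ann["chrom"].map(normalize_chrom),
        "win_start": np.maximum(win_start, 1),
        "win_end": win_end,
    }, index=ann.index)

    mhc_chrom, mhc_lo, mhc_hi = normalize_chrom(mhc_region[0]), *mhc_region[1:]
    if exclude_mhc:
        in_mhc = ((windows["chrom"] == mhc_chrom)
                  & (windows["win_start"] <= mhc_hi)
                  & (windows["win_end"] >= mhc_lo))
        windows = windows[~in_mhc]

    st = stats.table.copy()
    st["chrom"] = st["chrom"].map(normalize_chrom)
    if exclude_mhc:
        snp_mhc = ((st["chrom"] == mhc_chrom) & (st["pos"] >= mhc_lo)
                   & (st["pos"] <= mhc_hi))
        st = st[~snp_mhc]

    members: dict[str, list[str]] = {}
    for chrom, genes in windows.groupby("chrom", sort=False):
        snps = st[st["chrom"] == chrom]
        if snps.empty:
            continue
        pos = snps["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        vids = snps.index.to_numpy()[order]
        lo = np.searchsorted(pos_sorted, genes["win_start"].to_numpy(), side="left")
        hi = np.searchsorted(pos_sorted, genes["win_end"].to_numpy(), side="right")
        for gid, a, b in zip(genes.index, lo, hi):
            if b > a:
                members[gid] = list(vids[a:b])
    if not members:
        raise ValueError("no variant maps into any gene window")
    return SNPGeneMap(members=members, windows=windows, mhc_excluded=exclude_mhc)


def gene_statistic(stats: SummaryStats, snp_map: SNPGeneMap,
                   ld: LDMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Gene-level association p and Z from SNP p-values under local LD.

    Per gene, T = Σᵢ F⁻¹(1−pᵢ; χ²₁).  Under the null T has mean m (the SNP
    count) and variance 2m + 2Σ_{i<j} ρ²ᵢⱼ, with ρ² taken from the LD matrix;
    T is referred to the moment-matched scaled chi-square, and the gene Z is
    the probit of the resulting one-sided p.  Covariates for the competitive
    regression (gene length and SNP count, raw and logged) are attached.
    """
    rows = []
    ann = annotation.table
    for gid, vids in snp_map.members.items():
        p = stats.table.loc[vids, "p"].to_numpy(dtype=float)
        tiny = p < 1e-300
        if tiny.any():
            warnings.warn(f"{tiny.sum()} SNP p-value(s) clipped to 1e-300 for {gid}")
            p = np.clip(p, 1e-300, None)
        chi = sps.chi2.isf(p, df=1)
        T = float(chi.sum())
        m = len(p)
        rho2 = 0.0
        for i in range(m):
            for j in range(i + 1, m):
                rho2 += ld.r2(vids[i], vids[j])
        # Brown's approximation: cov(chi2_i, chi2_j) = 2 rho^2_ij
        var = 2.0 * m + 4.0 * rho2
        # scaled chi-square: T ~ c * chi2_f with c = var/(2m), f = 2m^2/var
        c = var / (2.0 * m)
        f = 2.0 * m * m / var
        gene_p = float(sps.chi2.sf(T / c, df=f))
        gene_p = min(max(gene_p, 1e-300), 1.0)
        z = float(sps.norm.isf(gene_p))
        length = int(ann.loc[gid, "end"] - ann.loc[gid, "start"] + 1) \
            if gid in ann.index else np.nan
        rows.append({"gene_id": gid, "n_snps": m, "p_value": gene_p, "Z": z,
                     "length_bp": length})
    df = pd.DataFrame(rows).set_index("gene_id")
    df["log_length"] = np.log(df["length_bp"])
    df["log_n_snps"] = np.log(df["n_snps"])
    return df


DEFAULT_COVARIATES = ("length_bp", "log_length", "n_snps", "log_n_snps")


def competitive_test(gene_stats: pd.DataFrame, gene_set,
                     covariates=DEFAULT_COVARIATES,
                     set_name: str = "set", min_set_size: int = 10
                     ) -> GeneSetTestResult:
    """OLS of gene Z on set membership plus covariates; one-sided p for β>0."""
    gset = set(gene_set)
    indicator = gene_stats.index.isin(gset).astype(float)
    n_set = int(indicator.sum())
    n_bg = len(gene_stats)
    if n_set < min_set_size:
        return GeneSetTestResult(set_name, np.nan, np.nan, np.nan, n_set, n_bg,
                                 reason=f"set smaller than floor {min_set_size}")
    if n_set == n_bg:
        raise ValueError("gene set covers the whole background; no contrast")
    cols = [np.ones(n_bg), indicator]
    names = ["intercept", "in_set"]
    for cov in covariates:
        v = gene_stats[cov].to_numpy(dtype=float)
        if np.std(v) == 0 or not np.all(np.isfinite(v)):
            warnings.warn(f"covariate {cov} constant or non-finite; dropped")
            continue
        cols.append(v)
        names.append(cov)
    X = np.column_stack(cols)
    # drop collinear columns (keep intercept and indicator)
    rank = np.linalg.matrix_rank(X)
    while rank < X.shape[1] and X.shape[1] > 2:
        X = X[:, :-1]
        names = names[:-1]
        warnings.warn("collinear covariate dropped from competitive test")
        rank = np.linalg.matrix_rank(X)
    y = gene_stats["Z"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n_bg - X.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    tstat = beta[1] / se
    p = float(sps.t.sf(tstat, df_resid))
    return GeneSetTestResult(set_name, float(beta[1]), se, p, n_set, n_bg)


def run_enrichment(profile: ExpressionProfile, stats: SummaryStats,
                   annotation: GeneAnnotation, ld: LDMatrix,
                   metrics=("absolute", "relative"),
                   up_bp: int = 35_000, down_bp: int = 10_000,
                   exclude_mhc: bool = True, min_set_size: int = 10
                   ) -> pd.DataFrame:
    """One competitive test per (context × metric) top-decile expression set."""
    snp_map = map_snps_to_genes(stats, annotation, up_bp, down_bp, exclude_mhc)
    gs = gene_statistic(stats, snp_map, ld, annotation)
    rows = []
    for metric in metrics:
        values = profile.metric(metric)
        for context in profile.context_ids:
            vals = values[context].fillna(0.0)
            try:
                qb = quantile_bins(vals)
            except ValueError as exc:
                rows.append({"context": context, "metric": metric,
                             "beta": np.nan, "se": np.nan, "p_value": np.nan,
                             "n_set": 0, "n_background": len(gs),
                             "reason": str(exc)})
                continue
            res = competitive_test(gs, qb.top_decile_set,
                                   set_name=f"{context}|top_decile|{metric}",
                                   min_set_size=min_set_size)
            rows.append({"context": context, "metric": metric,
                         "beta": res.beta, "se": res.se, "p_value": res.p_value,
                         "n_set": res.n_set, "n_background": res.n_background,
                         "reason": res.reason})
    df = pd.DataFrame(rows)
    df["neg_log10_p"] = -np.log10(df["p_value"].clip(lower=1e-300))
    return df
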