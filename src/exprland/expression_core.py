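"""Expression matrices and the absolute/relative expression layers.

The pipeline works with a gene-by-context matrix of TPM values (contexts are
tissues or cell types).  Two derived layers drive every downstream test:

* **absolute expression** ``A = log2(TPM + 1)`` — overall abundance of a gene
  in a context;
* **relative expression** ``R`` — the share of a gene's total absolute
  expression that falls in each context (1 means the gene is exclusive to
  that context, 0 means it is absent there).

The module also covers per-sample TPM computation from raw counts,
per-context rescaling so every column totals one million, quantile
normalisation across samples, 11-quantile binning (bin 1 = unexpressed,
bins 2–11 = deciles of expressed genes), pseudobulk aggregation of
single-cell counts with TMM scaling, and sex-stratified profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "RawCountsMatrix",
    "ExpressionProfile",
    "QuantileBinning",
    "PseudobulkMatrix",
    "compute_tpm",
    "rescale_context",
    "qc_filter",
    "absolute_expression",
    "relative_expression",
    "quantile_normalize",
    "pseudobulk",
    "quantile_bins",
    "sex_stratify",
    "read_expression_tsv",
    "write_expression_tsv",
    "bins_to_gmt",
]

SCALE = 1e6


@dataclass
class RawCountsMatrix:
    """Read counts per (gene, sample) plus gene lengths in kilobases."""

    counts: pd.DataFrame  # genes x samples
    gene_length_kb: pd.Series  # indexed by gene

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in counts matrix")
        self.gene_length_kb = self.gene_length_kb.reindex(self.counts.index)
        bad = self.gene_length_kb.isna() | (self.gene_length_kb <= 0)
        if bad.any():
            raise ValueError(
                f"non-positive or missing gene length for gene(s) "
                f"{list(self.counts.index[bad])[:5]}"
            )


@dataclass
class ExpressionProfile:
    """Gene-by-context TPM matrix with derived A and R layers.

    ``R`` rows are NaN for genes with zero total absolute expression; the
    ``r_defined`` mask flags the genes where R is meaningful.
    """

    tpm: pd.DataFrame  # genes x contexts, non-negative
    _A: pd.DataFrame | None = field(default=None, repr=False)
    _R: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def context_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def A(self) -> pd.DataFrame:
        if self._A is None:
            self._A = absolute_expression(self.tpm)
        return self._A

    @property
    def R(self) -> pd.DataFrame:
        if self._R is None:
            self._R = relative_expression(self.A)
        return self._R

    @property
    def expressed_mask(self) -> pd.DataFrame:
        return self.tpm > 0

    @property
    def r_defined(self) -> pd.Series:
        return self.A.sum(axis=1) > 0

    def metric(self, name: str) -> pd.DataFrame:
        if name == "absolute":
            return self.A
        if name == "relative":
            return self.R
        raise ValueError(f"unknown metric {name!r}; use 'absolute' or 'relative'")

    def subset_genes(self, gene_ids) -> "ExpressionProfile":
        keep = self.tpm.index.intersection(pd.Index(gene_ids))
        return ExpressionProfile(self.tpm.loc[keep])


@dataclass
class QuantileBinning:
    """Integer bins 1..(n_expressed_bins+1) per gene for one context."""

    bin: pd.Series  # gene -> bin
    n_expressed_bins: int

    @property
    def top_decile_set(self) -> set[str]:
        top = self.n_expressed_bins + 1
        return set(self.bin.index[self.bin == top])


@dataclass
class PseudobulkMatrix:
    """Aggregated single-cell counts per cell type with TMM scaling.

    ``cpm_abs`` is the absolute layer (counts per million per cell type,
    each column totalling 1e6); ``cell_specificity`` is the relative layer
    (a gene's share of its TMM-normalised counts across cell types).
    """

    counts: pd.DataFrame  # genes x cell types
    n_cells: pd.Series
    norm_factor: pd.Series
    cpm_abs: pd.DataFrame
    cell_specificity: pd.DataFrame


# ---------------------------------------------------------------------------
# TPM and scaling


def compute_tpm(raw: RawCountsMatrix) -> pd.DataFrame:
    """Length-normalised expression per (gene, sample).

    Each sample's counts are divided by gene length in kb, scaled by 1e6 and
    divided by the sample's total mapped reads.  Columns of the result do not
    total 1e6; follow with :func:`rescale_context` for proper TPM.
    """
    totals = raw.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    rate = raw.counts.div(raw.gene_length_kb, axis=0)
    return rate * SCALE / totals


def rescale_context(tpm: pd.DataFrame) -> pd.DataFrame:
    """Scale each context column so it sums to exactly 1e6."""
    totals = tpm.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"context(s) with all-zero expression: {list(zero.index)}")
    return tpm * (SCALE / totals)


def qc_filter(
    tpm: pd.DataFrame,
    context_metadata: pd.DataFrame,
    gene_biotype: pd.Series | None = None,
    min_samples: int = 100,
    biotype: str = "protein_coding",
) -> tuple[pd.DataFrame, dict]:
    """Drop small / tagged contexts and non-coding or silent genes.

    ``context_metadata`` must carry an ``n_samples`` column and may carry a
    boolean ``exclude`` column (cancer or cell-line contexts).  Returns the
    filtered matrix and a removal log.
    """
    log: dict = {}
    meta = context_metadata.reindex(tpm.columns)
    small = meta.index[meta["n_samples"].fillna(0) < min_samples]
    tagged = (
        meta.index[meta["exclude"].fillna(False).astype(bool)]
        if "exclude" in meta
        else pd.Index([])
    )
    drop_ctx = small.union(tagged)
    log["contexts_dropped_small"] = list(small)
    log["contexts_dropped_tagged"] = list(tagged)
    out = tpm.drop(columns=drop_ctx)

    if gene_biotype is not None:
        bt = gene_biotype.reindex(out.index)
        noncoding = out.index[bt != biotype]
        log["genes_dropped_biotype"] = len(noncoding)
        out = out.drop(index=noncoding)
    silent = out.index[(out == 0).all(axis=1)]
    log["genes_dropped_silent"] = len(silent)
    out = out.drop(index=silent)
    if out.empty:
        raise ValueError("QC filtering removed every gene or context")
    for key, val in log.items():
        logger.info("qc_filter: %s = %s", key, val)
    return out, log


def absolute_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """A = log2(TPM + 1), elementwise."""
    if (tpm.values < 0).any():
        raise ValueError("TPM must be non-negative")
    return np.log2(tpm + 1.0)


def relative_expression(A: pd.DataFrame) -> pd.DataFrame:
    """Each gene's share of its total absolute expression across contexts.

    Rows with zero total are returned as NaN (relative expression is
    undefined for genes silent everywhere).
    """
    totals = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = A.div(totals.where(totals > 0), axis=0)
    return R


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common (rank-mean) distribution.

    Ties within a column receive the mean of the reference values they span
    (average-rank convention).
    """
    if mat.shape[1] < 2:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return mat.copy()
    values = mat.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, ties averaged
        # interpolate reference at fractional (tied) ranks
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


# ---------------------------------------------------------------------------
# Pseudobulk + TMM


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> float:
    """Trimmed mean of M-values scaling factor of obs against ref."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse of the asymptotic (delta-method) variance of each M value
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0 or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def tmm_norm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                     sum_trim: float = 0.05) -> pd.Series:
    """TMM scaling factors per column, geometric mean normalised to 1.

    The reference column is the one whose upper-quartile (of library-scaled
    counts) is closest to the mean upper-quartile.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    scaled = counts.to_numpy(dtype=float) / lib
    uq = np.quantile(scaled, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts.iloc[:, ref_idx].to_numpy(dtype=float)
    factors = np.array([
        _tmm_factor(counts.iloc[:, j].to_numpy(dtype=float), ref,
                    logratio_trim, sum_trim)
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def pseudobulk(
    cell_counts: pd.DataFrame,
    cell_type_labels: pd.Series,
    donor_labels: pd.Series | None = None,
) -> PseudobulkMatrix:
    """Aggregate a gene-by-cell count matrix into per-cell-type pseudobulk.

    Cells with zero totals must already have been removed.  Counts are summed
    per cell type, TMM factors computed, and the absolute (CPM) and relative
    (cell-specificity) layers populated.
    """
    labels = cell_type_labels.reindex(cell_counts.columns)
    if labels.isna().any():
        raise ValueError("cell_type_labels must cover every cell")
    agg = cell_counts.T.groupby(labels).sum().T
    n_cells = labels.value_counts().reindex(agg.columns)
    empty = agg.columns[(agg.sum(axis=0) == 0)]
    if len(empty):
        warnings.warn(f"dropping cell type(s) with zero counts: {list(empty)}")
        agg = agg.drop(columns=empty)
        n_cells = n_cells.drop(index=empty)
    nf = tmm_norm_factors(agg)
    eff_lib = agg.sum(axis=0) * nf
    norm = agg / eff_lib  # per-column share after TMM
    cpm = rescale_context(norm)  # absolute layer: columns total 1e6
    row_tot = norm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = norm.div(row_tot.where(row_tot > 0), axis=0)
    return PseudobulkMatrix(counts=agg, n_cells=n_cells, norm_factor=nf,
                            cpm_abs=cpm, cell_specificity=spec)


def detect_outlier_cells(cell_counts: pd.DataFrame, n_mad: float = 5.0) -> pd.Index:
    """Cells whose number of detected genes exceeds median + n_mad * MAD."""
    detected = (cell_counts > 0).sum(axis=0)
    med = detected.median()
    mad = (detected - med).abs().median()
    return detected.index[detected > med + n_mad * mad]


# ---------------------------------------------------------------------------
# Quantile binning


def quantile_bins(values: pd.Series, n_expressed_bins: int = 10) -> QuantileBinning:
    """11-quantile classification of one context's expression values.

    Bin 1 holds the unexpressed genes (value 0); expressed genes are ranked
    and cut into ``n_expressed_bins`` near-equal groups (bins 2..11).  A tie
    block is assigned entirely to the bin containing its mean rank, so sets
    are deterministic and never split a tie.
    """
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    expressed = values[values > 0]
    n = len(expressed)
    if n < n_expressed_bins:
        raise ValueError(
            f"only {n} expressed genes; need at least {n_expressed_bins}"
        )
    ranks = rankdata(expressed.to_numpy(), method="average")
    idx = np.ceil(ranks * n_expressed_bins / n).astype(int)
    idx = np.clip(idx, 1, n_expressed_bins)
    bins = pd.Series(1, index=values.index, dtype=int)
    bins.loc[expressed.index] = idx + 1
    return QuantileBinning(bin=bins, n_expressed_bins=n_expressed_bins)


def top_fraction_genes(values: pd.Series, fraction: float = 0.10) -> set[str]:
    """Genes in the top `fraction` of the given values (tie rule as in binning)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(values)
    ranks = rankdata(values.to_numpy(), method="average")
    cut = (1.0 - fraction) * n
    return set(values.index[ranks > cut])


# ---------------------------------------------------------------------------
# Sex stratification


def sex_stratify(
    sample_tpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> dict[str, ExpressionProfile]:
    """Per-sex median-TPM profiles from a gene-by-sample matrix.

    ``sample_meta`` (indexed by sample) needs ``context`` and ``sex``
    columns.  A context present for only one sex is dropped for the missing
    sex and logged.
    """
    meta = sample_meta.reindex(sample_tpm.columns)
    if meta[["context", "sex"]].isna().any().any():
        raise ValueError("sample metadata must provide context and sex per sample")
    out: dict[str, ExpressionProfile] = {}
    for sex, meta_s in meta.groupby("sex"):
        cols = meta_s.index
        med = sample_tpm[cols].T.groupby(meta_s["context"]).median().T
        missing = set(meta["context"].unique()) - set(med.columns)
        if missing:
            logger.info("sex_stratify: contexts missing for sex %s: %s",
                        sex, sorted(missing))
        out[sex] = ExpressionProfile(med)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene-by-context TSV (first column gene ids); GCT 1.2 accepted."""
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.2") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    if skip and "Description" in df.columns:
        df = df.drop(columns="Description")
    df.index.name = None
    return df


def write_expression_tsv(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def bins_to_gmt(binnings: dict[str, QuantileBinning], metric: str, path) -> None:
    """Export per-context top-decile sets as GMT lines."""
    with open(path, "w") as fh:
        for context, qb in binnings.items():
            genes = sorted(qb.top_decile_set)
            name = f"{context}|top_decile|{metric}"
            fh.write("\t".join([name, metric] + genes) + "\n")
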