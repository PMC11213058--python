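"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the analyses assume, at
desk scale, so recovery and calibration can be tested without any download:

* ``synth_expression`` — log-normal TPM baselines with a planted log2-scale
  elevation of a designated disease-gene set in target contexts, plus
  dropout zeros (applied before per-context rescaling so zero handling is
  exercised downstream);
* ``synth_gwas`` — LD-blocked GWAS Z-scores with AR(1) within-block
  correlation, inflated (non-centrality λ) for variants falling inside
  disease-gene windows;
* ``synth_samples`` — sample-level expression driven by random intercepts
  with known variance fractions (tissue, donor, residual);
* ``synth_drug_labels`` — Bernoulli program-inclusion labels from a known
  logistic slope on expression quantiles (truth OR = e^β);
* ``synth_cells`` — negative-binomial single-cell counts with cell-type
  mean profiles and donor effects, for pseudobulk tests.

All generators are deterministic given (config, seed); truth records are
returned next to the data and serialise alongside any emitted files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .drug_development import quantile_scores
from .expression_core import ExpressionProfile, rescale_context
from .gene_sets import GeneAnnotation, LDMatrix, SummaryStats

__all__ = [
    "SyntheticConfig",
    "synth_annotation",
    "synth_expression",
    "synth_gwas",
    "synth_samples",
    "synth_drug_labels",
    "synth_cells",
    "write_truth",
]


@dataclass
class SyntheticConfig:
    """All knobs of the generators, with the study-scale defaults.

    Sizes are scaled to what the analyses need statistically rather than to
    the full public datasets: ~2,000 genes stand in for the protein-coding
    genome, 20 contexts for the tissue panel, 150 disease genes matches the
    typical prioritised-list size, and the +1 log2 planted shift is a
    conservative disease-gene elevation.
    """

    seed: int = 0
    # expression
    n_genes: int = 2000
    n_contexts: int = 20
    baseline_mean: float = 3.0
    baseline_sd: float = 2.0
    context_sd: float = 0.5
    n_disease_genes: int = 150
    shift: float = 1.0  # planted log2 elevation delta
    target_contexts: tuple[int, ...] = (3,)
    dropout: float = 0.3
    # GWAS
    n_variants: int = 2000
    ld_block_size: int = 20
    ld_rho: float = 0.8
    noncentrality: float = 7.0  # mean |Z| boost near disease genes
    chrom_span: int = 10_000_000
    # variance partition
    vp_sigma2: tuple[float, ...] = (0.5, 0.2, 0.3)  # tissue, donor, residual
    vp_factors: tuple[str, ...] = ("tissue", "donor")
    vp_levels: tuple[int, ...] = (10, 40)
    n_samples: int = 200
    # drug labels
    drug_alpha: float = -1.0
    drug_beta: float = 0.2
    drug_n_quantiles: int = 10
    # cells
    n_cell_types: int = 4
    n_donors: int = 2
    cells_per_type: int = 30
    nb_dispersion: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if max(self.target_contexts, default=0) >= self.n_contexts:
            raise ValueError("target context index beyond n_contexts")


def _rng(cfg: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def synth_annotation(cfg: SyntheticConfig, gene_length: int = 20_000,
                     spacing: int = 100_000, n_chroms: int = 5) -> GeneAnnotation:
    """Evenly spaced protein-coding genes over a few autosomes."""
    rng = _rng(cfg, 101)
    ids = _gene_ids(cfg.n_genes)
    per_chrom = int(np.ceil(cfg.n_genes / n_chroms))
    rows = []
    for i, gid in enumerate(ids):
        chrom = str(1 + i // per_chrom)
        slot = i % per_chrom
        start = 1 + slot * spacing
        rows.append({"gene_id": gid, "symbol": f"SYM{i:05d}", "chrom": chrom,
                     "start": start, "end": start + gene_length - 1,
                     "strand": "+" if rng.random() < 0.5 else "-",
                     "biotype": "protein_coding"})
    return GeneAnnotation(pd.DataFrame(rows).set_index("gene_id"))


def synth_expression(cfg: SyntheticConfig) -> tuple[ExpressionProfile, dict]:
    """Gene-by-context TPM with a planted disease-gene elevation.

    TPM = 2^(baseline + context effect + shift·1[disease gene, target
    context]) − 1, with dropout zeros applied before per-context rescaling.
    """
    rng = _rng(cfg, 1)
    ids = _gene_ids(cfg.n_genes)
    contexts = [f"context_{t:02d}" for t in range(cfg.n_contexts)]
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    log2e = base[:, None] + rng.normal(0.0, cfg.context_sd,
                                       size=(cfg.n_genes, cfg.n_contexts))
    disease = sorted(rng.choice(cfg.n_genes, cfg.n_disease_genes, replace=False))
    for t in cfg.target_contexts:
        log2e[disease, t] += cfg.shift
    tpm = np.maximum(2.0 ** log2e - 1.0, 0.0)
    drop = rng.random(tpm.shape) < cfg.dropout
    tpm[drop] = 0.0
    df = pd.DataFrame(tpm, index=ids, columns=contexts)
    df = rescale_context(df)
    truth = {"disease_genes": [ids[i] for i in disease],
             "target_contexts": [contexts[t] for t in cfg.target_contexts],
             "shift": cfg.shift}
    return ExpressionProfile(df), truth


def synth_gwas(cfg: SyntheticConfig, annotation: GeneAnnotation,
               disease_genes: list[str] | None = None
               ) -> tuple[SummaryStats, LDMatrix, dict]:
    """LD-blocked GWAS summary statistics with signal near disease genes.

    Variants are laid uniformly along each chromosome; per block of size B,
    Z is multivariate normal with AR(1) correlation ρ^|i−j|, and variants
    inside disease-gene bodies ±35/10 kb windows receive mean λ.  The LD
    matrix holds the block r² = ρ^(2|i−j|).
    """
    rng = _rng(cfg, 2)
    ann = annotation.table
    chroms = list(dict.fromkeys(ann["chrom"]))
    if disease_genes is None:
        disease_genes = []
    dis = ann.loc[ann.index.intersection(pd.Index(disease_genes))]
    per_chrom = int(np.ceil(cfg.n_variants / len(chroms)))
    span = max(int(ann["end"].max()) + 50_000, cfg.chrom_span)
    if cfg.ld_block_size > per_chrom:
        raise ValueError("LD block larger than the variants on a chromosome")
    rows = []
    ld = LDMatrix()
    B = cfg.ld_block_size
    # AR(1) covariance factor, shared across blocks
    idx = np.arange(B)
    cov = cfg.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(B))
    vid_counter = 0
    for chrom in chroms:
        pos = np.linspace(1, span, per_chrom).astype(int)
        dsub = dis[dis["chrom"] == chrom]
        starts = dsub["start"].to_numpy() - 35_000
        ends = dsub["end"].to_numpy() + 10_000
        in_window = np.zeros(per_chrom, dtype=bool)
        for s, e in zip(starts, ends):
            in_window |= (pos >= s) & (pos <= e)
        for b0 in range(0, per_chrom, B):
            b1 = min(b0 + B, per_chrom)
            nb = b1 - b0
            z = chol[:nb, :nb] @ rng.standard_normal(nb)
            mean = np.where(in_window[b0:b1], cfg.noncentrality, 0.0)
            z = z + mean
            vids = [f"rs{vid_counter + i}" for i in range(nb)]
            vid_counter += nb
            from scipy.stats import norm
            p = 2.0 * norm.sf(np.abs(z))
            p = np.clip(p, 1e-300, 1.0)
            for i in range(nb):
                rows.append({"variant_id": vids[i], "chrom": chrom,
                             "pos": int(pos[b0 + i]), "p": float(p[i]),
                             "z": float(z[i])})
                for j in range(i + 1, nb):
                    r2 = cfg.ld_rho ** (2 * (j - i))
                    if r2 > 1e-4:
                        ld.set(vids[i], vids[j], r2)
    table = pd.DataFrame(rows).set_index("variant_id", drop=False)
    table.index.name = None
    stats = SummaryStats(table[["variant_id", "chrom", "pos", "p"]])
    truth = {"disease_genes": list(disease_genes),
             "noncentrality": cfg.noncentrality}
    return stats, ld, truth


def synth_samples(cfg: SyntheticConfig, n_genes: int = 1
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sample-level expression with known variance fractions.

    Returns (expression genes×samples, metadata, truth).  y is the sum of a
    random intercept per factor level plus residual noise, with the variances
    given by ``vp_sigma2`` (last entry = residual).
    """
    sig = np.asarray(cfg.vp_sigma2, dtype=float)
    if sig.sum() <= 0:
        raise ValueError("total variance must be positive")
    if len(sig) != len(cfg.vp_factors) + 1:
        raise ValueError("vp_sigma2 must list one variance per factor plus residual")
    rng = _rng(cfg, 3)
    n = cfg.n_samples
    meta = {}
    for fac, L in zip(cfg.vp_factors, cfg.vp_levels):
        if L < 2:
            raise ValueError(f"factor {fac} needs at least 2 levels")
        meta[fac] = [f"{fac}_{v}" for v in rng.integers(0, L, size=n)]
    samples = [f"S{i:04d}" for i in range(n)]
    metadata = pd.DataFrame(meta, index=samples)
    ys = np.zeros((n_genes, n))
    for g in range(n_genes):
        y = rng.normal(0.0, np.sqrt(sig[-1]), size=n)
        for k, fac in enumerate(cfg.vp_factors):
            levels = metadata[fac]
            uniq = levels.unique()
            eff = dict(zip(uniq, rng.normal(0.0, np.sqrt(sig[k]), size=len(uniq))))
            y = y + levels.map(eff).to_numpy()
        ys[g] = y
    expr = pd.DataFrame(ys, index=[f"G{i:05d}" for i in range(n_genes)],
                        columns=samples)
    truth = {"fractions": dict(zip(list(cfg.vp_factors) + ["residual"],
                                   (sig / sig.sum()).tolist()))}
    return expr, metadata, truth


def synth_drug_labels(cfg: SyntheticConfig, expression: pd.Series,
                      max_attempts: int = 5) -> tuple[pd.Series, dict]:
    """Program-inclusion labels from a logistic model on expression quantiles."""
    rng = _rng(cfg, 4)
    q = quantile_scores(expression, cfg.drug_n_quantiles).to_numpy(float)
    eta = cfg.drug_alpha + cfg.drug_beta * q
    prob = 1.0 / (1.0 + np.exp(-eta))
    for attempt in range(max_attempts):
        labels = (rng.random(len(q)) < prob).astype(int)
        if 0 < labels.sum() < len(labels):
            truth = {"odds_ratio": float(np.exp(cfg.drug_beta)),
                     "alpha": cfg.drug_alpha, "beta": cfg.drug_beta}
            return pd.Series(labels, index=expression.index), truth
        import warnings
        warnings.warn(f"degenerate labels on attempt {attempt + 1}; regenerating")
    raise ValueError("could not generate non-degenerate labels; adjust alpha/beta")


def synth_cells(cfg: SyntheticConfig, n_genes: int = 200
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Negative-binomial single-cell counts with cell-type mean profiles.

    Returns (gene-by-cell counts, cell metadata, truth with the per-type
    mean profiles and planted marker genes).
    """
    if cfg.n_cell_types < 2 or cfg.n_donors < 1:
        raise ValueError("need at least 2 cell types and 1 donor")
    rng = _rng(cfg, 5)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    types = [f"type_{t}" for t in range(cfg.n_cell_types)]
    base = rng.gamma(2.0, 1.0, size=n_genes)
    type_mean = np.tile(base[:, None], (1, cfg.n_cell_types))
    # plant one marker gene per cell type (strongly elevated there)
    markers = {}
    for t in range(cfg.n_cell_types):
        g = t  # first genes are the markers
        type_mean[g, :] = 0.01
        type_mean[g, t] = base[g] * 50 + 10
        markers[types[t]] = genes[g]
    cells, rows = [], []
    counts = []
    for t, tname in enumerate(types):
        for c in range(cfg.cells_per_type):
            donor = f"donor_{rng.integers(0, cfg.n_donors)}"
            cid = f"{tname}_c{c:03d}"
            mu = type_mean[:, t] * rng.lognormal(0.0, 0.1)
            r = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(r, mu / r)
            counts.append(rng.poisson(lam))
            cells.append(cid)
            rows.append({"cell_id": cid, "cell_type": tname, "donor": donor,
                         "tissue": "tissue_0"})
    mat = pd.DataFrame(np.array(counts).T, index=genes, columns=cells)
    keep = mat.sum(axis=0) > 0
    mat = mat.loc[:, keep]
    meta = pd.DataFrame(rows).set_index("cell_id").loc[mat.columns]
    truth = {"markers": markers,
             "type_means": {t: type_mean[:, i].tolist()
                            for i, t in enumerate(types)}}
    return mat, meta, truth


# ---------------------------------------------------------------------------
# File emission (formats the pipeline readers accept)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)


def write_mtx(counts: pd.DataFrame, prefix) -> None:
    """MatrixMarket coordinate file plus genes.tsv / cells.tsv."""
    from pathlib import Path

    from scipy import io as sio
    from scipy import sparse

    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")),
                sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(prefix.parent / "genes.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(counts.columns).to_csv(prefix.parent / "cells.tsv", sep="\t",
                                     index=False, header=False)


def read_mtx(prefix) -> pd.DataFrame:
    from pathlib import Path

    from scipy import io as sio

    prefix = Path(prefix)
    genes = pd.read_csv(prefix.parent / "genes.tsv", sep="\t",
                        header=None)[0].tolist()
    cells = pd.read_csv(prefix.parent / "cells.tsv", sep="\t",
                        header=None)[0].tolist()
    mat = sio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(int)
    return pd.DataFrame(mat, index=genes, columns=cells)
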