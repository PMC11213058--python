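"""End-to-end orchestration from a single validated configuration.

A run configuration (YAML/dict) toggles stages, carries per-stage
parameters and a single seed that every stochastic step derives its
substream from.  ``run`` executes the enabled stages in dependency order —
synthetic-data generation, the disease-gene scan, the GWAS-signal
enrichment, variance partitioning and the drug-odds arm — writing one TSV
per stage plus a manifest (config hash, seed, package version) so a rerun
with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drug_development import label_genes, run_drug_scan
from .expression_to_gwas import run_enrichment
from .gene_sets import GeneList, clump, nearest_gene
from .gwas_to_expression import (ScanConfig, results_to_wide, run_scan,
                                 select_relevant_tissues)
from .synthetic_data import (SyntheticConfig, synth_annotation,
                             synth_drug_labels, synth_expression, synth_gwas,
                             synth_samples)
from .variance_partition import partition_all

logger = logging.getLogger(__name__)

__all__ = ["validate", "run", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "exprland_run",
    "stages": {
        "synth": True,
        "scan": True,
        "enrich": True,
        "varpart": True,
        "drugs": True,
    },
    "inputs": {},  # paths to real data; empty means synthetic stage feeds all
    "synth": {},  # SyntheticConfig overrides
    "scan": {"metrics": ["absolute", "relative"], "tests": ["t", "AD"],
             "n_perm": 10000, "log2_relative": True, "alpha": 0.05},
    "enrich": {"up_bp": 35000, "down_bp": 10000, "exclude_mhc": True,
               "min_set_size": 10},
    "varpart": {"n_genes": 50},
    "drugs": {"quantile_grids": [10, 100]},
}


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and isinstance(val, dict) and \
                key not in ("inputs", "synth"):
            out[key] = _deep_merge(base[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def validate(config: dict | None = None) -> dict:
    """Fill defaults, reject unknown keys and stamp a manifest hash."""
    cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    synth_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(cfg["synth"]) - synth_fields
    if unknown:
        raise ValueError(f"unknown synth config key(s): {sorted(unknown)}")
    missing = [p for p in cfg["inputs"].values() if not Path(p).exists()]
    if missing:
        raise ValueError(f"missing input path(s): {missing}")
    payload = json.dumps(cfg, sort_keys=True, default=str)
    cfg["_manifest"] = {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "seed": cfg["seed"],
        "version": __version__,
    }
    return cfg


def _write(df: pd.DataFrame, outdir: Path, name: str, index=False) -> None:
    df.to_csv(outdir / name, sep="\t", index=index, float_format="%.10g")


def run(config: dict) -> Path:
    """Execute the enabled stages; returns the output directory."""
    cfg = config if "_manifest" in config else validate(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfg["_manifest"], fh, indent=2)

    if not stages.get("synth", False):
        logger.info("run: synthetic stage disabled and no loaders requested; "
                    "manifest written only")
        return outdir

    scfg = SyntheticConfig(seed=seed, **cfg["synth"])
    profile, expr_truth = synth_expression(scfg)
    annotation = synth_annotation(scfg)
    stats, ld, _ = synth_gwas(scfg, annotation, expr_truth["disease_genes"])
    profile.tpm.to_csv(outdir / "expression_tpm.tsv", sep="\t",
                       index_label="gene_id")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(expr_truth, fh, indent=2)

    cres = clump(stats, ld)
    nearest = nearest_gene(cres.index_variants, stats, annotation,
                           disease="synthetic")
    planted = GeneList(name="synthetic_planted", disease="synthetic",
                       method="finemapped",
                       gene_ids=list(expr_truth["disease_genes"]))
    gene_lists = [planted, nearest] if len(nearest) >= 2 else [planted]

    scan_res = None
    if stages.get("scan", False):
        sc = cfg["scan"]
        scan_res = run_scan(profile, gene_lists,
                            ScanConfig(metrics=tuple(sc["metrics"]),
                                       tests=tuple(sc["tests"]),
                                       n_perm=sc["n_perm"],
                                       log2_relative=sc["log2_relative"],
                                       alpha=sc["alpha"]),
                            seed=seed)
        _write(scan_res, outdir, "scan_results.tsv")
        _write(results_to_wide(scan_res).reset_index(), outdir,
               "scan_neglog10p_wide.tsv")

    if stages.get("enrich", False):
        en = cfg["enrich"]
        enr = run_enrichment(profile, stats, annotation, ld,
                             up_bp=en["up_bp"], down_bp=en["down_bp"],
                             exclude_mhc=en["exclude_mhc"],
                             min_set_size=en["min_set_size"])
        _write(enr, outdir, "enrichment_results.tsv")

    if stages.get("varpart", False):
        expr, meta, vp_truth = synth_samples(scfg,
                                             n_genes=cfg["varpart"]["n_genes"])
        vp = partition_all(expr, meta)
        _write(vp.fractions.reset_index().rename(columns={"index": "gene_id"}),
               outdir, "variance_fractions.tsv")

    if stages.get("drugs", False) and scan_res is not None:
        sc = cfg["scan"]
        relevant = select_relevant_tissues(
            scan_res[scan_res["gene_list"] == planted.name],
            n_contexts=len(profile.context_ids), n_lists=len(gene_lists),
            n_tests=len(sc["tests"]))
        vals = profile.A[profile.context_ids[0]]
        labels, _ = synth_drug_labels(scfg, vals.loc[planted.gene_ids])
        drug = run_drug_scan(profile, relevant, labels,
                             quantile_grids=tuple(cfg["drugs"]["quantile_grids"]))
        _write(drug, outdir, "drug_odds.tsv")

    logger.info("run: outputs in %s", outdir)
    return outdir
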