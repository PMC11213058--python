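"""Disease-gene and control-gene list construction from GWAS results.

Three routes define a disease's gene list: the nearest protein-coding gene to
each clumped GWAS index variant, externally fine-mapped gene lists, and the
top percentile of PoPS prioritisation scores.  Controls are either all
protein-coding genes expressed in the analysed context, a gold-standard GWAS
gene list, or genes above an Open-Targets-style locus-to-gene (L2G) score
cutoff — always minus the disease genes themselves.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "SummaryStats",
    "LDMatrix",
    "GeneList",
    "ClumpResult",
    "parse_gtf",
    "clump",
    "nearest_gene",
    "top_pops",
    "build_control",
    "load_gene_list",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GeneAnnotation:
    """Gene-level annotation table: gene_id, symbol, chrom, start, end, strand, biotype.

    Coordinates are 1-based inclusive (GTF convention).
    """

    table: pd.DataFrame  # indexed by gene_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate gene_id in annotation")
        if (t["start"] > t["end"]).any():
            raise ValueError("gene with start > end")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def protein_coding(self) -> "GeneAnnotation":
        return GeneAnnotation(self.table[self.table["biotype"] == "protein_coding"])

    def autosomal(self) -> "GeneAnnotation":
        keep = self.table["chrom"].isin(_AUTOSOMES)
        return GeneAnnotation(self.table[keep])

    def resolve_symbols(self, names) -> tuple[list[str], list[str]]:
        """Map a mix of gene ids and symbols to gene ids; return (ids, unresolved)."""
        by_symbol = {}
        for gid, sym in self.table["symbol"].items():
            by_symbol.setdefault(sym, gid)
        ids, missing = [], []
        known = set(self.table.index)
        for name in names:
            if name in known:
                ids.append(name)
            elif name in by_symbol:
                ids.append(by_symbol[name])
            else:
                missing.append(name)
        return ids, missing


@dataclass
class SummaryStats:
    """Per-variant GWAS association p-values."""

    table: pd.DataFrame  # columns: variant_id, chrom, pos, p; indexed by variant_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate variant ids")
        p = t["p"].to_numpy()
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in (0, 1]")


class LDMatrix:
    """Sparse symmetric pairwise r-squared; absent pairs are zero."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), v in pairs.items():
                self.set(a, b, v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 out of range for pair ({a}, {b}): {r2}")
        if a != b:
            self._r2[self._key(a, b)] = min(float(r2), 1.0)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        ld = cls()
        for a, b, v in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            ld.set(str(a), str(b), float(v))
        return ld

    @classmethod
    def from_genotypes(cls, genotypes: pd.DataFrame) -> "LDMatrix":
        """r² as squared Pearson correlation of dosage columns (variants)."""
        ld = cls()
        ids = list(genotypes.columns)
        g = genotypes.to_numpy(dtype=float)
        sd = g.std(axis=0)
        ok = sd > 0
        corr = np.corrcoef(g[:, ok], rowvar=False)
        kept = [i for i, flag in enumerate(ok) if flag]
        for ii, i in enumerate(kept):
            for jj, j in enumerate(kept):
                if jj <= ii:
                    continue
                ld.set(ids[i], ids[j], float(corr[ii, jj] ** 2))
        return ld

    def to_tsv(self, path) -> None:
        rows = [(a, b, v) for (a, b), v in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["id1", "id2", "r2"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class GeneList:
    """A named gene set with the method that produced it."""

    name: str
    disease: str
    method: str  # nearest | finemapped | pops | control_all | control_goldstd | control_l2g
    gene_ids: list[str]
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.gene_ids:
            seen.setdefault(g, None)
        self.gene_ids = list(seen)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def as_set(self) -> set[str]:
        return set(self.gene_ids)


@dataclass
class ClumpResult:
    """Index variants in ascending-p order, with the members absorbed by each."""

    index_variants: list[str]
    members: dict[str, list[str]]


# ---------------------------------------------------------------------------
# GTF parsing


def parse_gtf(path, biotype_filter: str | None = None,
              autosomes_only: bool = False) -> GeneAnnotation:
    """Gene-level records from an Ensembl-dialect GTF.

    Only ``gene`` feature lines are consumed; each must carry ``gene_id`` and
    a biotype attribute (``gene_biotype`` or ``gene_type``).  Coordinates are
    kept 1-based inclusive and chromosome names normalised (``chr1`` → ``1``).
    """
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
            if gid in seen:
                warnings.warn(f"duplicate gene_id {gid} at line {lineno}; keeping first")
                continue
            seen.add(gid)
            rows.append({
                "gene_id": gid,
                "symbol": attr.get("gene_name", gid),
                "chrom": normalize_chrom(chrom),
                "start": start_i,
                "end": end_i,
                "strand": strand if strand in "+-" else "+",
                "biotype": attr.get("gene_biotype", attr.get("gene_type", "")),
            })
    if not rows:
        raise ValueError(f"no gene records found in {path}")
    table = pd.DataFrame(rows).set_index("gene_id")
    ann = GeneAnnotation(table)
    if biotype_filter:
        ann = GeneAnnotation(ann.table[ann.table["biotype"] == biotype_filter])
    if autosomes_only:
        ann = ann.autosomal()
    if ann.table.empty:
        raise ValueError("annotation empty after filtering")
    return ann


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Serialise gene-level records back to GTF (round-trips parse_gtf)."""
    with open(path, "w") as fh:
        for gid, row in annotation.table.iterrows():
            attrs = (f'gene_id "{gid}"; gene_name "{row["symbol"]}"; '
                     f'gene_biotype "{row["biotype"]}";')
            fh.write("\t".join([
                str(row["chrom"]), "exprland", "gene", str(row["start"]),
                str(row["end"]), ".", row["strand"], ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Clumping


def clump(stats: SummaryStats, ld: LDMatrix, p1: float = 5e-8,
          window_bp: int = 250_000, r2: float = 0.5, p2: float = 0.01,
          drop_p2_globally: bool = False) -> ClumpResult:
    """Greedy LD clumping of GWAS variants.

    Repeatedly the lowest-p remaining variant with p <= ``p1`` becomes an
    index; variants within ``window_bp`` of it with pairwise r² >= ``r2`` are
    absorbed into its clump.  Variants with p >= ``p2`` are never clump
    members (set ``drop_p2_globally`` to discard them outright).
    """
    t = stats.table.sort_values("p", kind="mergesort")
    if drop_p2_globally:
        t = t[t["p"] < p2]
    avail = dict(zip(t.index, zip(t["chrom"].map(normalize_chrom), t["pos"], t["p"])))
    order = list(t.index)
    index_variants: list[str] = []
    members: dict[str, list[str]] = {}
    taken: set[str] = set()
    for vid in order:
        if vid in taken or vid not in avail:
            continue
        chrom, pos, p = avail[vid]
        if p > p1:
            break  # sorted by p: nothing below threshold remains
        index_variants.append(vid)
        taken.add(vid)
        clumped: list[str] = []
        for other in order:
            if other in taken:
                continue
            ochrom, opos, op = avail[other]
            if ochrom != chrom or abs(opos - pos) > window_bp:
                continue
            if op >= p2:
                continue  # never eligible as a clump member
            if ld.r2(vid, other) >= r2:
                clumped.append(other)
                taken.add(other)
        members[vid] = clumped
    return ClumpResult(index_variants=index_variants, members=members)


# ---------------------------------------------------------------------------
# Gene list construction


def _distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def nearest_gene(index_variants: list[str], stats: SummaryStats,
                 annotation: GeneAnnotation, disease: str = "",
                 name: str | None = None) -> GeneList:
    """Nearest protein-coding gene per index variant (distance 0 inside the body)."""
    ann = annotation.table
    rows = []
    for vid in index_variants:
        chrom = normalize_chrom(stats.table.loc[vid, "chrom"])
        pos = int(stats.table.loc[vid, "pos"])
        cand = ann[ann["chrom"] == chrom]
        if cand.empty:
            warnings.warn(f"no genes on chromosome {chrom} for variant {vid}; skipped")
            continue
        d = np.minimum(np.abs(pos - cand["start"]), np.abs(pos - cand["end"]))
        inside = (cand["start"] <= pos) & (pos <= cand["end"])
        d = d.where(~inside, 0)
        best = d.idxmin()
        rows.append({"index_variant": vid, "gene_id": best,
                     "distance_bp": int(d.loc[best])})
    meta = pd.DataFrame(rows)
    genes = list(meta["gene_id"]) if len(meta) else []
    if len(meta):
        logger.info("nearest_gene: %d indices -> %d unique genes, median distance %.0f bp",
                    len(meta), len(set(genes)), meta["distance_bp"].median())
    return GeneList(name=name or f"{disease}_nearest", disease=disease,
                    method="nearest", gene_ids=genes, metadata=meta)


def top_pops(scores: pd.DataFrame, annotation: GeneAnnotation | None = None,
             top_pct: float = 1.0, disease: str = "",
             name: str | None = None) -> GeneList:
    """Top percentile of PoPS scores within the protein-coding universe.

    Selects ceil(top_pct/100 * N) genes; a tie at the cut is broken by
    gene-id order so the selection is deterministic.
    """
    if len(scores) == 0:
        raise ValueError("empty PoPS score table")
    if isinstance(scores, pd.Series):
        s = scores.astype(float)
    else:
        t = scores
        if t.columns[0].lower() in ("gene", "gene_id"):
            t = t.set_index(t.columns[0])
        s = t.iloc[:, 0].astype(float)
    if annotation is not None:
        keep = s.index.intersection(annotation.gene_ids)
        s = s.loc[keep]
    if s.empty:
        raise ValueError("no PoPS genes left after restricting to the annotation")
    k = math.ceil(top_pct / 100.0 * len(s))
    ordered = s.sort_values(ascending=False, kind="mergesort")
    # stable sort on descending score then ascending gene_id for ties
    ordered = ordered.iloc[np.lexsort((ordered.index, -ordered.to_numpy()))]
    cut_score = ordered.iloc[k - 1]
    if (s == cut_score).sum() > 1:
        logger.info("top_pops: tie at the cut score %.6g broken by gene id", cut_score)
    chosen = list(ordered.index[:k])
    meta = pd.DataFrame({"gene_id": chosen, "pops_score": ordered.iloc[:k].to_numpy()})
    return GeneList(name=name or f"{disease}_pops", disease=disease,
                    method="pops", gene_ids=chosen, metadata=meta)


def build_control(universe, disease_genes, mode: str = "all",
                  gold_standard=None, l2g_table: pd.DataFrame | None = None,
                  l2g_threshold: float = 0.8, disease: str = "") -> GeneList:
    """Control gene group for a disease list.

    * ``all`` — every gene of the universe (protein-coding genes expressed in
      the analysed context) that is not a disease gene;
    * ``goldstd`` — a supplied gold-standard list minus disease genes;
    * ``l2g`` — genes with L2G score >= threshold minus disease genes.
    """
    disease_set = set(disease_genes)
    if mode == "all":
        pool = [g for g in universe if g not in disease_set]
    elif mode == "goldstd":
        if gold_standard is None:
            raise ValueError("goldstd mode requires a gold_standard list")
        pool = [g for g in gold_standard if g not in disease_set]
    elif mode == "l2g":
        if l2g_table is None:
            raise ValueError("l2g mode requires an evidence table")
        t = l2g_table.set_index(l2g_table.columns[0]) \
            if l2g_table.columns[0] in ("gene", "gene_id") else l2g_table
        s = t.iloc[:, 0]
        pool = [g for g in s.index[s >= l2g_threshold] if g not in disease_set]
    else:
        raise ValueError(f"unknown control mode {mode!r}")
    if not pool:
        raise ValueError(f"empty control set for mode {mode!r}")
    return GeneList(name=f"{disease}_control_{mode}", disease=disease,
                    method=f"control_{mode}", gene_ids=pool)


def load_gene_list(path, annotation: GeneAnnotation | None = None,
                   disease: str = "", method: str = "finemapped",
                   name: str | None = None) -> GeneList:
    """Read a gene list: one id/symbol per line, or a 2-column (gene, disease) TSV.

    Symbols are resolved to gene ids through the annotation; unresolved names
    are logged and dropped.
    """
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            names.append(fields[0])
    if names and names[0].lower() in ("gene", "gene_id", "symbol"):
        names = names[1:]
    if annotation is not None:
        ids, missing = annotation.resolve_symbols(names)
        if missing:
            warnings.warn(f"{len(missing)} unresolved gene name(s) dropped: "
                          f"{missing[:5]}")
    else:
        ids = names
    if not ids:
        raise ValueError(f"no resolvable genes in {path}")
    return GeneList(name=name or f"{disease}_{method}", disease=disease,
                    method=method, gene_ids=ids)
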