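import numpy as np
import pandas as pd
import pytest

from exprland.gene_sets import GeneAnnotation, LDMatrix, SummaryStats


@pytest.fixture
def small_annotation() -> GeneAnnotation:
    """Three protein-coding genes on one chromosome, one on chrX."""
    df = pd.DataFrame(
        {
            "symbol": ["ALPHA", "BETA", "GAMMA", "XLINK"],
            "chrom": ["1", "1", "1", "X"],
            "start": [100_000, 500_000, 900_000, 5_000],
            "end": [120_000, 520_000, 920_000, 9_000],
            "strand": ["+", "+", "-", "+"],
            "biotype": ["protein_coding"] * 4,
        },
        index=pd.Index(["g1", "g2", "g3", "gx"], name="gene_id"),
    )
    return GeneAnnotation(df)


def make_stats(rows) -> SummaryStats:
    """rows: list of (variant_id, chrom, pos, p)."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])
    df = df.set_index("variant_id", drop=False)
    df.index.name = None
    return SummaryStats(df)


@pytest.fixture
def three_variant_stats() -> SummaryStats:
    return make_stats([
        ("A", "1", 100_000, 1e-10),
        ("B", "1", 150_000, 1e-9),
        ("C", "1", 140_000, 1e-8),
    ])


@pytest.fixture
def three_variant_ld() -> LDMatrix:
    ld = LDMatrix()
    ld.set("A", "B", 0.8)
    ld.set("A", "C", 0.1)
    return ld


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
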