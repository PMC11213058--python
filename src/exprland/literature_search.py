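"""PubMed query construction for tissue–disease pairs.

Two query modes are supported: MeSH-term queries
(``<tissue> [Mesh] AND <disease> [Mesh]``) and Title/Abstract keyword
queries (``<tissue> [Title/Abstract] AND <disease> [Title/Abstract]``).
Counting is delegated to an injectable fetcher callable so tests (and
offline runs) never touch the network; counts are descriptive evidence only
and no statistic is computed on them.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Callable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["QuerySpec", "build_query", "build_queries", "count_results"]

_TEMPLATES = {
    "mesh": "{tissue} [Mesh] AND {disease} [Mesh]",
    "tiab": "{tissue} [Title/Abstract] AND {disease} [Title/Abstract]",
}


@dataclass(frozen=True)
class QuerySpec:
    tissue: str
    disease: str
    mode: str
    query: str


def build_query(tissue: str, disease: str, mode: str = "mesh") -> QuerySpec:
    """Render one tissue–disease pair into a PubMed query string."""
    if not tissue or not disease:
        raise ValueError("tissue and disease terms must be non-empty")
    if mode not in _TEMPLATES:
        raise ValueError(f"unknown mode {mode!r}; use 'mesh' or 'tiab'")
    return QuerySpec(tissue, disease, mode,
                     _TEMPLATES[mode].format(tissue=tissue, disease=disease))


def build_queries(tissues, diseases, modes=("mesh", "tiab")) -> list[QuerySpec]:
    return [build_query(t, d, m) for m in modes for t in tissues for d in diseases]


def count_results(queries, fetcher: Callable[[str], int]) -> pd.DataFrame:
    """One literature count per query via the supplied fetcher.

    The fetcher maps a query string to a hit count (live HTTP, a recorded
    fixture, or a stub).  It is memoised here so duplicate queries cost one
    call; a fetcher exception yields an NA row and the scan continues.
    """
    cache: dict[str, int] = {}
    rows = []
    now = datetime.datetime.now().isoformat(timespec="seconds")
    for q in queries:
        row = {"tissue": q.tissue, "disease": q.disease, "mode": q.mode,
               "query": q.query, "retrieved_at": now}
        try:
            if q.query not in cache:
                cache[q.query] = int(fetcher(q.query))
            count = cache[q.query]
            if count < 0:
                raise ValueError("negative count")
            row.update(count=count, error="")
        except Exception as exc:  # keep scanning on fetcher failure
            logger.warning("count_results: query failed (%s): %s", q.query, exc)
            row.update(count=pd.NA, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
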