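"""Gene-set over-representation analysis (ORA).

A query gene list (e.g. the mutated genes of a tumor subset) is tested
against named gene sets with the hypergeometric upper tail, followed by
Benjamini-Hochberg adjustment. Defaults mirror a common pathway-portal
configuration: sets need at least 3 overlapping genes to be scored and
results are reported at q < 0.05. The background universe must be explicit
(defaulting to the union of all gene-set members) because ORA p-values are
meaningless without a stated null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "ora_hypergeometric",
    "bh_adjust",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with a source-database tag per set."""

    sets: dict[str, frozenset]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean

    def universe(self) -> frozenset:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    source: str
    overlap: int
    overlap_genes: tuple[str, ...]
    set_size: int
    p: float
    q: float


def read_gmt(path, source: Optional[str] = None) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, genes per tab-separated
    line). The description field is kept as the source tag unless ``source``
    overrides it."""
    sets: dict[str, frozenset] = {}
    tags: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = frozenset(g.upper() for g in genes)
            tags[name] = source if source is not None else desc
    return GeneSetCollection(sets=sets, source=tags)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_hypergeometric(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    min_overlap: int = 3,
    q_max: Optional[float] = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each gene set.

    p = P(X >= k) for X ~ Hypergeometric(N = |universe|, K = |set in
    universe|, n = |query|). Sets overlapping the query in fewer than
    ``min_overlap`` genes are removed before BH adjustment; ``q_max`` filters
    the report (pass None to keep everything surviving the overlap rule).
    Query genes outside the universe are dropped with a logged count.
    """
    query_set = {str(g).upper() for g in query}
    if not query_set:
        raise ValueError("empty query gene list")
    uni = frozenset(str(g).upper() for g in universe) if universe is not None else sets.universe()
    if not uni:
        raise ValueError("empty universe")
    dropped = query_set - uni
    if dropped:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    query_set &= uni
    if not query_set:
        raise ValueError("no query genes left inside the universe")

    N, n = len(uni), len(query_set)
    logger.info("ORA universe: %d genes; query: %d genes", N, n)
    candidates = []
    for name, genes in sets.sets.items():
        genes_in_uni = genes & uni
        overlap = sorted(genes_in_uni & query_set)
        if len(overlap) < min_overlap:
            continue
        K = len(genes_in_uni)
        p = float(hypergeom.sf(len(overlap) - 1, N, K, n))
        candidates.append((name, overlap, K, p))

    if not candidates:
        return []
    qs = bh_adjust([c[3] for c in candidates])
    results = [
        EnrichmentResult(
            set_name=name,
            source=sets.source.get(name, ""),
            overlap=len(overlap),
            overlap_genes=tuple(overlap),
            set_size=K,
            p=p,
            q=float(q),
        )
        for (name, overlap, K, p), q in zip(candidates, qs)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    if q_max is not None:
        results = [r for r in results if r.q < q_max]
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set": r.set_name, "source": r.source, "overlap": r.overlap,
             "set_size": r.set_size, "p": r.p, "q": r.q,
             "genes": ";".join(r.overlap_genes)}
            for r in results
        ]
    )
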