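"""Gene-set overlap enrichment (hypergeometric "compute overlaps").

Given a query gene list and a GMT collection, each set is scored by the
hypergeometric upper-tail probability of its overlap with the query within a
gene universe (default: the union of all genes in the collection, the
MSigDB compute-overlaps convention), with Benjamini-Hochberg FDR across all
tested sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeometric_overlap(query_size: int, set_size: int, overlap: int,
                           universe_size: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, set, query)."""
    if not (0 <= overlap <= min(query_size, set_size)):
        raise ValueError("overlap must satisfy 0 <= x <= min(query, set)")
    if query_size > universe_size or set_size > universe_size:
        raise ValueError("query and set sizes cannot exceed the universe")
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def enrich_collection(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Overlap enrichment of ``query_genes`` against every set in ``gene_sets``.

    Returns one row per gene set that intersects the universe, sorted by FDR
    q then p then name, with the overlapping genes listed.  Gene order inside
    GMT lines is irrelevant (sets are treated as sets).
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    if universe is None:
        universe_set: set[str] = set()
        for genes in gene_sets.values():
            universe_set.update(genes)
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")

    query = set(query_genes) & universe_set
    if not query:
        raise ValueError("query does not intersect the gene universe")

    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe_set
        if not members:
            continue
        overlap = sorted(query & members)
        p = hypergeometric_overlap(len(query), len(members), len(overlap),
                                   len(universe_set))
        rows.append((name, len(members), len(overlap), ",".join(overlap), p))
    out = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap_size", "overlap_genes", "p_value"]
    )
    out["fdr_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return (
        out.sort_values(["fdr_q", "p_value", "set_name"], kind="mergesort")
        .reset_index(drop=True)
    )
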