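"""Mouse protein -> human gene symbol query construction.

Connectivity-map databases are transcriptional and human; a mouse protein
signature must be converted to disjoint up/down sets of human gene symbols
before querying.  Mapping policy:

* ids with no row in the ortholog table are dropped (counted ``unmapped``) —
  except ids that are already all-uppercase human-style symbols, which map to
  themselves (the conversion is idempotent on human symbols);
* ids mapping to more than one human symbol are dropped by default
  (``ambiguous="drop"``) or expanded to all targets (``ambiguous="expand"``);
* a human symbol reached from both the up and the down input (a collision)
  is removed from both sets — a gene cannot be simultaneously up and down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class QuerySignature:
    """Disjoint up/down human gene-symbol sets with mapping provenance."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    mapping_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def _targets_of(protein_id: str, lookup: dict[str, list[str]]) -> list[str]:
    if protein_id in lookup:
        return lookup[protein_id]
    if protein_id == protein_id.upper():
        return [protein_id]  # already a human-style symbol
    return []


def map_to_human(
    up_ids,
    down_ids,
    ortholog_table: pd.DataFrame,
    ambiguous: str = "drop",
) -> QuerySignature:
    """Convert mouse protein id sets into a human up/down query signature.

    ``ortholog_table`` needs columns ``mouse_protein_id`` and ``human_gene``
    (one row per mapping).  Raises if either resulting set is empty — a
    connectivity query needs both tails.
    """
    if ambiguous not in ("drop", "expand"):
        raise ValueError("ambiguous policy must be 'drop' or 'expand'")
    up_ids, down_ids = set(up_ids), set(down_ids)
    if up_ids & down_ids:
        raise ValueError("up and down input sets must be disjoint")

    lookup: dict[str, list[str]] = {}
    for pid, human in zip(
        ortholog_table["mouse_protein_id"], ortholog_table["human_gene"]
    ):
        lookup.setdefault(str(pid), []).append(str(human).upper())

    log = {"unmapped": 0, "ambiguous": 0, "collided": 0}
    provenance: dict[str, list[str]] = {}

    def convert(ids: set[str]) -> set[str]:
        out: set[str] = set()
        for pid in sorted(ids):
            targets = _targets_of(pid, lookup)
            if not targets:
                log["unmapped"] += 1
                continue
            if len(targets) > 1 and ambiguous == "drop":
                log["ambiguous"] += 1
                continue
            for gene in targets:
                out.add(gene)
                provenance.setdefault(gene, []).append(pid)
        return out

    up = convert(up_ids)
    down = convert(down_ids)
    collisions = up & down
    if collisions:
        log["collided"] = len(collisions)
        up -= collisions
        down -= collisions
    if not up or not down:
        raise ValueError(
            "mapping produced an empty up or down set; provide a larger signature "
            f"(mapping log: {log})"
        )
    return QuerySignature(
        up_genes=frozenset(up),
        down_genes=frozenset(down),
        provenance=provenance,
        mapping_log=log,
    )
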