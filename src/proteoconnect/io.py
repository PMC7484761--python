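"""Readers and writers for the pipeline's plain-text formats.

Formats:

* quant table TSV — ``protein_id``, ``gene_symbol``, ``n_peptides``,
  ``contaminant`` (0/1), then one column per sample named
  ``<GROUP>_<replicate>``; empty cell = missing value.
* ortholog map TSV — ``mouse_protein_id``, ``mouse_gene``, ``human_gene``;
  one row per mapping (1-to-many ids repeat on several rows).
* GMT — standard gene-set format: name, description, then member genes,
  tab separated, one set per line.
* compound-signature database — long-format TSV with columns ``compound``,
  ``instance_id``, ``gene``, ``rank`` (1 = most up-regulated).
* .grp — one gene symbol per line (the classic connectivity-map query file).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import ProteinQuantTable


# -- quant table ---------------------------------------------------------------

def write_quant_tsv(table: ProteinQuantTable, path: str) -> None:
    out = table.meta.copy()
    out.insert(0, "protein_id", table.protein_ids)
    out["contaminant"] = out["contaminant"].astype(int)
    for sample in table.samples:
        out[sample] = table.data[sample].to_numpy()
    # full repr precision so write -> read round-trips exactly
    out.to_csv(path, sep="\t", index=False)


def read_quant_tsv(path: str) -> ProteinQuantTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_symbol": str})
    required = ["protein_id", "gene_symbol", "n_peptides", "contaminant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"quant table is missing columns: {missing}")
    df = df.set_index("protein_id")
    sample_cols = [c for c in df.columns if c not in required]
    meta = df[["gene_symbol", "n_peptides", "contaminant"]].copy()
    meta["n_peptides"] = meta["n_peptides"].astype(int)
    meta["contaminant"] = meta["contaminant"].astype(bool)
    data = df[sample_cols].astype(float)
    groups = [_group_of(s) for s in sample_cols]
    design = pd.Series(groups, index=sample_cols, name="group")
    return ProteinQuantTable(data=data, meta=meta, design=design)


def _group_of(sample: str) -> str:
    """Sample names are ``<GROUP>_<replicate>``; the group may contain '+'."""
    group, _, rep = sample.rpartition("_")
    if not group or not rep.isdigit():
        raise ValueError(f"sample name {sample!r} is not of the form <GROUP>_<replicate>")
    return group


# -- ortholog map --------------------------------------------------------------

def write_ortholog_tsv(mapping: pd.DataFrame, path: str) -> None:
    cols = ["mouse_protein_id", "mouse_gene", "human_gene"]
    missing = [c for c in cols if c not in mapping.columns]
    if missing:
        raise ValueError(f"ortholog table is missing columns: {missing}")
    mapping[cols].to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("mouse_protein_id", "mouse_gene", "human_gene") if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table is missing columns: {missing}")
    return df


# -- GMT gene sets -------------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            sets[fields[0]] = fields[2:]
    return sets


# -- compound-signature database ----------------------------------------------

def write_compound_db_tsv(profiles: Iterable, path: str) -> None:
    """Write instance profiles (see :mod:`proteoconnect.connectivity`) long-format."""
    rows = []
    for prof in profiles:
        for rank, gene in enumerate(prof.ranking, start=1):
            rows.append((prof.compound, prof.instance_id, gene, rank))
    pd.DataFrame(rows, columns=["compound", "instance_id", "gene", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_compound_db_tsv(path: str) -> list:
    from .connectivity import InstanceProfile

    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "instance_id": str, "gene": str})
    profiles = []
    for (compound, instance_id), sub in df.groupby(["compound", "instance_id"], sort=False):
        sub = sub.sort_values("rank")
        ranks = sub["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError(
                f"instance {compound}/{instance_id}: ranks must be a permutation 1..N"
            )
        profiles.append(
            InstanceProfile(compound=compound, instance_id=str(instance_id),
                            ranking=tuple(sub["gene"]))
        )
    return profiles


# -- .grp query files ----------------------------------------------------------

def write_grp(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_grp(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
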