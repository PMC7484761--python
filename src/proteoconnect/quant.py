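"""Protein quantification table container.

A :class:`ProteinQuantTable` bundles a proteins x samples intensity matrix
(raw scale, NaN = not quantified) with per-protein annotation (gene symbol,
peptide count, contaminant flag) and the sample -> group design.  Samples are
named ``<GROUP>_<replicate>`` and each sample is, by default, its own
analytical run (single-injection acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("gene_symbol", "n_peptides", "contaminant")


@dataclass
class ProteinQuantTable:
    """Proteins x samples abundance matrix with design and annotation.

    Attributes
    ----------
    data
        DataFrame indexed by protein id; one float column per sample on the
        raw intensity scale, NaN where the protein was not quantified.
    meta
        DataFrame indexed like ``data`` with columns ``gene_symbol``,
        ``n_peptides`` and ``contaminant`` (bool).
    design
        Series mapping sample name -> group label, in column order.
    runs
        Series mapping sample name -> analytical run id.  Defaults to one
        run per sample.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    design: pd.Series
    runs: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.runs is None:
            self.runs = pd.Series(self.data.columns, index=self.data.columns, name="run")
        self.validate()

    def validate(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same protein index")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns: {missing}")
        if list(self.design.index) != list(self.data.columns):
            raise ValueError("design index must equal the sample columns, in order")
        if self.design.isna().any():
            raise ValueError("every sample must belong to exactly one group")
        values = self.data.to_numpy()
        observed = values[~np.isnan(values)]
        if observed.size and (~np.isfinite(observed)).any():
            raise ValueError("observed intensities must be finite")
        if observed.size and (observed < 0).any():
            raise ValueError("intensities must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.design):
            raise KeyError(f"unknown group label: {group!r}")
        return [s for s, g in self.design.items() if g == group]

    def n_proteins(self) -> int:
        return len(self.data)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            data=self.data.copy(),
            meta=self.meta.copy(),
            design=self.design.copy(),
            runs=self.runs.copy(),
        )

    def subset(self, protein_ids) -> "ProteinQuantTable":
        """Row subset preserving order of ``protein_ids``."""
        return ProteinQuantTable(
            data=self.data.loc[protein_ids],
            meta=self.meta.loc[protein_ids],
            design=self.design.copy(),
            runs=self.runs.copy(),
        )

    def log2(self) -> pd.DataFrame:
        """Log2 intensities (NaN preserved)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.data)

    def equals(self, other: "ProteinQuantTable") -> bool:
        return (
            self.data.equals(other.data)
            and self.meta.equals(other.meta)
            and self.design.equals(other.design)
            and self.runs.equals(other.runs)
        )
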