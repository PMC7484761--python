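"""Protein-table preprocessing.

The preprocessing chain for a label-free quant table, in order:

1. :func:`filter_proteins` — drop potential contaminants and proteins
   identified by fewer than two peptides.
2. :func:`median_normalize` — equalise per-sample log2 medians across all
   conditions.
3. :func:`quantification_filter` — per pairwise comparison, keep proteins
   quantified in at least ``min_obs`` replicates of at least one of the two
   groups (disjunctive rule).
4. :func:`impute_noise` — replace the remaining missing values with a
   constant noise floor per analytical run: a low percentile (default the
   1st) of that run's observed protein population.  Missingness in such data
   is left-censored (low-abundance measurements drop out preferentially), so
   the floor is an MNAR-appropriate stand-in.

An analytical run is one sample column by default (single-injection
acquisition: one run per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import ProteinQuantTable


@dataclass
class PreprocessReport:
    """Counts and missingness bookkeeping for a preprocessing pass."""

    n_input: int
    n_after_filters: int
    per_run_missing: dict[str, float] = field(default_factory=dict)
    mean_missing: float = 0.0
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if self.n_after_filters > self.n_input:
            raise ValueError("protein counts must be non-increasing through filters")
        for run, frac in self.per_run_missing.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"missing fraction for run {run!r} outside [0, 1]")


def filter_proteins(table: ProteinQuantTable, min_peptides: int = 2) -> ProteinQuantTable:
    """Remove contaminant-flagged rows and rows with < ``min_peptides`` peptides.

    Row order of the survivors is preserved; applying the filter twice is a
    no-op.
    """
    keep = (~table.meta["contaminant"]) & (table.meta["n_peptides"] >= min_peptides)
    return table.subset(table.protein_ids[keep.to_numpy()])


def median_normalize(table: ProteinQuantTable) -> ProteinQuantTable:
    """Equalise sample log2 medians to the grand median of the column medians.

    Each sample column is shifted on the log2 scale (a multiplicative factor
    on the raw scale) so that all per-sample medians over observed values
    coincide.  Any common target is equivalent up to a global shift — the
    grand median keeps the output on the input's scale.  Missing cells stay
    missing.  Idempotent.
    """
    log2 = table.log2()
    col_medians = log2.median(axis=0, skipna=True)
    empty = col_medians[col_medians.isna()]
    if len(empty):
        raise ValueError(f"sample(s) with no observed values: {list(empty.index)}")
    target = float(col_medians.median())
    factors = np.power(2.0, target - col_medians)
    out = table.copy()
    out.data = table.data.mul(factors, axis=1)
    return out


def quantification_filter(
    table: ProteinQuantTable, group_a: str, group_b: str, min_obs: int = 4
) -> pd.Series:
    """Boolean mask: protein quantified >= ``min_obs`` times in A **or** in B.

    The mask is comparison-specific and depends only on the missingness
    pattern, never on intensity magnitudes.
    """
    obs_a = table.data[table.samples_of(group_a)].notna().sum(axis=1)
    obs_b = table.data[table.samples_of(group_b)].notna().sum(axis=1)
    mask = (obs_a >= min_obs) | (obs_b >= min_obs)
    mask.name = f"retained_{group_a}_vs_{group_b}"
    return mask


def impute_noise(
    table: ProteinQuantTable,
    percentile: float = 1.0,
    method: str = "linear",
) -> ProteinQuantTable:
    """Replace missing cells with a per-run constant noise floor.

    The floor is the ``percentile``-th percentile (default 1%) of the run's
    observed intensity population, computed with numpy's ``method``
    convention (default linear interpolation between order statistics).
    Observed cells are untouched; the output has no missing cells.
    """
    out = table.copy()
    values = out.data.to_numpy(copy=True)
    runs = table.runs
    for run in dict.fromkeys(runs):
        cols = [i for i, s in enumerate(table.samples) if runs[s] == run]
        block = values[:, cols]
        observed = block[~np.isnan(block)]
        if observed.size == 0:
            raise ValueError(f"analytical run {run!r} has no observed values to impute from")
        floor = float(np.percentile(observed, percentile, method=method))
        block[np.isnan(block)] = floor
        values[:, cols] = block
    out.data = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    return out


def missing_report(table: ProteinQuantTable, n_input: int | None = None) -> PreprocessReport:
    """Per-run missing fractions (before imputation) and their mean."""
    per_run: dict[str, float] = {}
    runs = table.runs
    n_missing_total = 0
    for run in dict.fromkeys(runs):
        cols = [s for s in table.samples if runs[s] == run]
        block = table.data[cols]
        n_cells = block.size
        n_missing = int(block.isna().to_numpy().sum())
        n_missing_total += n_missing
        per_run[run] = n_missing / n_cells if n_cells else 0.0
    mean_missing = float(np.mean(list(per_run.values()))) if per_run else 0.0
    return PreprocessReport(
        n_input=n_input if n_input is not None else table.n_proteins(),
        n_after_filters=table.n_proteins(),
        per_run_missing=per_run,
        mean_missing=mean_missing,
        n_imputed=n_missing_total,
    )


def preprocess(
    table: ProteinQuantTable, min_peptides: int = 2
) -> tuple[ProteinQuantTable, PreprocessReport]:
    """Contaminant/peptide filter then median normalization, with a report.

    The per-comparison quantification filter and the imputation are applied
    later, inside each pairwise comparison (see
    :func:`proteoconnect.differential.run_comparison`), because both are
    comparison-specific.
    """
    n_input = table.n_proteins()
    filtered = filter_proteins(table, min_peptides=min_peptides)
    normalized = median_normalize(filtered)
    report = missing_report(normalized, n_input=n_input)
    return normalized, report
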