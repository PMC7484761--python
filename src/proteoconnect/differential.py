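"""Per-protein two-group differential abundance.

Each pairwise comparison (named Set1/Set2/Set3 in the four-arm design) is run
on log2 intensities after the comparison-specific quantification filter and
percentile-noise imputation: Welch's unequal-variance t-test by default
(Student's is config-selectable), Benjamini-Hochberg q-values computed over
the retained proteins, and a significance flag at raw p < alpha (q-based
selection is config-selectable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import impute_noise, quantification_filter
from .quant import ProteinQuantTable

#: Default pairwise comparisons, first-listed group minus second:
#: Set1 = disease vs control, Set2 = disease+drug vs disease,
#: Set3 = control+drug vs control.
COMPARISONS: dict[str, tuple[str, str]] = {
    "Set1": ("DKD", "WT"),
    "Set2": ("DKD+R", "DKD"),
    "Set3": ("WT+R", "WT"),
}

RESULT_COLUMNS = [
    "protein_id", "comparison", "log2fc", "t_stat", "df",
    "p_value", "q_value", "n_obs_a", "n_obs_b", "significant",
]


def welch_test(values_a, values_b, equal_var: bool = False):
    """Two-sided two-sample t-test on log2 values.

    Returns ``(t_stat, df, p_value, log2fc)`` with
    ``log2fc = mean(values_a) - mean(values_b)``.  Welch–Satterthwaite
    degrees of freedom unless ``equal_var``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue), float(a.mean() - b.mean())


def run_comparison(
    table: ProteinQuantTable,
    comparison_id: str,
    comparisons: dict[str, tuple[str, str]] | None = None,
    alpha: float = 0.05,
    test: str = "welch",
    selection_mode: str = "p",
    min_obs: int = 4,
    percentile: float = 1.0,
    percentile_method: str = "linear",
) -> pd.DataFrame:
    """Differential abundance for one pairwise comparison.

    Applies the quantification filter for this pair of groups, imputes the
    retained submatrix per analytical run, tests every retained protein on
    the log2 scale and computes BH q-values over the retained set.  Fully
    deterministic.

    Returns a volcano-ready DataFrame with one row per retained protein.
    """
    comparisons = comparisons or COMPARISONS
    if comparison_id not in comparisons:
        raise KeyError(f"unknown comparison {comparison_id!r}; known: {sorted(comparisons)}")
    group_a, group_b = comparisons[comparison_id]
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    if selection_mode not in ("p", "q"):
        raise ValueError("selection_mode must be 'p' or 'q'")

    mask = quantification_filter(table, group_a, group_b, min_obs=min_obs)
    retained = table.subset(table.protein_ids[mask.to_numpy()])
    if retained.n_proteins() == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    cols_a = retained.samples_of(group_a)
    cols_b = retained.samples_of(group_b)
    n_obs_a = retained.data[cols_a].notna().sum(axis=1).to_numpy()
    n_obs_b = retained.data[cols_b].notna().sum(axis=1).to_numpy()

    # Impute only the two groups under comparison (per analytical run).
    pair_cols = cols_a + cols_b
    pair = ProteinQuantTable(
        data=retained.data[pair_cols],
        meta=retained.meta,
        design=retained.design[pair_cols],
        runs=retained.runs[pair_cols],
    )
    imputed = impute_noise(pair, percentile=percentile, method=percentile_method)
    log2 = imputed.log2()
    a = log2[cols_a].to_numpy()
    b = log2[cols_b].to_numpy()

    res = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    t_stat = np.asarray(res.statistic, dtype=float)
    p_value = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    # Degenerate rows (zero variance in both groups, t undefined): p = 1.
    bad = ~np.isfinite(p_value)
    if bad.any():
        t_stat[bad] = 0.0
        p_value[bad] = 1.0

    q_value = multipletests(p_value, method="fdr_bh")[1]
    crit = p_value if selection_mode == "p" else q_value

    return pd.DataFrame(
        {
            "protein_id": retained.protein_ids,
            "comparison": comparison_id,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "df": df,
            "p_value": p_value,
            "q_value": q_value,
            "n_obs_a": n_obs_a,
            "n_obs_b": n_obs_b,
            "significant": crit < alpha,
        }
    ).reset_index(drop=True)


def run_all_comparisons(table: ProteinQuantTable, **kwargs) -> dict[str, pd.DataFrame]:
    """Run every comparison in :data:`COMPARISONS` (or ``kwargs['comparisons']``)."""
    comparisons = kwargs.get("comparisons") or COMPARISONS
    return {cid: run_comparison(table, cid, **kwargs) for cid in comparisons}
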