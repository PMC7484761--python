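from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proteoconnect import ProteinQuantTable, StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic synthetic study shared across tests."""
    cfg = StudyConfig(n_proteins=300, n_dkd_effect=60, n_ramipril_only=10, seed=11)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def high_power_study():
    """Strong planted effects (|log2 effect| >= 1.5) with exact drug reversal."""
    cfg = StudyConfig(
        n_proteins=800,
        n_dkd_effect=200,
        effect_log2_range=(1.5, 2.5),
        rs_reversal_range=(1.0, 1.0),
        n_ramipril_only=20,
        seed=7,
    )
    return generate_study(cfg)


def make_table(values, groups, n_peptides=None, contaminant=None, protein_ids=None):
    """Hand-built quant table: ``values`` is proteins x samples (np.nan = missing),
    ``groups`` one label per sample column."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    assert m == len(groups)
    counts: dict[str, int] = {}
    samples = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        samples.append(f"{g}_{counts[g]}")
    ids = protein_ids or [f"P{i:03d}" for i in range(n)]
    data = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=samples)
    meta = pd.DataFrame(
        {
            "gene_symbol": [f"Gene{i}" for i in range(n)],
            "n_peptides": n_peptides if n_peptides is not None else [5] * n,
            "contaminant": contaminant if contaminant is not None else [False] * n,
        },
        index=data.index,
    )
    return ProteinQuantTable(data=data, meta=meta,
                             design=pd.Series(list(groups), index=samples, name="group"))
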