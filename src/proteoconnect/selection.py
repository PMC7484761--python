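"""Signature selection: drug-insensitive and drug-sensitive disease proteins.

Given the three pairwise comparisons of the four-arm design —
Set1 = disease vs control, Set2 = disease+drug vs disease,
Set3 = control+drug vs control — the flowchart selects:

* **disease signature** (DKD-GPs): Set1-significant proteins, split by the
  sign of their Set1 log2 fold change;
* **drug-insensitive signature** (RI): disease proteins *not* significant in
  Set2 (candidates), minus those significant in Set3 (whose apparent
  insensitivity hides an unspecific drug response in healthy animals);
* **drug-sensitive signature** (RS): disease proteins significant in Set2
  with the *opposite* trend to Set1 (counter-regulated by the drug), minus
  those whose Set3 behaviour shows the same drug response in healthy animals
  (not disease-specific).

The Set3 removal rule for the RS branch is configurable (``filter2_policy``):
``"same"`` (default) removes candidates Set3-significant with the same sign
as their Set2 change, ``"opposite"`` with the opposite sign, ``"any"``
regardless of sign.

Proteins absent from a comparison (they failed that pair's quantification
filter) are treated as not significant there, and counted in the trace log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SignatureSets:
    """Selected protein sets plus the ordered trace of flowchart counts."""

    dkd_up: frozenset[str] = frozenset()
    dkd_down: frozenset[str] = frozenset()
    ri_up: frozenset[str] = frozenset()
    ri_down: frozenset[str] = frozenset()
    rs_up: frozenset[str] = frozenset()
    rs_down: frozenset[str] = frozenset()
    trace: dict[str, int] = field(default_factory=dict)

    @property
    def dkd(self) -> frozenset[str]:
        return self.dkd_up | self.dkd_down

    @property
    def ri(self) -> frozenset[str]:
        return self.ri_up | self.ri_down

    @property
    def rs(self) -> frozenset[str]:
        return self.rs_up | self.rs_down

    def validate(self) -> None:
        """Assert the flowchart's set algebra."""
        if self.dkd_up & self.dkd_down:
            raise ValueError("dkd_up and dkd_down overlap")
        if not self.ri <= self.dkd:
            raise ValueError("RI must be a subset of the disease signature")
        if not self.rs <= self.dkd:
            raise ValueError("RS must be a subset of the disease signature")
        if self.ri & self.rs:
            raise ValueError("RI and RS must be disjoint")
        t = self.trace
        if t:
            if len(self.ri) != t["n_filter3_candidates"] - t["n_filter4_removed"]:
                raise ValueError("RI size inconsistent with filter trace")
            if len(self.rs) != t["n_filter1_candidates"] - t["n_filter2_removed"]:
                raise ValueError("RS size inconsistent with filter trace")


def _by_protein(res: pd.DataFrame) -> pd.DataFrame:
    return res.set_index("protein_id")


def select_dkd_gps(res1: pd.DataFrame) -> tuple[frozenset[str], frozenset[str]]:
    """Disease signature: Set1-significant proteins split by fold-change sign.

    A significant protein with log2fc exactly 0 (impossible under continuous
    data) is excluded from both sets with a warning.
    """
    sig = res1[res1["significant"]]
    zero = sig[sig["log2fc"] == 0.0]
    if len(zero):
        logger.warning(
            "%d significant protein(s) with log2fc == 0 excluded from both directions",
            len(zero),
        )
    up = frozenset(sig.loc[sig["log2fc"] > 0, "protein_id"])
    down = frozenset(sig.loc[sig["log2fc"] < 0, "protein_id"])
    return up, down


def select_ri(
    res1: pd.DataFrame, res2: pd.DataFrame, res3: pd.DataFrame
) -> tuple[frozenset[str], frozenset[str], dict[str, int]]:
    """Drug-insensitive disease proteins with trace counts.

    Candidates (Filter 3) = disease proteins not significant in Set2; the
    final set removes candidates significant in Set3 (Filter 4).  Direction
    (up/down) is inherited from the Set1 sign.
    """
    dkd_up, dkd_down = select_dkd_gps(res1)
    dkd = dkd_up | dkd_down
    r2 = _by_protein(res2)
    r3 = _by_protein(res3)

    def sig_in(r: pd.DataFrame, pid: str) -> bool:
        # absent from the comparison -> treated as not significant
        return bool(r["significant"].get(pid, False))

    missing2 = sum(1 for p in dkd if p not in r2.index)
    missing3 = sum(1 for p in dkd if p not in r3.index)
    if missing2 or missing3:
        logger.info(
            "proteins absent from a comparison treated as non-significant: "
            "%d in Set2, %d in Set3", missing2, missing3,
        )

    candidates = frozenset(p for p in dkd if not sig_in(r2, p))
    removed = frozenset(p for p in candidates if sig_in(r3, p))
    final = candidates - removed
    trace = {
        "n_set1_sig": len(dkd),
        "n_set2_nonsig": int((~res2["significant"]).sum()),
        "n_filter3_candidates": len(candidates),
        "n_filter4_removed": len(removed),
        "n_ri_final": len(final),
    }
    return final & dkd_up, final & dkd_down, trace


def select_rs(
    res1: pd.DataFrame,
    res2: pd.DataFrame,
    res3: pd.DataFrame,
    filter2_policy: str = "same",
) -> tuple[frozenset[str], frozenset[str], dict[str, int]]:
    """Drug-sensitive (counter-regulated) disease proteins with trace counts.

    Candidates (Filter 1) = disease proteins significant in Set2 with sign
    opposite to Set1 (the drug pushes abundance back toward control).
    Filter 2 then removes candidates whose Set3 behaviour matches
    ``filter2_policy`` — a drug response reproduced in healthy animals is not
    disease-specific.
    """
    if filter2_policy not in ("same", "opposite", "any"):
        raise ValueError("filter2_policy must be 'same', 'opposite' or 'any'")
    dkd_up, dkd_down = select_dkd_gps(res1)
    dkd = dkd_up | dkd_down
    r1 = _by_protein(res1)
    r2 = _by_protein(res2)
    r3 = _by_protein(res3)

    candidates = frozenset(
        p for p in dkd
        if p in r2.index
        and bool(r2.loc[p, "significant"])
        and np.sign(r2.loc[p, "log2fc"]) == -np.sign(r1.loc[p, "log2fc"])
    )

    def filter2_hits(pid: str) -> bool:
        if pid not in r3.index or not bool(r3.loc[pid, "significant"]):
            return False
        if filter2_policy == "any":
            return True
        same = np.sign(r3.loc[pid, "log2fc"]) == np.sign(r2.loc[pid, "log2fc"])
        return same if filter2_policy == "same" else not same

    removed = frozenset(p for p in candidates if filter2_hits(p))
    final = candidates - removed
    trace = {
        "n_set2_sig": int(res2["significant"].sum()),
        "n_filter1_candidates": len(candidates),
        "n_filter2_removed": len(removed),
        "n_rs_final": len(final),
    }
    return final & dkd_up, final & dkd_down, trace


def select_signatures(
    res1: pd.DataFrame,
    res2: pd.DataFrame,
    res3: pd.DataFrame,
    filter2_policy: str = "same",
) -> SignatureSets:
    """Run both branches of the flowchart and assemble a validated result."""
    dkd_up, dkd_down = select_dkd_gps(res1)
    ri_up, ri_down, ri_trace = select_ri(res1, res2, res3)
    rs_up, rs_down, rs_trace = select_rs(res1, res2, res3, filter2_policy=filter2_policy)
    sets = SignatureSets(
        dkd_up=dkd_up, dkd_down=dkd_down,
        ri_up=ri_up, ri_down=ri_down,
        rs_up=rs_up, rs_down=rs_down,
        trace={**ri_trace, **rs_trace},
    )
    sets.validate()
    return sets


def flowchart_report(sets: SignatureSets) -> tuple[str, pd.DataFrame]:
    """Human-readable trace plus a TSV-ready table of the flowchart counts.

    The RI fraction is 100 * |RI| / |disease signature|, truncated to a whole
    percent; reported as None when the disease signature is empty.
    """
    n_dkd = len(sets.dkd)
    fraction = int(100 * len(sets.ri) / n_dkd) if n_dkd else None
    rows = list(sets.trace.items()) + [
        ("n_dkd_up", len(sets.dkd_up)),
        ("n_dkd_down", len(sets.dkd_down)),
        ("n_ri_up", len(sets.ri_up)),
        ("n_ri_down", len(sets.ri_down)),
        ("n_rs_up", len(sets.rs_up)),
        ("n_rs_down", len(sets.rs_down)),
        ("ri_fraction_pct", -1 if fraction is None else fraction),
    ]
    table = pd.DataFrame(rows, columns=["quantity", "count"])
    lines = [f"{k}: {v}" for k, v in rows[:-1]]
    lines.append(
        "ri_fraction_pct: undefined (empty disease signature)"
        if fraction is None else f"ri_fraction_pct: {fraction}"
    )
    return "\n".join(lines), table


def ri_fraction_pct(n_ri: int, n_dkd: int) -> int | None:
    """Share of the disease signature insensitive to the drug, truncated to a
    whole percent (the convention the field's summary figures use)."""
    if n_dkd == 0:
        return None
    return int(100 * n_ri / n_dkd)
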