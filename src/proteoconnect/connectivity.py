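"""Connectivity mapping: KS enrichment of a query signature against a
compound-signature database.

The database holds, per compound *instance*, a complete ranking of the gene
universe by drug-induced differential expression (rank 1 = most
up-regulated).  Scoring follows the classic connectivity-map construction:

* per instance, a weighted two-tail Kolmogorov–Smirnov statistic for the up
  tags and the down tags of the query (:func:`ks_statistic`), combined into a
  raw connectivity score ``ks_up - ks_down`` when the two tails disagree in
  sign, else 0 (:func:`instance_connectivity`);
* raw scores scaled into [-1, 1] by dividing positives by the maximum
  positive and negatives by the magnitude of the minimum negative
  (:func:`scale_scores`);
* per compound, the KS enrichment of its instances' positions within all
  instances ordered by scaled score (:func:`compound_enrichment`), a
  permutation p-value, a specificity against null queries, and the percent of
  instances supporting the connection's sign (:func:`summarize`);
* a simplified modern-CMap analogue (:func:`cmap2_score`) on per-compound
  aggregated rankings, normalised and percentile-standardised to [-100, 100].

A *negative* enrichment means the compound's expression profile opposes the
query — the drug is predicted to reverse the signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class InstanceProfile:
    """One compound instance: a full ranking of the gene universe."""

    compound: str
    instance_id: str
    ranking: tuple[str, ...]  # position 0 = rank 1 = most up-regulated

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError(
                f"instance {self.compound}/{self.instance_id}: ranking must be a "
                "strict permutation (duplicate genes found)"
            )

    def rank_of(self) -> dict[str, int]:
        """Gene -> 1-based rank."""
        return {g: i + 1 for i, g in enumerate(self.ranking)}


@dataclass(frozen=True)
class CompoundSummary:
    name: str
    mean: float
    n: int
    enrichment: float
    p: float
    specificity: float
    percent_non_null: int
    low_n: bool = False


@dataclass(frozen=True)
class CMap2Result:
    name: str
    wtcs: float
    ncs: float
    score: float


# -- KS statistic ----------------------------------------------------------------


def ks_statistic(tag_positions: Sequence[int], n_total: int) -> float:
    """Two-sided KS enrichment of ``n`` tag positions in a ranked list of ``N``.

    With V(1) < ... < V(n) the sorted tag positions (1-based),

        a = max_j [ j/n - V(j)/N ]
        b = max_j [ V(j)/N - (j-1)/n ]

    and the statistic is ``a`` if a > b else ``-b``.  Positive values mean
    tags concentrated at the top of the list, negative at the bottom.
    """
    positions = np.asarray(sorted(tag_positions), dtype=float)
    n = positions.size
    if n == 0:
        raise ValueError("empty tag set")
    if n > n_total:
        raise ValueError("more tags than list entries")
    if positions[0] < 1 or positions[-1] > n_total:
        raise ValueError("positions must lie in 1..N")
    if np.unique(positions).size != n:
        raise ValueError("positions must be distinct")
    j = np.arange(1, n + 1, dtype=float)
    a = float(np.max(j / n - positions / n_total))
    b = float(np.max(positions / n_total - (j - 1) / n))
    return a if a > b else -b


def instance_connectivity(query, profile: InstanceProfile,
                          rank_map: dict[str, int] | None = None) -> float:
    """Raw connectivity score of a query against one instance.

    ``raw_s = ks_up - ks_down`` when the two tail statistics disagree in
    sign, else 0.  Negative when the query's up genes sit low and its down
    genes sit high in the ranking (a signature-reversing profile).
    """
    ranks = rank_map if rank_map is not None else profile.rank_of()
    n_total = len(profile.ranking)
    missing = sorted(
        (set(query.up_genes) | set(query.down_genes)) - ranks.keys()
    )
    if missing:
        raise ValueError(f"query genes absent from the instance universe: {missing}")
    ks_up = ks_statistic([ranks[g] for g in query.up_genes], n_total)
    ks_down = ks_statistic([ranks[g] for g in query.down_genes], n_total)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def scale_scores(raw_scores: Iterable[float]) -> np.ndarray:
    """Scale raw scores into [-1, 1]: positives by max positive, negatives by
    the magnitude of the minimum negative.  Zeros stay zero."""
    raw = np.asarray(list(raw_scores), dtype=float)
    scaled = np.zeros_like(raw)
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = raw[neg] / abs(raw[neg].min())
    return scaled


# -- database scoring ------------------------------------------------------------


def score_db(db: Sequence[InstanceProfile], query) -> pd.DataFrame:
    """Raw and scaled connectivity scores for every instance in the database."""
    rows = []
    for prof in db:
        raw = instance_connectivity(query, prof)
        rows.append((prof.compound, prof.instance_id, raw))
    out = pd.DataFrame(rows, columns=["compound", "instance_id", "raw_s"])
    out["scaled_score"] = scale_scores(out["raw_s"])
    return out


def _ordered_positions(scores: pd.DataFrame) -> pd.DataFrame:
    """Instances ordered by scaled score descending, deterministic tie-break."""
    ordered = scores.sort_values(
        ["scaled_score", "compound", "instance_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered["position"] = np.arange(1, len(ordered) + 1)
    return ordered


def compound_enrichment(scores: pd.DataFrame, compound: str) -> float:
    """KS enrichment of one compound's instances within the scored database.

    Instances are ordered by scaled score descending; a compound whose
    instances cluster at the bottom (the reversing end) gets a negative
    enrichment.
    """
    ordered = _ordered_positions(scores)
    positions = ordered.loc[ordered["compound"] == compound, "position"]
    if positions.empty:
        raise KeyError(f"compound {compound!r} not present in the scored database")
    return ks_statistic(positions.to_list(), len(ordered))


def permutation_p(
    n: int, m_total: int, enrichment_obs: float, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value of a compound enrichment.

    ``p = (r + 1) / (n_perm + 1)`` where r counts random n-subsets of
    1..m_total whose KS statistic matches the observed sign and is at least
    as extreme in magnitude.  The +1/+1 correction avoids zero p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs_sign = np.sign(enrichment_obs)
    obs_mag = abs(enrichment_obs)
    r = 0
    for _ in range(n_perm):
        positions = rng.choice(m_total, size=n, replace=False) + 1
        ks = ks_statistic(positions, m_total)
        if np.sign(ks) == obs_sign and abs(ks) >= obs_mag:
            r += 1
    return (r + 1) / (n_perm + 1)


def percent_non_null(scaled_scores: Iterable[float], enrichment_sign: float) -> int:
    """Percent of instances with a non-zero scaled score matching the
    enrichment's sign, rounded to the nearest integer."""
    scores = np.asarray(list(scaled_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one instance")
    sign = np.sign(enrichment_sign)
    if sign == 0:
        return 0
    supporting = int(np.sum((scores != 0) & (np.sign(scores) == sign)))
    return round(100 * supporting / scores.size)


def random_query(universe: Sequence[str], n_up: int, n_down: int, rng) -> "NullQuery":
    genes = rng.choice(len(universe), size=n_up + n_down, replace=False)
    names = [universe[i] for i in genes]
    return NullQuery(frozenset(names[:n_up]), frozenset(names[n_up:]))


@dataclass(frozen=True)
class NullQuery:
    up_genes: frozenset[str]
    down_genes: frozenset[str]


def specificity(
    db: Sequence[InstanceProfile],
    compound: str,
    enrichment_obs: float,
    n_up: int,
    n_down: int,
    n_null: int = 100,
    seed: int = 0,
) -> float:
    """Uniqueness of the match: the fraction of random null queries (same
    up/down sizes over the database universe) for which the compound scores
    an enrichment of the same sign at least as extreme as observed."""
    if n_null < 1:
        raise ValueError("need at least one null query")
    universe = list(db[0].ranking)
    rng = np.random.default_rng(seed)
    obs_sign = np.sign(enrichment_obs)
    obs_mag = abs(enrichment_obs)
    hits = 0
    for _ in range(n_null):
        nq = random_query(universe, n_up, n_down, rng)
        scores = score_db(db, nq)
        e = compound_enrichment(scores, compound)
        if np.sign(e) == obs_sign and abs(e) >= obs_mag:
            hits += 1
    return hits / n_null


def summarize(
    db: Sequence[InstanceProfile],
    query,
    n_perm: int = 1000,
    n_null: int = 100,
    min_n: int = 4,
    seed: int = 0,
) -> list[CompoundSummary]:
    """Per-compound connectivity table, sorted by enrichment ascending.

    The most negative enrichment (the strongest predicted reverser) comes
    first; ties are broken alphabetically by compound name.  Compounds with
    fewer than ``min_n`` instances are flagged ``low_n``.
    """
    scores = score_db(db, query)
    m_total = len(scores)
    summaries = []
    for i, (compound, sub) in enumerate(sorted(scores.groupby("compound"))):
        enrich = compound_enrichment(scores, compound)
        n = len(sub)
        p = permutation_p(n, m_total, enrich, n_perm=n_perm, seed=seed + i)
        uniqueness = specificity(
            db, compound, enrich,
            n_up=len(query.up_genes), n_down=len(query.down_genes),
            n_null=n_null, seed=seed + 10_000 + i,
        )
        summaries.append(
            CompoundSummary(
                name=compound,
                mean=float(sub["scaled_score"].mean()),
                n=n,
                enrichment=enrich,
                p=p,
                specificity=uniqueness,
                percent_non_null=percent_non_null(sub["scaled_score"], enrich),
                low_n=n < min_n,
            )
        )
    return sorted(summaries, key=lambda s: (s.enrichment, s.name))


def summary_frame(summaries: Sequence[CompoundSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.name, s.mean, s.n, s.enrichment, s.p, s.specificity,
             s.percent_non_null, s.low_n)
            for s in summaries
        ],
        columns=["cmap_name", "mean", "n", "enrichment", "p", "specificity",
                 "percent_non_null", "low_n"],
    )


# -- simplified modern-CMap analogue ----------------------------------------------


def aggregate_profile(db: Sequence[InstanceProfile], compound: str) -> InstanceProfile:
    """Per-compound consensus ranking: genes ordered by mean rank across the
    compound's instances (ties broken by gene name for determinism)."""
    instances = [p for p in db if p.compound == compound]
    if not instances:
        raise KeyError(f"compound {compound!r} not in database")
    mean_rank: dict[str, float] = {}
    for prof in instances:
        for gene, rank in prof.rank_of().items():
            mean_rank[gene] = mean_rank.get(gene, 0.0) + rank
    genes = sorted(mean_rank, key=lambda g: (mean_rank[g], g))
    return InstanceProfile(compound=compound, instance_id="aggregate",
                           ranking=tuple(genes))


def _wtcs(query, profile: InstanceProfile) -> float:
    ranks = profile.rank_of()
    n_total = len(profile.ranking)
    es_up = ks_statistic([ranks[g] for g in query.up_genes], n_total)
    es_down = ks_statistic([ranks[g] for g in query.down_genes], n_total)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def _ncs_values(wtcs: dict[str, float]) -> dict[str, float]:
    """Normalise per-compound scores by the mean |wtcs| of same-sign compounds."""
    values = np.array(list(wtcs.values()))
    pos_mean = np.abs(values[values > 0]).mean() if (values > 0).any() else 1.0
    neg_mean = np.abs(values[values < 0]).mean() if (values < 0).any() else 1.0
    out = {}
    for name, w in wtcs.items():
        if w > 0:
            out[name] = w / pos_mean
        elif w < 0:
            out[name] = w / neg_mean
        else:
            out[name] = 0.0
    return out


def cmap2_score(
    db: Sequence[InstanceProfile],
    query,
    n_reference: int = 100,
    reference_queries: Sequence | None = None,
    seed: int = 0,
) -> list[CMap2Result]:
    """Simplified modern connectivity score on aggregated compound profiles.

    Per compound: ``wtcs = (ES_up - ES_down)/2`` when the tails disagree in
    sign else 0; ``ncs`` normalises wtcs by the mean magnitude of same-sign
    compounds; the final score is ``sign(ncs) * 100 *`` the fraction of
    reference (null) queries whose |ncs| for the same compound is strictly
    smaller.  Scores lie in [-100, 100]; sorted ascending (strongest
    predicted reverser first).
    """
    compounds = sorted({p.compound for p in db})
    aggregates = {c: aggregate_profile(db, c) for c in compounds}
    wtcs_obs = {c: _wtcs(query, aggregates[c]) for c in compounds}
    ncs_obs = _ncs_values(wtcs_obs)

    if reference_queries is None:
        rng = np.random.default_rng(seed)
        universe = list(db[0].ranking)
        reference_queries = [
            random_query(universe, len(query.up_genes), len(query.down_genes), rng)
            for _ in range(n_reference)
        ]
    if not len(reference_queries):
        raise ValueError("need at least one reference query")

    ref_ncs: dict[str, list[float]] = {c: [] for c in compounds}
    for ref in reference_queries:
        wtcs_ref = {c: _wtcs(ref, aggregates[c]) for c in compounds}
        ncs_ref = _ncs_values(wtcs_ref)
        for c in compounds:
            ref_ncs[c].append(ncs_ref[c])

    results = []
    for c in compounds:
        ncs = ncs_obs[c]
        if ncs == 0.0:
            score = 0.0
        else:
            frac = np.mean([abs(r) < abs(ncs) for r in ref_ncs[c]])
            score = float(np.sign(ncs) * 100.0 * frac)
        results.append(CMap2Result(name=c, wtcs=wtcs_obs[c], ncs=ncs, score=score))
    return sorted(results, key=lambda r: (r.score, r.name))
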