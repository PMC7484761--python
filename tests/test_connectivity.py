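"""KS connectivity scoring: statistic, instance scores, compound summaries."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import ks_running_sum
from proteoconnect import (
    CompoundDbConfig,
    InstanceProfile,
    QuerySignature,
    cmap2_score,
    compound_enrichment,
    generate_compound_db,
    instance_connectivity,
    ks_statistic,
    percent_non_null,
    permutation_p,
    scale_scores,
    score_db,
    specificity,
    summarize,
)


class TestKsStatistic:
    def test_tags_at_top(self):
        assert ks_statistic([1, 2], 10) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        assert ks_statistic([9, 10], 10) == pytest.approx(-0.9)

    def test_exhaustive_agreement_with_running_sum_oracle(self):
        for n_total in range(2, 9):
            for n in range(1, min(3, n_total) + 1):
                for tags in itertools.combinations(range(1, n_total + 1), n):
                    assert ks_statistic(tags, n_total) == pytest.approx(
                        ks_running_sum(tags, n_total)
                    ), f"tags={tags} N={n_total}"

    def test_full_list_degenerate_case_matches_oracle(self):
        n_total = 6
        tags = tuple(range(1, n_total + 1))
        assert ks_statistic(tags, n_total) == pytest.approx(
            ks_running_sum(tags, n_total)
        )

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_total = int(rng.integers(5, 200))
            n = int(rng.integers(1, n_total + 1))
            tags = rng.choice(n_total, size=n, replace=False) + 1
            v = ks_statistic(tags, n_total)
            assert -1.0 <= v <= 1.0

    def test_empty_tags_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ks_statistic([], 10)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([0, 5], 10)
        with pytest.raises(ValueError):
            ks_statistic([3, 3], 10)


def profile_of(genes, compound="c", instance="i1"):
    return InstanceProfile(compound=compound, instance_id=instance,
                           ranking=tuple(genes))


def query_of(up, down):
    return QuerySignature(up_genes=frozenset(up), down_genes=frozenset(down))


class TestInstanceConnectivity:
    UNIVERSE = [f"G{i:02d}" for i in range(20)]

    def test_matching_profile_scores_positive(self):
        prof = profile_of(self.UNIVERSE)
        q = query_of(self.UNIVERSE[:4], self.UNIVERSE[-4:])
        assert instance_connectivity(q, prof) > 0

    def test_antisymmetric_under_rank_reversal(self):
        prof = profile_of(self.UNIVERSE)
        rev = profile_of(self.UNIVERSE[::-1])
        q = query_of(self.UNIVERSE[:4], self.UNIVERSE[-4:])
        s = instance_connectivity(q, prof)
        assert instance_connectivity(q, rev) == pytest.approx(-s)

    def test_same_sign_tails_give_zero(self):
        # both tails at the top: ks_up and ks_down both positive
        prof = profile_of(self.UNIVERSE)
        q = query_of(self.UNIVERSE[:3], self.UNIVERSE[3:6])
        assert instance_connectivity(q, prof) == 0.0

    def test_range_bounded_by_two(self):
        prof = profile_of(self.UNIVERSE)
        q = query_of(self.UNIVERSE[:4], self.UNIVERSE[-4:])
        assert abs(instance_connectivity(q, prof)) <= 2.0

    def test_query_gene_outside_universe_listed(self):
        prof = profile_of(self.UNIVERSE)
        q = query_of({"MISSING"}, {self.UNIVERSE[0]})
        with pytest.raises(ValueError, match="MISSING"):
            instance_connectivity(q, prof)


class TestScaleScores:
    def test_stated_rule(self):
        np.testing.assert_allclose(scale_scores([2.0, 1.0, -1.0]), [1.0, 0.5, -1.0])

    def test_all_zero(self):
        np.testing.assert_array_equal(scale_scores([0.0, 0.0]), [0.0, 0.0])

    def test_extremes_attained(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=50)
        scaled = scale_scores(raw)
        assert scaled.max() == pytest.approx(1.0)
        assert scaled.min() == pytest.approx(-1.0)
        assert np.all(np.sign(scaled) == np.sign(raw))


def scored_frame(compound_positions, m_total, compound="drug"):
    """Scores frame where ``compound`` occupies the given descending-order
    positions; every other instance is a distinct filler compound."""
    scores = np.linspace(1.0, -1.0, m_total)
    rows = []
    for i in range(m_total):
        pos = i + 1
        if pos in compound_positions:
            rows.append((compound, f"x{pos}", scores[i], scores[i]))
        else:
            rows.append((f"filler{pos:03d}", "f1", scores[i], scores[i]))
    return pd.DataFrame(rows, columns=["compound", "instance_id", "raw_s", "scaled_score"])


class TestCompoundEnrichment:
    def test_bottom_clustered_instances_strongly_negative(self):
        scores = scored_frame({97, 98, 99, 100}, 100)
        e = compound_enrichment(scores, "drug")
        assert e == pytest.approx(ks_running_sum([97, 98, 99, 100], 100))
        assert e < -0.9

    def test_interleaved_instances_near_zero(self):
        scores = scored_frame({13, 38, 63, 88}, 100)
        e = compound_enrichment(scores, "drug")
        assert abs(e) < 0.2

    def test_single_instance_definition(self):
        scores = scored_frame({1}, 50)
        assert compound_enrichment(scores, "drug") == pytest.approx(
            ks_statistic([1], 50)
        )

    def test_unknown_compound_rejected(self):
        with pytest.raises(KeyError):
            compound_enrichment(scored_frame({1}, 10), "absent")


class TestPermutationP:
    def test_lower_bound_when_observation_beats_every_permutation(self):
        p = permutation_p(4, 100, -0.999999, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_all_positions_used_gives_p_one(self):
        obs = ks_statistic(range(1, 11), 10)
        assert permutation_p(10, 10, obs, n_perm=100, seed=2) == 1.0

    def test_seeded_reproducibility(self):
        a = permutation_p(4, 80, -0.5, n_perm=300, seed=9)
        b = permutation_p(4, 80, -0.5, n_perm=300, seed=9)
        assert a == b

    def test_null_p_values_uniform_after_sign_doubling(self):
        # The estimator counts only same-sign permutations, so it behaves as
        # a one-tailed p within the observed sign class: under a null query
        # the *doubled* p-value is approximately Uniform(0, 1).
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        m_total, n = 60, 4
        pvals = []
        for i in range(300):
            positions = rng.choice(m_total, size=n, replace=False) + 1
            obs = ks_statistic(positions, m_total)
            pvals.append(permutation_p(n, m_total, obs, n_perm=199, seed=1000 + i))
        doubled = np.minimum(2 * np.asarray(pvals), 1.0)
        stat = kstest(doubled, "uniform")
        assert stat.pvalue > 0.001


class TestPercentNonNull:
    def test_all_supporting(self):
        assert percent_non_null([-0.5, -0.8, -0.2, -0.9], -1) == 100

    def test_half_supporting(self):
        assert percent_non_null([-0.5, -0.8, 0.2, 0.9], -1) == 50

    def test_all_zero_scores(self):
        assert percent_non_null([0.0, 0.0], -1) == 0
        assert percent_non_null([0.4, -0.4], 0.0) == 0


@pytest.fixture(scope="module")
def planted_db():
    query = query_of([f"U{i:03d}" for i in range(50)], [f"D{i:03d}" for i in range(50)])
    cfg = CompoundDbConfig(n_genes=500, n_compounds=22, instances_per_compound=4,
                           reverser_noise=0.05, seed=13)
    return generate_compound_db(cfg, query), query


class TestPlantedRecovery:
    def test_reverser_instances_all_negative_raw(self, planted_db):
        db, query = planted_db
        scores = score_db(db, query)
        rev = scores[scores["compound"] == "reverser"]
        assert (rev["raw_s"] < 0).all()
        # cross-check one instance against the brute-force oracle
        prof = next(p for p in db if p.compound == "reverser")
        ranks = prof.rank_of()
        n_total = len(prof.ranking)
        ks_up = ks_running_sum([ranks[g] for g in query.up_genes], n_total)
        ks_down = ks_running_sum([ranks[g] for g in query.down_genes], n_total)
        expected = ks_up - ks_down if np.sign(ks_up) != np.sign(ks_down) else 0.0
        assert scores.loc[
            scores["instance_id"] == prof.instance_id, "raw_s"
        ].iloc[0] == pytest.approx(expected)

    def test_reverser_ranked_first_with_full_support(self, planted_db):
        db, query = planted_db
        summaries = summarize(db, query, n_perm=200, n_null=20, seed=5)
        top = summaries[0]
        assert top.name == "reverser"
        assert top.enrichment < 0
        assert top.percent_non_null == 100
        assert top.p <= 0.01
        assert top.specificity == 0.0

    def test_mimic_has_most_positive_enrichment(self, planted_db):
        db, query = planted_db
        summaries = summarize(db, query, n_perm=200, n_null=20, seed=5)
        assert summaries[-1].name == "mimic"
        assert summaries[-1].enrichment > 0

    def test_antisymmetry_under_database_reversal(self, planted_db):
        # Reversing every ranking negates raw_s exactly wherever the
        # same-sign zeroing rule does not engage; near the sign boundary the
        # discrete a-vs-b decision can flip, so zeros are exempted.
        db, query = planted_db
        reversed_db = [
            InstanceProfile(p.compound, p.instance_id, tuple(reversed(p.ranking)))
            for p in db
        ]
        s1 = score_db(db, query)["raw_s"].to_numpy()
        s2 = score_db(reversed_db, query)["raw_s"].to_numpy()
        both_nonzero = (s1 != 0) & (s2 != 0)
        assert both_nonzero.sum() >= len(s1) // 2
        np.testing.assert_allclose(s2[both_nonzero], -s1[both_nonzero], atol=1e-12)
        # every exemption really is a zero-rule case on one side
        assert np.all((s1 == 0) | (s2 == 0) | both_nonzero)

    def test_specificity_of_unrelated_compound_is_high_or_low_sign(self, planted_db):
        db, query = planted_db
        scores = score_db(db, query)
        e = compound_enrichment(scores, "decoy001")
        s = specificity(db, "decoy001", e, 50, 50, n_null=20, seed=3)
        assert 0.0 <= s <= 1.0


class TestCMap2:
    def test_planted_reverser_scores_below_minus_80(self, planted_db):
        db, query = planted_db
        results = cmap2_score(db, query, n_reference=50, seed=2)
        assert results[0].name == "reverser"
        assert results[0].score < -80

    def test_zero_wtcs_gives_zero_score(self):
        universe = [f"G{i:02d}" for i in range(30)]
        db = [profile_of(universe, "a", "a1"), profile_of(universe, "b", "b1")]
        # both tails at the top of the single profile: wtcs = 0
        q = query_of(universe[:3], universe[3:6])
        results = cmap2_score(db, q, n_reference=10, seed=0)
        assert all(r.wtcs == 0.0 and r.score == 0.0 for r in results)

    def test_scores_bounded(self, planted_db):
        db, query = planted_db
        results = cmap2_score(db, query, n_reference=30, seed=8)
        for r in results:
            assert -100.0 <= r.score <= 100.0
            assert np.sign(r.score) in (0.0, np.sign(r.ncs))


class TestSummaryDeterminism:
    def test_tie_break_alphabetical(self):
        # beta's instances land at score positions {1, 4} and zeta's at
        # {2, 3}: both position sets share the KS value -0.5, forcing an
        # exact enrichment tie resolved alphabetically.
        universe = [f"G{i:02d}" for i in range(20)]
        q = query_of(universe[:3], universe[-3:])
        mid = [g for g in universe if g not in q.up_genes | q.down_genes]
        moderate = (mid[:3] + sorted(q.up_genes) + mid[3:10]
                    + sorted(q.down_genes) + mid[10:])
        db = [
            profile_of(universe, "beta", "b1"),
            profile_of(list(reversed(universe)), "beta", "b2"),
            profile_of(moderate, "zeta", "z1"),
            profile_of(list(reversed(moderate)), "zeta", "z2"),
        ]
        summaries = summarize(db, q, n_perm=100, n_null=5, seed=1)
        assert summaries[0].enrichment == summaries[1].enrichment == -0.5
        assert [s.name for s in summaries] == ["beta", "zeta"]

    def test_low_n_flagged(self, planted_db):
        db, query = planted_db
        summaries = summarize(db, query, n_perm=100, n_null=5, min_n=5, seed=1)
        assert all(s.low_n for s in summaries)  # 4 instances < 5
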