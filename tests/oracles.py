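"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (running sums, explicit
combinatorics, textbook formulas) kept independent of the package's
implementation paths.
"""

from __future__ import annotations

import math


def ks_running_sum(tag_positions, n_total: int) -> float:
    """Brute-force two-sided KS enrichment by scanning every list position.

    Walks the ranked list once, tracking the empirical CDF of the tags
    against the uniform CDF, and maximises the positive and negative
    deviations separately.
    """
    tags = set(tag_positions)
    n = len(tags)
    assert 0 < n <= n_total
    a = -math.inf
    b = -math.inf
    hits = 0
    for i in range(1, n_total + 1):
        before = hits
        if i in tags:
            hits += 1
        a = max(a, hits / n - i / n_total)
        b = max(b, i / n_total - before / n)
    return a if a > b else -b


def welch_textbook(a, b):
    """Welch's t, Welch-Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as t_dist  # distribution function only

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def hypergeom_upper_tail(query_size: int, set_size: int, overlap: int,
                         universe_size: int) -> float:
    """Exact P(X >= overlap) by direct binomial-coefficient summation."""
    denom = math.comb(universe_size, query_size)
    total = 0
    for x in range(overlap, min(query_size, set_size) + 1):
        total += math.comb(set_size, x) * math.comb(universe_size - set_size,
                                                    query_size - x)
    return total / denom
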