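"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (definitions, exact
integer arithmetic, O(n^2) scans) and shares no code path with the package
under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def bh_stepup(pvalues):
    """Benjamini–Hochberg q-values straight from the step-up definition.

    Sort p-values ascending, scale p_(i) by n/i, then enforce monotonicity
    by taking the running minimum from the largest rank down; report in the
    original order, capped at 1.
    """
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def binom_upper_tail(mc: int, cov: int, r: float) -> float:
    """P(X >= mc) for X ~ Binomial(cov, r) by direct summation."""
    return float(
        sum(
            Fraction(math.comb(cov, k)) * Fraction(r) ** k * Fraction(1 - r) ** (cov - k)
            for k in range(mc, cov + 1)
        )
    )


def fisher_two_sided(mc_a: int, cov_a: int, mc_b: int, cov_b: int) -> tuple[float, float]:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Conditions on the margins (row totals cov_a, cov_b and column total
    s = mc_a + mc_b) and sums the probabilities of every table at most as
    likely as the observed one. Weights are exact integers
    C(cov_a, k) * C(cov_b, s - k).

    Returns a (strict, loose) pair: *strict* includes tables with weight
    <= the observed weight exactly; *loose* additionally includes weights
    within a 1e-7 relative slack, matching the tie tolerance a floating
    point implementation needs. Any correct implementation's p-value lies
    between the two.
    """
    s = mc_a + mc_b
    lo = max(0, s - cov_b)
    hi = min(s, cov_a)
    weights = {k: math.comb(cov_a, k) * math.comb(cov_b, s - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[mc_a]
    strict = sum(w for w in weights.values() if w <= w_obs)
    # integer form of w <= w_obs * (1 + 1e-7)
    loose = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return strict / total, loose / total


def chain_positions(positions, max_gap: int, min_dms: int):
    """O(n^2) interval chaining: every pair of cluster-mates is linked by a
    path of steps <= max_gap; clusters of >= min_dms positions reported as
    (first, last) 1-based spans."""
    pos = sorted(set(int(p) for p in positions))
    clusters = []
    for p in pos:
        placed = False
        for cl in clusters:
            if any(abs(p - q) <= max_gap for q in cl):
                cl.append(p)
                placed = True
                break
        if not placed:
            clusters.append([p])
    # adjacent clusters can become linkable after later insertions; merge to fixpoint
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(abs(a - b) <= max_gap for a in clusters[i] for b in clusters[j]):
                    clusters[i].extend(clusters.pop(j))
                    merged = True
                    break
            if merged:
                break
    out = []
    for cl in clusters:
        if len(cl) >= min_dms:
            out.append((min(cl), max(cl), len(cl)))
    return sorted(out)
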