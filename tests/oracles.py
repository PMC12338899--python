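"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a statistic by a route independent of the package's
implementation: exact rational arithmetic, full enumeration, or O(n^2)
search.  They are deliberately slow and simple.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_midp_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """HWE exact mid-p by full enumeration with exact rational probabilities.

    Enumerates every heterozygote count of the right parity for the
    conditional (Levene-Haldane) distribution, computing each probability
    as an exact Fraction from factorials, then applies the mid-p rule:
    outcomes strictly less probable in full, equally probable at half
    weight.
    """
    n = n_AA + n_Aa + n_aa
    n1 = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    n2 = 2 * n - n1
    if n1 == 0:
        return 1.0
    weights: dict[int, Fraction] = {}
    for h in range(n1 % 2, min(n1, n2) + 1, 2):
        a = (n1 - h) // 2
        b = (n2 - h) // 2
        weights[h] = Fraction(2**h, math.factorial(a) * math.factorial(h) * math.factorial(b))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    p = sum(q for q in probs.values() if q < p_obs)
    p += Fraction(1, 2) * sum(q for q in probs.values() if q == p_obs)
    return float(min(p, Fraction(1)))


def fisher_one_sided_enumeration(ac_t: int, an_t: int, ac_r: int, an_r: int) -> float:
    """One-sided Fisher p by exact hypergeometric enumeration (Fractions).

    Sums P(X = k) over all feasible target minor counts k >= observed,
    with X hypergeometric (total = an_t + an_r chromosomes, successes =
    ac_t + ac_r minor alleles, draws = an_t).
    """
    K = ac_t + ac_r
    N = an_t + an_r
    k_min = max(0, K - an_r)
    k_max = min(K, an_t)
    total = math.comb(N, an_t)
    p = Fraction(0)
    for k in range(max(ac_t, k_min), k_max + 1):
        p += Fraction(math.comb(K, k) * math.comb(N - K, an_t - k), total)
    return float(p)


def mendelian_impossible_set() -> set[tuple[int, int, int]]:
    """All (father, mother, child) dosage triples impossible under Mendel.

    Enumerates the 27 unphased dosage combinations and the gametes each
    parent can contribute.
    """
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    bad = set()
    for f in range(3):
        for m in range(3):
            reachable = {a + b for a in gametes[f] for b in gametes[m]}
            for c in range(3):
                if c not in reachable:
                    bad.add((f, m, c))
    return bad


def knn_brute_force(ref_coords: np.ndarray, ref_is_a: np.ndarray,
                    points: np.ndarray, k: int, threshold: int) -> np.ndarray:
    """KNN group assignment by exhaustive distance sort with (dist, idx) keys."""
    out = []
    for p in np.atleast_2d(points):
        dists = sorted(
            (float(np.sum((p - r) ** 2)), i) for i, r in enumerate(ref_coords)
        )
        votes = sum(bool(ref_is_a[i]) for _, i in dists[:k])
        out.append(votes >= threshold)
    return np.array(out)


def clopper_pearson_by_inversion(k: int, n: int, level: float = 0.95
                                 ) -> tuple[float, float]:
    """Clopper-Pearson bounds by numeric inversion of the binomial tails."""
    from scipy.optimize import brentq
    from scipy.stats import binom

    alpha = 1 - level
    lo = 0.0 if k == 0 else brentq(
        lambda q: binom.sf(k - 1, n, q) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-14)
    hi = 1.0 if k == n else brentq(
        lambda q: binom.cdf(k, n, q) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-14)
    return lo, hi
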