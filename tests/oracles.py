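"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from first principles (enumeration,
permutation, from-scratch recursion) without touching the implementation
path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration with the
    point-probability rule: sum the probabilities of every table with the
    observed margins whose probability does not exceed the observed one."""
    (a, b), (c, d) = table
    r, s = a + b, c + d          # row margins
    k = a + c                    # first column margin
    n = r + s
    lo, hi = max(0, k - s), min(r, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r, k)
    p_obs = hypergeom.pmf(a, n, r, k)
    # the epsilon guards against floating-point asymmetry between equal-
    # probability tables on opposite tails
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def ranksum_two_sided_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p for tie-free samples by enumerating all
    C(n+m, n) assignments of ranks to the first sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1
    w_obs = ranks[:n].sum()
    total = 0
    n_le = n_ge = 0
    for comb in combinations(range(n + m), n):
        w = sum(c + 1 for c in comb)
        total += 1
        n_le += w <= w_obs
        n_ge += w >= w_obs
    return min(1.0, 2 * min(n_le / total, n_ge / total))


def ward_heights_bruteforce(X: np.ndarray) -> list[float]:
    """Ward merge heights recomputed from scratch at every step.

    At each step every cluster pair's merge cost is evaluated as the increase
    in total within-cluster sum of squares,
    ΔSSE(A,B) = |A||B|/(|A|+|B|) · ||mean(A) − mean(B)||², and the height is
    reported on the distance scale, sqrt(2·ΔSSE) (so two singletons merge at
    their Euclidean distance).  The minimum-cost pair merges.
    """
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            A = X[clusters[i]]
            B = X[clusters[j]]
            d2 = np.sum((A.mean(axis=0) - B.mean(axis=0)) ** 2)
            cost = len(A) * len(B) / (len(A) + len(B)) * d2
            if best is None or cost < best[0]:
                best = (cost, i, j)
        cost, i, j = best
        heights.append(float(np.sqrt(2 * cost)))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def trend_permutation_p(n_per_bin, r_per_bin, scores, n_perm: int = 100_000,
                        seed: int = 0) -> float:
    """One-sided (increasing) permutation p-value for the binomial trend
    statistic T = Σ s_i (r_i − n_i R/N): the R successes are reassigned
    uniformly over the N subjects and T recomputed."""
    n = np.asarray(n_per_bin, dtype=int)
    r = np.asarray(r_per_bin, dtype=int)
    s = np.asarray(scores, dtype=float)
    N, R = int(n.sum()), int(r.sum())
    bin_of = np.repeat(np.arange(len(n)), n)
    t_obs = float(np.sum(s * (r - n * R / N)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        chosen = rng.choice(N, size=R, replace=False)
        r_perm = np.bincount(bin_of[chosen], minlength=len(n))
        t = np.sum(s * (r_perm - n * R / N))
        hits += t >= t_obs - 1e-12
    return hits / n_perm
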