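"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, naive scans, combinatorics) without touching the package's
dynamic programs, so that agreement is informative.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
            ("G", "U"), ("U", "G")}
PAIR_NAMES = "CG GC GU UG AU UA".split()


def enumerate_structures(seq: str, min_loop: int = 3):
    """All nested structures (as frozensets of 0-based pairs)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i > j:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in WC_PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(left | right | {(i, k)})
        return out

    return rec(0, len(seq) - 1)


def loop_energy(seq: str, pairs, model) -> float:
    """Score a structure by explicit loop decomposition (independent of the
    package's DP): each pair closes a hairpin, a stack/bulge/internal loop,
    or a multiloop with linear branch/unpaired costs; exterior is free."""
    if not pairs:
        return 0.0
    plist = sorted(pairs)
    partner = {}
    for i, j in plist:
        partner[i], partner[j] = j, i
    hp, bu, it = model.tables(len(seq))
    total = 0.0
    for i, j in plist:
        enclosed = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                enclosed.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not enclosed:
            total += hp[j - i - 1]
        elif len(enclosed) == 1:
            (a, b), = enclosed
            l1, l2 = a - i - 1, j - b - 1
            if l1 + l2 == 0:
                total += model.stack[PAIR_NAMES.index(seq[i] + seq[j]),
                                     PAIR_NAMES.index(seq[a] + seq[b])]
            elif l1 == 0 or l2 == 0:
                total += bu[l1 + l2]
            else:
                total += it[l1 + l2]
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in enclosed)
            total += (model.ml_init + model.ml_branch * (len(enclosed) + 1)
                      + model.ml_unpaired * unpaired)
    return total


def boltzmann_ensemble(seq: str, model):
    """(Z, pair-probability matrix, unpaired probs) by full enumeration."""
    structs = enumerate_structures(seq, model.min_loop)
    weights = [math.exp(-loop_energy(seq, s, model) / model.kT)
               for s in structs]
    Z = sum(weights)
    n = len(seq)
    p = np.zeros((n, n))
    for s, w in zip(structs, weights):
        for i, j in s:
            p[i, j] += w
    p /= Z
    q = 1.0 - (p + p.T).sum(axis=1)
    return Z, p, q


def best_mea_score(seq: str, p: np.ndarray, q: np.ndarray,
                   gamma: float = 1.0, min_loop: int = 3) -> float:
    best = -1.0
    for s in enumerate_structures(seq, min_loop):
        paired = {x for ij in s for x in ij}
        sc = sum(2 * gamma * p[i, j] for i, j in s) \
            + sum(q[i] for i in range(len(seq)) if i not in paired)
        best = max(best, sc)
    return best


def naive_site_scan(utr: str, seed_rc: str) -> list[int]:
    """All (overlapping) occurrences of a motif by explicit sliding window."""
    return [i for i in range(len(utr) - len(seed_rc) + 1)
            if utr[i:i + len(seed_rc)] == seed_rc]


def hypergeom_tail_exact(k: int, K: int, n: int, N: int):
    """P(X >= k) from binomial coefficients (exact rational arithmetic)."""
    from fractions import Fraction
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)
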