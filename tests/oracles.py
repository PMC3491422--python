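"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or textbook
dynamic programming, sharing no code with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Seq import Seq

NEG = float("-inf")


def affine_dp_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Three-state affine-gap global alignment score with free end gaps.

    Gap of length L costs gap_open + (L-1)*gap_extend internally; leading
    and trailing gaps are free.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in aligned pair
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends consuming a (gap in b)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends consuming b (gap in a)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0        # free leading gap in b
    for j in range(1, m + 1):
        Y[0][j] = 0.0        # free leading gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)
    best = NEG
    for i in range(n + 1):   # free trailing gap consuming the rest of a
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):   # free trailing gap consuming the rest of b
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


# ---------------------------------------------------------------------------
# Nei-Gojobori single-codon oracle (direct enumeration via Bio.Seq.translate)

def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon by enumerating all 9 mutations."""
    total = 0.0
    for pos in range(3):
        syn = possible = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _aa(alt) == "*":
                continue
            possible += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if possible:
            total += syn / possible
    return total


def oracle_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating all orderings of single-nucleotide steps."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    kept, blocked = [], []
    for order in permutations(diff):
        cur, syn, non, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            if _aa(nxt) == "*":
                stop = True
            cur = nxt
        (blocked if stop else kept).append((syn, non))
    use = kept or blocked
    return (sum(u[0] for u in use) / len(use), sum(u[1] for u in use) / len(use))


def oracle_ng86(cds1: str, cds2: str) -> dict:
    """Full NG86 estimate for two equal-length, gap-free, sense CDS."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        ca, cb = cds1[i:i + 3], cds2[i:i + 3]
        s = 0.5 * (oracle_codon_sites(ca) + oracle_codon_sites(cb))
        S += s
        N += 3 - s
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p: float):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd,
            "dS": jc(Sd / S), "dN": jc(Nd / N)}


# ---------------------------------------------------------------------------
# shared-motif oracle: all maximal substring matches by direct comparison

def oracle_motifs(a: str, b: str, l: int) -> list[tuple[int, int, int]]:
    """All maximal (start_a, start_b, length >= l) exact matches; N never matches."""

    def eq(x: str, y: str) -> bool:
        return x == y and x != "N"

    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            if i > 0 and j > 0 and eq(a[i - 1], b[j - 1]):
                continue        # not left-maximal
            k = 0
            while i + k < len(a) and j + k < len(b) and eq(a[i + k], b[j + k]):
                k += 1
            if k >= l:
                out.append((i, j, k))
    return sorted(out)


def oracle_dsm(a: str, b: str, l: int) -> float:
    """dSM via explicit position sets."""
    cov_a, cov_b = set(), set()
    for i, j, k in oracle_motifs(a, b, l):
        cov_a.update(range(i, i + k))
        cov_b.update(range(j, j + k))
    return 1.0 - (len(cov_a) + len(cov_b)) / (len(a) + len(b))


# ---------------------------------------------------------------------------
# KS statistic by exhaustive ECDF scan

def oracle_ks_d(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)


def oracle_yates_prop_chi2(x1: int, n1: int, x2: int, n2: int) -> float:
    """Closed-form Yates-corrected pooled two-proportion chi-square."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n = n1 + n2
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def oracle_hypergeom_upper(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for hypergeometric(M population, K successes, n draws)."""
    from math import comb

    total = comb(M, n)
    return sum(comb(K, x) * comb(M - K, n - x)
               for x in range(k, min(K, n) + 1)) / total
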