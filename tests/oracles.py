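"""Independent brute-force oracles used by the tests.

These deliberately avoid scipy: exact rational arithmetic over explicit
enumeration of tables, so they can referee the production statistics.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_fisher_two_sided(a: int, b: int, n1: int, n2: int) -> Fraction:
    """Two-sided Fisher's exact p for the table [[a, n1-a], [b, n2-b]] by
    enumerating every table with the same margins and summing those no more
    probable than the observed one."""
    k = a + b
    obs = comb(n1, a) * comb(n2, b)
    total = 0
    for i in range(max(0, k - n2), min(n1, k) + 1):
        w = comb(n1, i) * comb(n2, k - i)
        if w <= obs:
            total += w
    return Fraction(total, comb(n1 + n2, k))


def exact_hypergeom_tail(k: int, big_k: int, n: int, big_n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact summation."""
    total = sum(
        comb(big_k, i) * comb(big_n - big_k, n - i)
        for i in range(k, min(big_k, n) + 1)
    )
    return Fraction(total, comb(big_n, n))


def naive_cpg_counts(seq: str) -> tuple[int, int, int, int]:
    """(n_cpg, n_c, n_g, effective_length) by character-by-character scan;
    N breaks dinucleotides and is excluded from all counts."""
    s = seq.upper()
    n_c = sum(1 for ch in s if ch == "C")
    n_g = sum(1 for ch in s if ch == "G")
    n_cpg = sum(1 for x, y in zip(s, s[1:]) if x == "C" and y == "G")
    length = sum(1 for ch in s if ch != "N")
    return n_cpg, n_c, n_g, length
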