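"""Brute-force enumeration oracles shared by the test modules."""

from collections import Counter
from itertools import combinations_with_replacement
from math import factorial


def discrete_spacing_tail(i: int, j: int, m: int, N: int, gap: int) -> float:
    """P(X_(j) - X_(i) <= gap) for order statistics of m iid discrete
    uniform draws on {1..N}, by complete enumeration of position multisets
    weighted by their number of orderings."""
    total = 0
    for multiset in combinations_with_replacement(range(1, N + 1), m):
        if multiset[j - 1] - multiset[i - 1] <= gap:
            weight = factorial(m)
            for rep in Counter(multiset).values():
                weight //= factorial(rep)
            total += weight
    return total / N**m
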