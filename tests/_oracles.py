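"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the hypergeometric tail
is obtained by exhaustively enumerating subsets, and the step-up FDR
adjustment is a naive quadratic re-implementation straight from its
definition.
"""

from bisect import bisect_left
from fractions import Fraction
from itertools import combinations


def tail_by_enumeration(x: int, k: int, m: int, N: int) -> Fraction:
    """P(X >= x) as the exact fraction of k-subsets of an N-universe (whose
    first m elements are 'marked') containing at least x marked elements."""
    hits = total = 0
    for sub in combinations(range(N), k):
        total += 1
        if sum(1 for e in sub if e < m) >= x:
            hits += 1
    return Fraction(hits, total)


def overlap_tail_tables(N: int, k: int) -> dict[int, list[int]]:
    """For every m in 0..N, the histogram over k-subsets of the overlap with
    the first m universe elements.  One subset enumeration serves all m."""
    hists: dict[int, list[int]] = {m: [0] * (k + 1) for m in range(N + 1)}
    for sub in combinations(range(N), k):
        for m in range(N + 1):
            hists[m][bisect_left(sub, m)] += 1
    return hists


def bh_step_up(p_values) -> list[float]:
    """Benjamini–Hochberg step-up, written naively from the definition:
    q_(i) = min_{j >= i} p_(j) * M / j, capped at 1, in input order."""
    M = len(p_values)
    order = sorted(range(M), key=lambda i: (p_values[i], i))
    out = [0.0] * M
    for pos, i in enumerate(order, start=1):
        candidates = [
            p_values[order[r - 1]] * M / r for r in range(pos, M + 1)
        ]
        out[i] = min(1.0, min(candidates))
    return out
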