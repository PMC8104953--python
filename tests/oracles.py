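"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive re-derivations of each operation's definition
(top-down recursion, literal set counting, literal reciprocal checks) and
share no code with the package's own computational paths.
"""

from __future__ import annotations

import math
from functools import lru_cache


def sw_local_score(a: str, b: str, scheme) -> float:
    """Optimal Smith-Waterman local score by memoized top-down recursion.

    Affine gaps in the BLAST convention: a gap of length L costs
    ``gap_open + L * gap_extend`` (both negative).  Returns 0.0 when no
    alignment scores above zero.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = scheme.substitution
    NEG = -math.inf

    @lru_cache(maxsize=None)
    def m(i: int, j: int) -> float:
        # best alignment ending with column (a[i-1] : b[j-1])
        if i == 0 or j == 0:
            return NEG
        prev = max(0.0, m(i - 1, j - 1), x(i - 1, j - 1), y(i - 1, j - 1))
        return sub(a[i - 1], b[j - 1]) + prev

    @lru_cache(maxsize=None)
    def x(i: int, j: int) -> float:
        # best alignment ending with a[i-1] against a gap
        if i == 0:
            return NEG
        opens = max(0.0, m(i - 1, j), y(i - 1, j) if j else NEG)
        extend = x(i - 1, j) + ge if i > 1 else NEG
        return max(opens + go + ge, extend)

    @lru_cache(maxsize=None)
    def y(i: int, j: int) -> float:
        # best alignment ending with b[j-1] against a gap
        if j == 0:
            return NEG
        opens = max(0.0, m(i, j - 1), x(i, j - 1) if i else NEG)
        extend = y(i, j - 1) + ge if j > 1 else NEG
        return max(opens + go + ge, extend)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, m(i, j), x(i, j), y(i, j))
    return best


def merge_oracle(call_sets: dict[str, set[tuple]]) -> dict[str, set[tuple]]:
    """Literal k-of-n membership counting over caller key sets."""
    n = len(call_sets)
    counts: dict[tuple, int] = {}
    for keys in call_sets.values():
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    return {
        "superset": set(counts),
        "consensus": {k for k, c in counts.items() if c >= 2},
        "common": {k for k, c in counts.items() if c == n},
    }


def rbh_oracle(
    a_genes: list[str],
    b_genes: list[str],
    hits_ab: list,
    hits_ba: list,
) -> dict[str, tuple[str, str | None]]:
    """Literal reciprocal-best-hit classification of A-genes against B.

    Returns gene -> (status, partner).  Best hits are chosen by exhaustive
    sort over (score desc, e-value asc, length desc, subject id asc).
    """

    def best(hits, query):
        mine = [h for h in hits if h.query_id == query]
        if not mine:
            return None
        mine.sort(
            key=lambda h: (
                -h.score,
                h.evalue if h.evalue is not None else math.inf,
                -h.aln_length,
                h.subject_id,
            )
        )
        return mine[0]

    out = {}
    for gene in a_genes:
        top = best(hits_ab, gene)
        if top is None:
            out[gene] = ("loner", None)
            continue
        reciprocal = best(hits_ba, top.subject_id)
        if reciprocal is not None and reciprocal.subject_id == gene:
            out[gene] = ("mutual", top.subject_id)
        else:
            out[gene] = ("singular", top.subject_id)
    return out
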