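"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic programs: structures are
enumerated exhaustively and scored/aligned with straight-line code, so they
can vouch for the DP implementations on small inputs.
"""

from functools import lru_cache

PAIR_W = {"GC": 3, "CG": 3, "AU": 2, "UA": 2, "GU": 1, "UG": 1}
MIN_LOOP = 3


def enumerate_structures(seq: str):
    """Yield every valid nested pair set (1-based) for ``seq``."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        # pair sets over seq[i..j], 0-based inclusive
        if j - i < MIN_LOOP + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if seq[i] + seq[k] not in PAIR_W:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append(inner | outer | {(i + 1, k + 1)})
        return out

    yield from rec(0, len(seq) - 1)


def score_structure(seq: str, pairs) -> int:
    """Pair weights plus +1 per stacked pair (independent re-implementation)."""
    score = 0
    pairset = set(pairs)
    for i, j in pairs:
        score += PAIR_W[seq[i - 1] + seq[j - 1]]
        if (i + 1, j - 1) in pairset:
            score += 1
    return score


def best_structures(seq: str):
    """(max score, list of optimal pair sets) by exhaustive enumeration."""
    best = -1
    optima = []
    for pairs in enumerate_structures(seq):
        s = score_structure(seq, pairs)
        if s > best:
            best, optima = s, [pairs]
        elif s == best:
            optima.append(pairs)
    return best, optima


# ---------------------------------------------------------------------------
# Alignment enumeration with affine gaps


def enumerate_alignments(a: str, b: str):
    """All global alignments of a and b as (row_a, row_b) strings."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            yield "", ""
            return
        if i < len(a):
            for ra, rb in rec(i + 1, j):
                yield a[i] + ra, "-" + rb
        if j < len(b):
            for ra, rb in rec(i, j + 1):
                yield "-" + ra, b[j] + rb
        if i < len(a) and j < len(b):
            for ra, rb in rec(i + 1, j + 1):
                yield a[i] + ra, b[j] + rb

    yield from rec(0, 0)


def score_alignment(ra: str, rb: str, match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0) -> float:
    """Affine-gap score: a gap run of length k costs open + k*extend."""
    score = 0.0
    gap_a = gap_b = False
    for x, y in zip(ra, rb):
        if x == "-":
            score += gap_extend + (0 if gap_a else gap_open)
            gap_a, gap_b = True, False
        elif y == "-":
            score += gap_extend + (0 if gap_b else gap_open)
            gap_a, gap_b = False, True
        else:
            score += match if x == y else mismatch
            gap_a = gap_b = False
    return score


def best_alignment_score(a: str, b: str) -> float:
    return max(score_alignment(ra, rb) for ra, rb in enumerate_alignments(a, b))
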