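"""Secondary-structure prediction and four-helix domain annotation for ITS2.

The folder is a Nussinov-style dynamic program over nested structures with
weighted base pairs (GC/CG = 3, AU/UA = 2, GU/UG wobble = 1), a +1 bonus for
each stacked pair, and a minimum hairpin loop of 3 unpaired bases.  It is a
deliberately simple, fully deterministic stand-in for a thermodynamic folder:
for published-quality ITS2 models the recommended route is to import an
externally computed structure in Vienna dot-bracket format and use this
module only for domain annotation.  Ties between equal-score structures are
broken toward the lexicographically smallest pair list, so identical input
yields an identical structure on every platform.

Annotation follows the canonical eukaryote ITS2 model: the four largest
top-level stems are labelled helices I-IV in 5'->3' order, each helix owning
its whole hairpin arm (basal pair through apical loop); the single-stranded
regions are the top-level unpaired intervals between and around the helices,
of which the canonical model has five.  Coordinates are 1-based throughout.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConstraintError, Its2Error, ValidationError
from .seqio import NucSequence, check_dotbracket

PAIR_WEIGHTS: dict[tuple[str, str], int] = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
CANONICAL_PAIRS = frozenset(PAIR_WEIGHTS)
MIN_LOOP = 3  # unpaired bases enclosed by any pair
STACK_BONUS = 1
_NEG = -(2**30)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure in dot-bracket form."""

    structure: str
    pairs: tuple[tuple[int, int], ...]  # 1-based, i < j, sorted by i

    @classmethod
    def from_dotbracket(cls, structure: str) -> "SecondaryStructure":
        pairs = check_dotbracket(structure)
        for i, j in pairs:
            if j - i < MIN_LOOP + 1:
                raise ValidationError(f"pair ({i},{j}) violates the minimum hairpin loop of {MIN_LOOP}")
        return cls(structure, tuple(pairs))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], length: int) -> "SecondaryStructure":
        chars = ["."] * length
        for i, j in pairs:
            if not (1 <= i < j <= length):
                raise ValidationError(f"pair ({i},{j}) out of range 1..{length}")
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return cls.from_dotbracket("".join(chars))

    def __len__(self) -> int:
        return len(self.structure)

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


@dataclass(frozen=True)
class StructuredSequence:
    """A sequence attached to a structure; every pair must be AU/UA/GC/CG/GU/UG."""

    seq: NucSequence
    ss: SecondaryStructure

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.ss):
            raise ValidationError(f"{self.seq.id}: sequence length {len(self.seq)} != structure length {len(self.ss)}")
        for i, j in self.ss.pairs:
            duo = (self.seq.residues[i - 1], self.seq.residues[j - 1])
            if duo not in CANONICAL_PAIRS:
                raise ValidationError(f"{self.seq.id}: illegal base pair {duo[0]}-{duo[1]} at ({i},{j})")

    def pair_bases(self, pair: tuple[int, int]) -> tuple[str, str]:
        i, j = pair
        return self.seq.residues[i - 1], self.seq.residues[j - 1]


def pair_weight(a: str, b: str) -> int | None:
    return PAIR_WEIGHTS.get((a, b))


def structure_score(ssq: StructuredSequence) -> int:
    """Score of a structure under the folder's scheme (pairs + stacking)."""
    score = 0
    pairset = set(ssq.ss.pairs)
    for i, j in ssq.ss.pairs:
        score += PAIR_WEIGHTS[ssq.pair_bases((i, j))]
        if (i + 1, j - 1) in pairset:
            score += STACK_BONUS
    return score


def _validate_constraints(
    seq: str,
    forced: Sequence[tuple[int, int]],
    forbidden: Sequence[tuple[int, int]],
) -> tuple[dict[int, int], set[tuple[int, int]]]:
    n = len(seq)
    partner: dict[int, int] = {}
    norm_forced = []
    for i, j in forced:
        i, j = (i, j) if i < j else (j, i)
        if not (1 <= i < j <= n):
            raise ConstraintError(f"forced pair ({i},{j}) out of range 1..{n}")
        if j - i < MIN_LOOP + 1:
            raise ConstraintError(f"forced pair ({i},{j}) violates the minimum hairpin loop")
        if pair_weight(seq[i - 1], seq[j - 1]) is None:
            raise ConstraintError(f"forced pair ({i},{j}) joins non-pairing bases {seq[i-1]}-{seq[j-1]}")
        for p in (i, j):
            if p in partner:
                raise ConstraintError(f"position {p} appears in more than one forced pair")
        partner[i] = j
        partner[j] = i
        norm_forced.append((i, j))
    for (a, b) in norm_forced:
        for (c, d) in norm_forced:
            if a < c < b < d:
                raise ConstraintError(f"forced pairs ({a},{b}) and ({c},{d}) cross (pseudoknot)")
    forb = set()
    for i, j in forbidden:
        i, j = (i, j) if i < j else (j, i)
        if (i, j) in set(norm_forced):
            raise ConstraintError(f"pair ({i},{j}) is both forced and forbidden")
        forb.add((i, j))
    return partner, forb


def fold(
    seq: NucSequence,
    forced: Sequence[tuple[int, int]] = (),
    forbidden: Sequence[tuple[int, int]] = (),
) -> StructuredSequence:
    """Maximum-score nested structure of ``seq`` under the weighted scheme.

    ``forced`` pairs must appear in the result; ``forbidden`` pairs may not.
    Among equal-score optima the structure with the lexicographically
    smallest sorted pair list is returned (fixed tie-breaking).
    """
    s = seq.residues
    n = len(s)
    if n == 0:
        raise ValidationError(f"{seq.id}: empty sequence cannot be folded")
    partner, forb = _validate_constraints(s, forced, forbidden)
    is_forced = np.zeros(n + 2, dtype=bool)
    for p in partner:
        is_forced[p] = True

    def allowed(i: int, j: int) -> int | None:  # 1-based; returns weight or None
        if j - i < MIN_LOOP + 1 or (i, j) in forb:
            return None
        if is_forced[i] and partner[i] != j:
            return None
        if is_forced[j] and partner[j] != i:
            return None
        return pair_weight(s[i - 1], s[j - 1])

    # DP tables, 1-based indexing; W[i][j] = best score on [i..j];
    # P[i][j] = best score on [i..j] given (i,j) paired.
    W = np.full((n + 2, n + 2), _NEG, dtype=np.int64)
    P = np.full((n + 2, n + 2), _NEG, dtype=np.int64)
    # base: short or empty windows hold no pair; infeasible if a forced
    # position would be stranded unpaired inside.
    for i in range(1, n + 2):
        for j in range(i - 1, min(i + MIN_LOOP + 1, n + 1)):
            if j < i:
                W[i][j] = 0
            elif not is_forced[i : j + 1].any():
                W[i][j] = 0
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            w = allowed(i, j)
            if w is not None:
                inner = max(W[i + 1][j - 1], P[i + 1][j - 1] + STACK_BONUS)
                if inner > _NEG // 2:
                    P[i][j] = w + inner
            best = W[i][j - 1] if not is_forced[j] else _NEG
            for k in range(i, j - MIN_LOOP):
                if P[k][j] <= _NEG // 2:
                    continue
                left = W[i][k - 1] if k > i else 0
                if left <= _NEG // 2:
                    continue
                cand = left + P[k][j]
                if cand > best:
                    best = cand
            W[i][j] = best
    if W[1][n] <= _NEG // 2:
        raise ConstraintError("constraints admit no valid structure")

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * n + 100))
    memo_w: dict[tuple[int, int], list[tuple[int, int]]] = {}
    memo_p: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def trace_w(i: int, j: int) -> list[tuple[int, int]]:
        if j < i or W[i][j] == 0:
            return []
        key = (i, j)
        if key in memo_w:
            return memo_w[key]
        target = W[i][j]
        result = None
        for a in range(i, j - MIN_LOOP):
            if a > i and is_forced[a - 1]:
                break  # a forced position cannot be skipped as unpaired
            for b in range(a + MIN_LOOP + 1, j + 1):
                if P[a][b] <= _NEG // 2:
                    continue
                right = W[b + 1][j] if b < j else 0
                if right <= _NEG // 2:
                    continue
                if P[a][b] + right == target:
                    result = trace_p(a, b) + trace_w(b + 1, j)
                    break
            if result is not None:
                break
        assert result is not None, "traceback failed to reproduce the DP score"
        memo_w[key] = result
        return result

    def trace_p(i: int, j: int) -> list[tuple[int, int]]:
        key = (i, j)
        if key in memo_p:
            return memo_p[key]
        w = allowed(i, j)
        assert w is not None
        target = P[i][j] - w
        cands = []
        if P[i + 1][j - 1] > _NEG // 2 and P[i + 1][j - 1] + STACK_BONUS == target:
            cands.append(trace_p(i + 1, j - 1))
        if W[i + 1][j - 1] > _NEG // 2 and W[i + 1][j - 1] == target:
            cands.append(trace_w(i + 1, j - 1))
        assert cands, "traceback failed inside a paired region"
        result = [(i, j)] + min(cands)
        memo_p[key] = result
        return result

    pairs = sorted(trace_w(1, n))
    ss = SecondaryStructure.from_pairs(pairs, n)
    return StructuredSequence(seq, ss)


def fold_score(seq: NucSequence, forced: Sequence[tuple[int, int]] = (), forbidden: Sequence[tuple[int, int]] = ()) -> int:
    """Score of the optimal structure (convenience wrapper)."""
    return structure_score(fold(seq, forced, forbidden))


# ---------------------------------------------------------------------------
# Domain annotation


@dataclass(frozen=True)
class Helix:
    label: str  # "I".."IV", or "" for an unlabelled minor stem
    pairs: tuple[tuple[int, int], ...]  # basal -> apical chain
    span: tuple[int, int]  # (basal 5' position, basal 3' position)


@dataclass(frozen=True)
class DomainModel:
    """Helix I-IV layout of a structured sequence.

    ``ss_regions`` are the maximal top-level unpaired intervals (the central
    ring plus 5'/3' tails); positions inside a helix span — including its
    hairpin loop and tolerated internal loops — belong to that helix, so the
    union of helix spans and ss_regions tiles 1..length exactly once.
    """

    length: int
    helices: tuple[Helix, ...]
    ss_regions: tuple[tuple[int, int], ...]
    canonical: bool

    def helix(self, label: str) -> Helix:
        for h in self.helices:
            if h.label == label:
                return h
        raise KeyError(label)


def annotate_domains(ssq: StructuredSequence | SecondaryStructure, merge_tolerance: int = 3) -> DomainModel:
    """Group stems into helices and label the four largest I-IV in 5' order.

    Stems separated by internal loops or bulges of at most ``merge_tolerance``
    unpaired bases on either strand are merged into one helix chain.  Models
    without exactly four top-level helices and five single-stranded regions
    are returned flagged non-canonical rather than rejected.
    """
    ss = ssq.ss if isinstance(ssq, StructuredSequence) else ssq
    L = len(ss)
    pairs = list(ss.pairs)
    # parent/children relations from the bracket nesting
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    close_at = {j: (i, j) for i, j in pairs}
    open_at = {i: (i, j) for i, j in pairs}
    for pos in range(1, L + 1):
        if pos in open_at:
            p = open_at[pos]
            par = stack[-1] if stack else None
            parent[p] = par
            children.setdefault(par, []).append(p)
            children.setdefault(p, [])
            stack.append(p)
        elif pos in close_at:
            stack.pop()

    helices: list[Helix] = []
    for basal in children[None]:
        chain = [basal]
        cur = basal
        while True:
            kids = children.get(cur, [])
            if len(kids) != 1:
                break
            (q,) = kids
            if q[0] - cur[0] - 1 <= merge_tolerance and cur[1] - q[1] - 1 <= merge_tolerance:
                chain.append(q)
                cur = q
            else:
                break
        helices.append(Helix("", tuple(chain), (basal[0], basal[1])))

    # label the four largest top-level stems I..IV in 5' order
    order = sorted(range(len(helices)), key=lambda k: (-len(helices[k].pairs), helices[k].span[0]))
    chosen = sorted(order[:4])
    roman = ["I", "II", "III", "IV"]
    labelled: list[Helix] = []
    for rank, idx in enumerate(chosen):
        h = helices[idx]
        labelled.append(Helix(roman[rank], h.pairs, h.span))

    covered = np.zeros(L + 1, dtype=bool)
    for h in labelled:
        covered[h.span[0] : h.span[1] + 1] = True
    ss_regions: list[tuple[int, int]] = []
    pos = 1
    while pos <= L:
        if not covered[pos]:
            start = pos
            while pos <= L and not covered[pos]:
                pos += 1
            ss_regions.append((start, pos - 1))
        else:
            pos += 1

    canonical = len(helices) == 4 and len(labelled) == 4 and len(ss_regions) == 5
    return DomainModel(L, tuple(labelled), tuple(ss_regions), canonical)


def fraction_paired(ssq: StructuredSequence) -> float:
    """Proportion of nucleotides engaged in base pairs: 2|pairs|/L."""
    return 2 * len(ssq.ss.pairs) / len(ssq.ss)


def helix_local_coordinates(dm: DomainModel, pair: tuple[int, int]) -> tuple[str, int]:
    """Helix label and 1-based offset from the basal pair for ``pair``."""
    i, j = (pair[0], pair[1]) if pair[0] < pair[1] else (pair[1], pair[0])
    for h in dm.helices:
        for off, p in enumerate(h.pairs, start=1):
            if p == (i, j):
                return h.label, off
    raise Its2Error(f"pair ({i},{j}) does not belong to any helix")


def domain_table(dm: DomainModel, ssq: StructuredSequence):
    """Per-position annotation as a DataFrame: position, partner, helix, basal offset."""
    import pandas as pd

    partner = ssq.ss.partner_map()
    helix_of: dict[int, tuple[str, int]] = {}
    for h in dm.helices:
        for off, (i, j) in enumerate(h.pairs, start=1):
            helix_of[i] = (h.label, off)
            helix_of[j] = (h.label, off)
    span_of: dict[int, str] = {}
    for h in dm.helices:
        for p in range(h.span[0], h.span[1] + 1):
            span_of[p] = h.label
    rows = []
    for pos in range(1, dm.length + 1):
        lab, off = helix_of.get(pos, (span_of.get(pos, ""), 0))
        rows.append(
            {
                "position": pos,
                "base": ssq.seq.residues[pos - 1],
                "partner": partner.get(pos, 0),
                "helix": lab,
                "basal_offset": off,
            }
        )
    return pd.DataFrame(rows)


def annotated_dotbracket(dm: DomainModel, ss: SecondaryStructure) -> str:
    """Two-line rendering: dot-bracket over a helix-label track (I/V/X chars)."""
    letter = {"I": "1", "II": "2", "III": "3", "IV": "4"}
    track = ["-"] * dm.length
    for h in dm.helices:
        for p in range(h.span[0], h.span[1] + 1):
            track[p - 1] = letter.get(h.label, "?")
    return ss.structure + "\n" + "".join(track)
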