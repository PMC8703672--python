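"""Pairwise alignment and uncorrected distance estimation.

The distance stage mirrors the classic MEGA workflow: p-distance (proportion
of differing sites) with pairwise deletion of gap/ambiguous columns, and a
standard error that is either the analytic binomial form sqrt(p(1-p)/n) or a
seeded column bootstrap.  Between-species distances are group means over all
cross-species strain pairs, with the SE computed on the concatenated
comparison.

The global aligner is a Gotoh affine-gap Needleman-Wunsch (match +1,
mismatch -1, gap open -4, gap extend -1; a gap of length k costs
open + k*extend) with deterministic tie-breaking.  It exists so that
pipelines without a pre-made alignment remain runnable; curated alignments
can always be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .errors import UndefinedDistanceError, ValidationError
from .seqio import Alignment, NucSequence

GAP = "-"
AMBIGUOUS = "N"


@dataclass(frozen=True)
class AlignScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with standard errors and site counts."""

    taxa: list[str]
    d: np.ndarray
    se: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.taxa)
        for name in ("d", "se", "n_sites"):
            arr = getattr(self, name)
            if arr.shape != (k, k):
                raise ValidationError(f"{name} matrix shape {arr.shape} does not match {k} taxa")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not (np.allclose(self.d, self.d.T) and np.allclose(self.se, self.se.T)):
            raise ValidationError("distance and SE matrices must be symmetric")

    def entry(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j]), float(self.se[i, j])


# ---------------------------------------------------------------------------
# Global alignment (Gotoh)


def global_align(a: NucSequence, b: NucSequence, scores: AlignScores = AlignScores()) -> Alignment:
    """Optimal global alignment of two sequences under affine gap costs.

    Ties are broken with a fixed state preference (substitution, then gap in
    the second sequence, then gap in the first), which pushes gaps 5'-ward
    and keeps the result deterministic.
    """
    if not a.residues or not b.residues:
        raise ValidationError("global_align requires non-empty sequences")
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    NEG = -math.inf
    # M: sa[i] aligned to sb[j]; X: gap in b (sa[i] over '-'); Y: gap in a
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = scores.gap_open + scores.gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = scores.gap_open + scores.gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = scores.match if sa[i - 1] == sb[j - 1] else scores.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + scores.gap_open + scores.gap_extend, X[i - 1, j] + scores.gap_extend)
            Y[i, j] = max(M[i, j - 1] + scores.gap_open + scores.gap_extend, Y[i, j - 1] + scores.gap_extend)
    # traceback from the best final state, preferring M, then X, then Y
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    rows_a: list[str] = []
    rows_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            sub = scores.match if sa[i - 1] == sb[j - 1] else scores.mismatch
            rows_a.append(sa[i - 1])
            rows_b.append(sb[j - 1])
            here = M[i, j]
            i, j = i - 1, j - 1
            for s, tab in (("M", M), ("X", X), ("Y", Y)):
                if tab[i, j] + sub == here:
                    state = s
                    break
        elif state == "X":
            rows_a.append(sa[i - 1])
            rows_b.append(GAP)
            if i == 1 and j == 0:
                state = "M"  # reached origin through the left border
                i -= 1
                continue
            if M[i - 1, j] + scores.gap_open + scores.gap_extend == X[i, j]:
                state = "M"
            i -= 1
        else:
            rows_a.append(GAP)
            rows_b.append(sb[j - 1])
            if j == 1 and i == 0:
                state = "M"
                j -= 1
                continue
            if M[i, j - 1] + scores.gap_open + scores.gap_extend == Y[i, j]:
                state = "M"
            j -= 1
    return Alignment([(a.id, "".join(reversed(rows_a))), (b.id, "".join(reversed(rows_b)))])


def alignment_score(aln: Alignment, scores: AlignScores = AlignScores()) -> float:
    """Score an existing pairwise alignment under the affine-gap scheme."""
    (ra, rb) = (aln.records[0][1], aln.records[1][1])
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ra, rb):
        if x == GAP:
            score += scores.gap_extend + (0 if in_gap_a else scores.gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += scores.gap_extend + (0 if in_gap_b else scores.gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += scores.match if x == y else scores.mismatch
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# p-distances


def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Columns where either row carries a gap or N are excluded; raises
    :class:`UndefinedDistanceError` when no comparable site remains.
    """
    if len(row_a) != len(row_b):
        raise ValidationError("rows have unequal length")
    diffs = n = 0
    for x, y in zip(row_a, row_b):
        if x in (GAP, AMBIGUOUS) or y in (GAP, AMBIGUOUS):
            continue
        n += 1
        diffs += x != y
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between the two rows")
    return diffs / n, n


def p_distance_se(
    p: float,
    n: int,
    method: Literal["analytic", "bootstrap"] = "analytic",
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Standard error of a p-distance.

    ``analytic``: binomial form sqrt(p(1-p)/n).  ``bootstrap``: resample the
    n compared columns with replacement ``reps`` times (a column differs with
    probability p) and report the standard deviation of the replicate
    estimates.
    """
    if not (0.0 <= p <= 1.0) or n < 1:
        raise ValidationError(f"invalid p={p}, n={n}")
    if method == "analytic":
        return math.sqrt(p * (1 - p) / n)
    if method == "bootstrap":
        if reps < 2:
            raise ValidationError("bootstrap requires reps >= 2")
        rng = np.random.default_rng(seed)
        reps_p = rng.binomial(n, p, size=reps) / n
        return float(np.std(reps_p, ddof=1))
    raise ValidationError(f"unknown SE method {method!r}")


def _pairwise_stats(row_a: str, row_b: str) -> tuple[int, int]:
    diffs = n = 0
    for x, y in zip(row_a, row_b):
        if x in (GAP, AMBIGUOUS) or y in (GAP, AMBIGUOUS):
            continue
        n += 1
        diffs += x != y
    return diffs, n


def species_distance_matrix(
    aln: Alignment,
    grouping: Mapping[str, str],
    se_method: Literal["analytic", "bootstrap"] = "bootstrap",
    reps: int = 1000,
    seed: int | None = 0,
    deletion: Literal["pairwise", "complete"] = "pairwise",
) -> DistanceMatrix:
    """Species-by-species mean p-distance matrix with standard errors.

    Each between-species entry is the arithmetic mean of all cross-species
    strain-pair p-distances (the group mean distance); its SE is computed on
    the concatenated comparison (total differences over total compared
    sites).  ``complete`` deletion drops every column containing a gap or N
    in any row before any comparison.
    """
    missing = [t for t in aln.ids if t not in grouping]
    if missing:
        raise ValidationError(f"taxa without a species assignment: {missing}")
    species = sorted(set(grouping[t] for t in aln.ids))
    members = {sp: [t for t in aln.ids if grouping[t] == sp] for sp in species}
    for sp, mem in members.items():
        if not mem:
            raise ValidationError(f"species {sp!r} has no taxa in the alignment")
    rows = dict(aln.records)
    if deletion == "complete":
        keep = [
            c
            for c in range(aln.length)
            if all(rows[t][c] not in (GAP, AMBIGUOUS) for t in aln.ids)
        ]
        rows = {t: "".join(rows[t][c] for c in keep) for t in aln.ids}
    k = len(species)
    d = np.zeros((k, k))
    se = np.zeros((k, k))
    n_sites = np.ones((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            ps = []
            tot_diffs = tot_n = 0
            for ta in members[species[i]]:
                for tb in members[species[j]]:
                    p, n = p_distance(rows[ta], rows[tb])
                    ps.append(p)
                    diffs, nn = _pairwise_stats(rows[ta], rows[tb])
                    tot_diffs += diffs
                    tot_n += nn
            d[i, j] = d[j, i] = float(np.mean(ps))
            p_pooled = tot_diffs / tot_n
            se[i, j] = se[j, i] = p_distance_se(p_pooled, tot_n, se_method, reps=reps, seed=seed)
            n_sites[i, j] = n_sites[j, i] = tot_n
    return DistanceMatrix(species, d, se, n_sites)
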