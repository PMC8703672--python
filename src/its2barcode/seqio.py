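"""Strict readers and writers for the formats the pipeline touches.

Sequences are held internally in the RNA alphabet {A, C, G, U, N}; DNA input
(T) is accepted and normalized on read, and the original alphabet is recorded
so writers can restore it.  All parsers raise :class:`ValidationError` with
the offending line number — silent coercion of malformed input is a bug
factory in taxonomic pipelines where a single residue matters.

Formats: FASTA (sequences and alignments), Vienna dot-bracket triplets
(header / sequence / structure), relaxed PHYLIP alignments (via Biopython),
and square or lower-triangle-with-SE distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import ValidationError

RNA_ALPHABET = set("ACGUN")
GAP = "-"

Alphabet = Literal["DNA", "RNA"]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence, normalized to RNA uppercase.

    ``source_alphabet`` records whether the input spelled the sequence with
    T (DNA) or U (RNA) so that round-trips can be exact.
    """

    id: str
    residues: str
    source_alphabet: Alphabet = "RNA"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id must be non-empty without whitespace: {self.id!r}")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"{self.id}: illegal residues {sorted(bad)} (normalized alphabet is ACGUN)")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> tuple[str, Alphabet]:
    """Uppercase and map T->U; report whether the input looked like DNA.

    Idempotent: normalizing the output again is a no-op and reports RNA.
    """
    upper = raw.upper()
    alphabet: Alphabet = "DNA" if "T" in upper else "RNA"
    return upper.replace("T", "U"), alphabet


@dataclass
class Alignment:
    """An ungappable-by-row multiple alignment ('-' is the gap character)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.records:
            L = len(self.records[0][1])
            for rid, row in self.records:
                if len(row) != L:
                    raise ValidationError(f"ragged alignment: row {rid!r} has length {len(row)}, expected {L}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, row in self.records:
            if r == rid:
                return row
        raise KeyError(rid)

    def ungapped(self, rid: str) -> NucSequence:
        res, alpha = normalize_residues(self.row(rid).replace(GAP, ""))
        return NucSequence(rid, res, alpha)


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_blocks(lines: list[str], *, allow_gaps: bool) -> list[tuple[str, str, int]]:
    """Return (id, raw_residues, header_lineno) triples with strict checks."""
    records: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    current: list[str] | None = None
    cur_id = ""
    cur_line = 0
    legal = set("ACGTUNacgtun") | ({GAP} if allow_gaps else set())
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if current is not None:
                records.append((cur_id, "".join(current), cur_line))
            cur_id = line[1:].split()[0] if line[1:].strip() else ""
            if not cur_id:
                raise ValidationError(f"line {lineno}: malformed header (empty id)")
            if cur_id in seen:
                raise ValidationError(f"line {lineno}: duplicate id {cur_id!r}")
            seen.add(cur_id)
            current = []
            cur_line = lineno
        else:
            if current is None:
                raise ValidationError(f"line {lineno}: sequence data before any '>' header")
            bad = set(line) - legal
            if bad:
                raise ValidationError(f"line {lineno}: illegal character(s) {sorted(bad)} in {cur_id!r}")
            current.append(line)
    if current is not None:
        records.append((cur_id, "".join(current), cur_line))
    return records


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file of nucleotide sequences, normalizing T->U."""
    lines = Path(path).read_text().splitlines()
    out = []
    for rid, raw, lineno in _parse_fasta_blocks(lines, allow_gaps=False):
        if not raw:
            raise ValidationError(f"line {lineno}: record {rid!r} has no residues")
        res, alpha = normalize_residues(raw)
        out.append(NucSequence(rid, res, alpha))
    return out


def write_fasta(records: Iterable[NucSequence], path: str | Path, *, width: int = 70) -> None:
    """Write FASTA, restoring T for records read from DNA. Wraps at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            res = rec.residues.replace("U", "T") if rec.source_alphabet == "DNA" else rec.residues
            fh.write(f">{rec.id}\n")
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Vienna dot-bracket triplets


def check_dotbracket(structure: str, *, lineno: int | None = None) -> list[tuple[int, int]]:
    """Validate a dot-bracket string; return its 1-based pair list."""
    where = f"line {lineno}: " if lineno is not None else ""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"{where}unbalanced brackets (unmatched ')' at position {pos})")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValidationError(f"{where}illegal structure character {ch!r} at position {pos}")
    if stack:
        raise ValidationError(f"{where}unbalanced brackets ({len(stack)} unmatched '(')")
    return sorted(pairs)


def read_vienna(path: str | Path) -> list[tuple[NucSequence, str]]:
    """Read header/sequence/structure triplets in Vienna dot-bracket format."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) % 3:
        raise ValidationError(f"{path}: expected header/sequence/structure triplets, got {len(lines)} lines")
    out: list[tuple[NucSequence, str]] = []
    seen: set[str] = set()
    for i in range(0, len(lines), 3):
        header, seqline, ssline = lines[i], lines[i + 1], lines[i + 2]
        lineno = i + 1
        if not header.startswith(">") or not header[1:].strip():
            raise ValidationError(f"line {lineno}: malformed header {header!r}")
        rid = header[1:].split()[0]
        if rid in seen:
            raise ValidationError(f"line {lineno}: duplicate id {rid!r}")
        seen.add(rid)
        res, alpha = normalize_residues(seqline)
        if len(ssline) != len(res):
            raise ValidationError(
                f"line {lineno + 2}: structure length {len(ssline)} != sequence length {len(res)} for {rid!r}"
            )
        check_dotbracket(ssline, lineno=lineno + 2)
        out.append((NucSequence(rid, res, alpha), ssline))
    return out


def write_vienna(records: Iterable[tuple[NucSequence, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec, ss in records:
            if len(ss) != len(rec.residues):
                raise ValidationError(f"{rec.id}: structure/sequence length mismatch")
            res = rec.residues.replace("U", "T") if rec.source_alphabet == "DNA" else rec.residues
            fh.write(f">{rec.id}\n{res}\n{ss}\n")


# ---------------------------------------------------------------------------
# Alignments (FASTA or relaxed PHYLIP)


def read_alignment(path: str | Path, dialect: Literal["fasta", "phylip"] = "fasta") -> Alignment:
    if dialect == "fasta":
        lines = Path(path).read_text().splitlines()
        rows = []
        for rid, raw, _ in _parse_fasta_blocks(lines, allow_gaps=True):
            res, _alpha = normalize_residues(raw)
            rows.append((rid, res))
    elif dialect == "phylip":
        from Bio import AlignIO

        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        rows = [(rec.id, normalize_residues(str(rec.seq))[0]) for rec in aln]
    else:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")
    for rid, row in rows:
        bad = set(row) - RNA_ALPHABET - {GAP}
        if bad:
            raise ValidationError(f"{rid}: illegal alignment character(s) {sorted(bad)}")
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path, dialect: Literal["fasta", "phylip"] = "fasta") -> None:
    if dialect == "fasta":
        with open(path, "w") as fh:
            for rid, row in aln.records:
                fh.write(f">{rid}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i : i + 70] + "\n")
    elif dialect == "phylip":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment([SeqRecord(Seq(row), id=rid, description="") for rid, row in aln.records])
        with open(path, "w") as fh:
            from Bio import AlignIO

            AlignIO.write(msa, fh, "phylip-relaxed")
    else:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(matrix, path: str | Path, layout: Literal["full", "lower-with-SE-upper"] = "full") -> None:
    """Write a DistanceMatrix (taxa, d, se) as a tab-separated table.

    ``full``: square distance matrix (round-trippable with
    :func:`read_distance_matrix`).  ``lower-with-SE-upper``: the classic
    published layout — p-distances below the diagonal, standard errors above,
    blank diagonal.  Values to 4 decimals.
    """
    taxa = list(matrix.taxa)
    d = np.asarray(matrix.d, dtype=float)
    se = np.asarray(matrix.se, dtype=float)
    if d.shape != (len(taxa), len(taxa)) or se.shape != d.shape:
        raise ValidationError("distance matrix is not square over its taxa")
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(taxa) + "\n")
        for i, t in enumerate(taxa):
            cells = []
            for j in range(len(taxa)):
                if layout == "full":
                    cells.append(f"{d[i, j]:.4f}")
                elif i == j:
                    cells.append("")
                elif i > j:
                    cells.append(f"{d[i, j]:.4f}")
                else:
                    cells.append(f"{se[i, j]:.4f}")
            fh.write(t + "\t" + "\t".join(cells) + "\n")


def read_distance_matrix(path: str | Path):
    """Read back a ``full``-layout distance matrix (SEs not stored)."""
    from .alignment import DistanceMatrix

    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "taxon":
        raise ValidationError(f"{path}: not a distance-matrix table (header {header[0]!r})")
    taxa = header[1:]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n + 1 or cells[0] != taxa[i]:
            raise ValidationError(f"{path}: row {i + 1} does not match header taxa")
        d[i] = [float(c) for c in cells[1:]]
    return DistanceMatrix(taxa=taxa, d=d, se=np.zeros((n, n)), n_sites=np.ones((n, n), dtype=int))
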