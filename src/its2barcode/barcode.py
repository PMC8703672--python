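"""Numeric barcoding of conserved ITS2 base pairs and CBC/hCBC detection.

Each template slot — a base pair (or single-stranded position) on a
reference secondary structure — is encoded as an integer:

    1 = A-U   2 = U-A   3 = G-C   4 = C-G   5 = G.U   6 = U.G
    7 = mismatch (both bases present but non-pairing)
    8 = deletion, single or unpaired bases

The ordered code vector is a taxon's barcode; identical barcodes share a
ribotype.  Differences between two taxa at one slot are classified by how
the nucleotide pair changed: a CBC substitutes both partners while pairing
is preserved (A-U -> G-C), an hCBC substitutes exactly one (G.U -> G-C),
and transitions into or out of the pairing codes 1-6 are pairing losses or
gains (indel/unpairing events).  CBC/hCBC status is decided on nucleotide
identity, not code identity, so U-A -> A-U is a CBC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import TemplateMismatchError, ValidationError
from .folding import DomainModel, StructuredSequence, helix_local_coordinates
from .seqio import Alignment

PAIR_TO_CODE: dict[tuple[str, str], int] = {
    ("A", "U"): 1,
    ("U", "A"): 2,
    ("G", "C"): 3,
    ("C", "G"): 4,
    ("G", "U"): 5,
    ("U", "G"): 6,
}
MISMATCH = 7
UNPAIRED = 8
PAIRING_CODES = frozenset(range(1, 7))

EventKind = Literal["CBC", "hCBC", "pairing_loss", "pairing_gain", "silent", "none"]


def code_pair(nt5: str, nt3: str, paired: bool) -> int:
    """Integer code for the bases at a template pair slot.

    An unpaired, deleted or gapped position codes 8 regardless of the bases;
    paired non-complementary bases code 7.  A single N facing a concrete
    base codes 7 (cannot be confirmed to pair); two Ns code 8.
    """
    for nt in (nt5, nt3):
        if nt not in "ACGUN-":
            raise ValidationError(f"illegal base {nt!r} at a barcode slot")
    if not paired or nt5 == "-" or nt3 == "-":
        return UNPAIRED
    if nt5 == "N" and nt3 == "N":
        return UNPAIRED
    if nt5 == "N" or nt3 == "N":
        return MISMATCH
    return PAIR_TO_CODE.get((nt5, nt3), MISMATCH)


@dataclass(frozen=True)
class TemplateSlot:
    """One barcode position anchored on the reference structure."""

    label: int  # 1-based barcode position number
    anchor5: int  # 1-based reference position
    anchor3: int | None  # None for a single-stranded slot
    conserved: bool = True


@dataclass(frozen=True)
class BarcodeTemplate:
    slots: tuple[TemplateSlot, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.slots]
        if labels != list(range(1, len(labels) + 1)):
            raise ValidationError("template labels must be consecutive from 1")
        anchors = [s.anchor5 for s in self.slots]
        if anchors != sorted(anchors) or len(set(anchors)) != len(anchors):
            raise ValidationError("template slots must be strictly ordered by 5' anchor")

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def conserved_labels(self) -> frozenset[int]:
        return frozenset(s.label for s in self.slots if s.conserved)


@dataclass(frozen=True)
class Barcode:
    """A taxon's ordered pair-code vector plus the observed bases behind it."""

    taxon: str
    codes: tuple[int, ...]
    bases: tuple[tuple[str, str], ...]
    ribotype: str | None = None

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.bases):
            raise ValidationError("codes and bases must have equal length")
        if any(c not in range(1, 9) for c in self.codes):
            raise ValidationError("barcode codes must lie in 1..8")

    def __len__(self) -> int:
        return len(self.codes)

    def code_string(self) -> str:
        return "".join(str(c) for c in self.codes)


@dataclass(frozen=True)
class ChangeEvent:
    """A classified difference between two taxa at one barcode slot."""

    slot: int
    helix_context: str | None  # e.g. "III:1" = basal pair of helix III
    from_code: int
    to_code: int
    from_pair: tuple[str, str]
    to_pair: tuple[str, str]
    kind: EventKind


def _check_consistent(code: int, pair: tuple[str, str]) -> None:
    if code in PAIRING_CODES:
        if PAIR_TO_CODE.get(pair) != code:
            raise ValidationError(f"code {code} inconsistent with bases {pair[0]}-{pair[1]}")
    elif code == MISMATCH:
        if pair in PAIR_TO_CODE or "-" in pair:
            raise ValidationError(f"code 7 (mismatch) inconsistent with bases {pair[0]}-{pair[1]}")
    elif code != UNPAIRED:
        raise ValidationError(f"illegal pair code {code}")


def classify_change(
    from_code: int, to_code: int, from_pair: tuple[str, str], to_pair: tuple[str, str]
) -> EventKind:
    """Kind of change between two coded slots (CBC/hCBC/loss/gain/silent/none)."""
    _check_consistent(from_code, from_pair)
    _check_consistent(to_code, to_pair)
    f_pairs = from_code in PAIRING_CODES
    t_pairs = to_code in PAIRING_CODES
    if f_pairs and t_pairs:
        changed = (from_pair[0] != to_pair[0]) + (from_pair[1] != to_pair[1])
        return ("none", "hCBC", "CBC")[changed]
    if f_pairs and not t_pairs:
        return "pairing_loss"
    if not f_pairs and t_pairs:
        return "pairing_gain"
    return "silent"


# ---------------------------------------------------------------------------
# Extraction


def mapping_from_alignment(aln: Alignment, ref_id: str, query_id: str) -> dict[int, int | None]:
    """Map 1-based reference positions to query positions via an alignment."""
    ref_row, q_row = aln.row(ref_id), aln.row(query_id)
    mapping: dict[int, int | None] = {}
    rpos = qpos = 0
    for rc, qc in zip(ref_row, q_row):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
            mapping[rpos] = qpos if qc != "-" else None
    return mapping


def extract_barcode(
    ssq: StructuredSequence,
    template: BarcodeTemplate,
    mapping: Mapping[int, int | None] | None = None,
) -> Barcode:
    """Encode a structured sequence against a barcode template.

    ``mapping`` sends each reference anchor position to the homologous query
    position (``None`` where the query has a gap); omit it only when the
    query is in the reference's own coordinate system (identity mapping).
    A slot whose anchor maps to a gap, or whose mapped positions the query
    structure leaves unpaired, codes 8.
    """
    L = len(ssq.seq)
    if mapping is None:
        mapping = {p: p for p in range(1, L + 1)}
    partner = ssq.ss.partner_map()

    def base_at(qpos: int | None) -> str:
        if qpos is None:
            return "-"
        return ssq.seq.residues[qpos - 1]

    codes: list[int] = []
    bases: list[tuple[str, str]] = []
    for slot in template.slots:
        anchors = (slot.anchor5,) if slot.anchor3 is None else (slot.anchor5, slot.anchor3)
        for a in anchors:
            if a not in mapping:
                raise ValidationError(f"mapping does not cover template anchor {a} (slot {slot.label})")
        if slot.anchor3 is None:
            codes.append(UNPAIRED)
            bases.append((base_at(mapping[slot.anchor5]), "-"))
            continue
        q5, q3 = mapping[slot.anchor5], mapping[slot.anchor3]
        b5, b3 = base_at(q5), base_at(q3)
        paired = q5 is not None and q3 is not None and partner.get(q5) == q3
        codes.append(code_pair(b5, b3, paired))
        bases.append((b5, b3))
    return Barcode(ssq.seq.id, tuple(codes), tuple(bases))


def detect_events(
    a: Barcode,
    b: Barcode,
    template: BarcodeTemplate,
    conserved_only: bool = False,
    domain_model: DomainModel | None = None,
) -> list[ChangeEvent]:
    """All non-trivial slot changes from ``a`` to ``b`` (kind != none/silent).

    With ``conserved_only`` set, slots flagged non-conserved in the template
    (e.g. variable apical helix-I pairs) are skipped.  ``domain_model`` of
    the template's reference structure adds helix-local context (label and
    basal offset) to each event.
    """
    if len(a) != len(template) or len(b) != len(template):
        raise TemplateMismatchError("barcodes do not match the template length")
    events: list[ChangeEvent] = []
    for slot in template.slots:
        if conserved_only and not slot.conserved:
            continue
        k = slot.label - 1
        kind = classify_change(a.codes[k], b.codes[k], a.bases[k], b.bases[k])
        if kind in ("none", "silent"):
            continue
        context = None
        if domain_model is not None and slot.anchor3 is not None:
            try:
                hl, off = helix_local_coordinates(domain_model, (slot.anchor5, slot.anchor3))
                context = f"{hl}:{off}"
            except Exception:
                context = None
        events.append(
            ChangeEvent(slot.label, context, a.codes[k], b.codes[k], a.bases[k], b.bases[k], kind)
        )
    return events


def assign_ribotypes(barcodes: Sequence[Barcode], prefix: str = "RT") -> tuple[list[Barcode], int]:
    """Label identical code vectors with shared ribotype names.

    Ribotypes are numbered by first occurrence: ``1<prefix>``, ``2<prefix>``,
    ... (e.g. prefix ``CORI`` yields 1CORI, 2CORI).  Returns the relabelled
    barcodes and the number of distinct ribotypes.
    """
    seen: dict[tuple[int, ...], str] = {}
    out: list[Barcode] = []
    for bc in barcodes:
        if bc.codes not in seen:
            seen[bc.codes] = f"{len(seen) + 1}{prefix}"
        out.append(replace(bc, ribotype=seen[bc.codes]))
    return out, len(seen)


# ---------------------------------------------------------------------------
# TSV interfaces


def read_template(path: str | Path) -> BarcodeTemplate:
    df = pd.read_csv(path, sep="\t")
    required = {"slot", "anchor5", "anchor3", "conserved"}
    if not required.issubset(df.columns):
        raise ValidationError(f"template TSV must have columns {sorted(required)}")
    slots = []
    for _, row in df.iterrows():
        anchor3 = None if pd.isna(row["anchor3"]) else int(row["anchor3"])
        slots.append(TemplateSlot(int(row["slot"]), int(row["anchor5"]), anchor3, bool(row["conserved"])))
    return BarcodeTemplate(tuple(slots))


def write_template(template: BarcodeTemplate, path: str | Path) -> None:
    rows = [
        {
            "slot": s.label,
            "anchor5": s.anchor5,
            "anchor3": "" if s.anchor3 is None else s.anchor3,
            "conserved": s.conserved,
        }
        for s in template.slots
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_barcode_table(barcodes: Iterable[Barcode], path: str | Path) -> None:
    rows = [{"taxon": b.taxon, "ribotype": b.ribotype or "", "codes": b.code_string()} for b in barcodes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_events_table(events: Iterable[ChangeEvent], path: str | Path) -> None:
    rows = [
        {
            "slot": e.slot,
            "helix": e.helix_context or "",
            "from_code": e.from_code,
            "to_code": e.to_code,
            "from_pair": f"{e.from_pair[0]}{e.from_pair[1]}",
            "to_pair": f"{e.to_pair[0]}{e.to_pair[1]}",
            "kind": e.kind,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["slot", "helix", "from_code", "to_code", "from_pair", "to_pair", "kind"]).to_csv(
        path, sep="\t", index=False
    )
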