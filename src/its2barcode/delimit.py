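"""Species-comparison reports combining distances, barcodes and events.

The report mirrors how ITS2 barcoding evidence is actually weighed: a
p-distance with its standard error, the CBC/hCBC/indel events split into
conserved-region and variable-region lists, and two flags — whether the two
taxa are differentiated by at least one CBC or hCBC at a conserved slot,
and whether their barcodes differ at all (distinct ribotypes).  The flags
are descriptive; the module never renders a binary "new species" verdict,
because compensatory changes support, but do not decide, a delimitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import p_distance, p_distance_se
from .barcode import Barcode, BarcodeTemplate, ChangeEvent, classify_change, detect_events
from .errors import TemplateMismatchError, ValidationError
from .folding import DomainModel
from .seqio import Alignment

_DIRECTIONLESS = {"pairing_loss": "pairing_change", "pairing_gain": "pairing_change"}


@dataclass
class ComparisonReport:
    taxon_a: str
    taxon_b: str
    p: float
    se: float
    n_sites: int
    events_conserved: list[ChangeEvent]
    events_variable: list[ChangeEvent]

    @property
    def n_cbc(self) -> int:
        return sum(e.kind == "CBC" for e in self.all_events)

    @property
    def n_hcbc(self) -> int:
        return sum(e.kind == "hCBC" for e in self.all_events)

    @property
    def n_indel(self) -> int:
        return sum(e.kind in ("pairing_loss", "pairing_gain") for e in self.all_events)

    @property
    def all_events(self) -> list[ChangeEvent]:
        return self.events_conserved + self.events_variable

    @property
    def distinct_conserved_cbc_or_hcbc(self) -> bool:
        return any(e.kind in ("CBC", "hCBC") for e in self.events_conserved)

    @property
    def distinct_ribotype(self) -> bool:
        return bool(self.all_events)

    def summary(self) -> str:
        lines = [
            f"comparison: {self.taxon_a} vs {self.taxon_b}",
            f"p-distance: {self.p:.4f} +/- {self.se:.4f} ({self.n_sites} sites)",
            f"events: {self.n_cbc} CBC, {self.n_hcbc} hCBC, {self.n_indel} indel/unpairing",
            f"differentiated at conserved positions: {'yes' if self.distinct_conserved_cbc_or_hcbc else 'no'}",
            f"distinct ribotypes: {'yes' if self.distinct_ribotype else 'no'}",
        ]
        return "\n".join(lines)


def compare_taxa(
    a: Barcode,
    b: Barcode,
    aln: Alignment,
    template: BarcodeTemplate,
    domain_model: DomainModel | None = None,
    se_method: str = "bootstrap",
    reps: int = 1000,
    seed: int | None = 0,
) -> ComparisonReport:
    """Full pairwise comparison of two barcoded taxa present in ``aln``."""
    for t in (a.taxon, b.taxon):
        if t not in aln.ids:
            raise ValidationError(f"taxon {t!r} is not in the alignment")
    p, n = p_distance(aln.row(a.taxon), aln.row(b.taxon))
    se = p_distance_se(p, n, se_method, reps=reps, seed=seed)
    events = detect_events(a, b, template, conserved_only=False, domain_model=domain_model)
    conserved = template.conserved_labels
    return ComparisonReport(
        a.taxon,
        b.taxon,
        p,
        se,
        n,
        [e for e in events if e.slot in conserved],
        [e for e in events if e.slot not in conserved],
    )


def report_to_tsv(report: ComparisonReport, path: str | Path) -> None:
    rows = []
    for region, events in (("conserved", report.events_conserved), ("variable", report.events_variable)):
        for e in events:
            rows.append(
                {
                    "taxon_a": report.taxon_a,
                    "taxon_b": report.taxon_b,
                    "p": f"{report.p:.6f}",
                    "se": f"{report.se:.6f}",
                    "n_sites": report.n_sites,
                    "region": region,
                    "slot": e.slot,
                    "helix": e.helix_context or "",
                    "from_code": e.from_code,
                    "to_code": e.to_code,
                    "from_pair": f"{e.from_pair[0]}{e.from_pair[1]}",
                    "to_pair": f"{e.to_pair[0]}{e.to_pair[1]}",
                    "kind": e.kind,
                }
            )
    if not rows:
        rows.append(
            {
                "taxon_a": report.taxon_a,
                "taxon_b": report.taxon_b,
                "p": f"{report.p:.6f}",
                "se": f"{report.se:.6f}",
                "n_sites": report.n_sites,
                "region": "",
                "slot": "",
                "helix": "",
                "from_code": "",
                "to_code": "",
                "from_pair": "",
                "to_pair": "",
                "kind": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def report_from_tsv(path: str | Path) -> ComparisonReport:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: empty report table")
    first = df.iloc[0]
    cons: list[ChangeEvent] = []
    var: list[ChangeEvent] = []
    for _, row in df.iterrows():
        if row["region"] == "":
            continue
        ev = ChangeEvent(
            int(row["slot"]),
            str(row["helix"]) or None,
            int(row["from_code"]),
            int(row["to_code"]),
            (row["from_pair"][0], row["from_pair"][1]),
            (row["to_pair"][0], row["to_pair"][1]),
            row["kind"],
        )
        (cons if row["region"] == "conserved" else var).append(ev)
    return ComparisonReport(
        str(first["taxon_a"]),
        str(first["taxon_b"]),
        float(first["p"]),
        float(first["se"]),
        int(first["n_sites"]),
        cons,
        var,
    )


def render_barcode_alignment(
    barcodes: Sequence[Barcode], template: BarcodeTemplate, markdown: bool = False
) -> str:
    """Ribotype-by-slot code table with an asterisk track.

    One row per distinct ribotype (first strain carrying it named), one
    column per template slot; a slot gets an asterisk when any pair of
    barcodes in the set differs there by a CBC, hCBC or pairing change.
    """
    for bc in barcodes:
        if len(bc) != len(template):
            raise TemplateMismatchError(f"barcode of {bc.taxon!r} does not match the template")
    rows: list[Barcode] = []
    seen: set[tuple[int, ...]] = set()
    for bc in barcodes:
        if bc.codes not in seen:
            seen.add(bc.codes)
            rows.append(bc)
    marks = []
    for k in range(len(template)):
        flagged = False
        for x in range(len(rows)):
            for y in range(x + 1, len(rows)):
                kind = classify_change(rows[x].codes[k], rows[y].codes[k], rows[x].bases[k], rows[y].bases[k])
                if kind in ("CBC", "hCBC", "pairing_loss", "pairing_gain"):
                    flagged = True
        marks.append("*" if flagged else "")
    header = ["ribotype"] + [str(s.label) for s in template.slots]
    body = [[bc.ribotype or bc.taxon] + [str(c) for c in bc.codes] for bc in rows]
    footer = ["marks"] + marks
    if markdown:
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for row in body + [footer]:
            lines.append("| " + " | ".join(row) + " |")
        return "\n".join(lines) + "\n"
    lines = ["\t".join(header)]
    for row in body + [footer]:
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
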