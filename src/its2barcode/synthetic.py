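"""Seeded generator of ITS2-like datasets with known ground truth.

The generator emits a reference sequence designed to fold into the canonical
four-helix / five-single-stranded-region ITS2 layout, a barcode template over
its designed pairs (the basal five pairs of each helix flagged conserved),
species derived from the reference by planting CBC / hCBC / pairing-loss
events at chosen slots, strains differing at designated non-conserved slots
(so a species can carry several ribotypes), and background divergence placed
by quota: exactly round(d * sites) substitutions, so a recovery test has a
zero-variance target.  Every choice is driven by one integer seed and the
emitted files are byte-identical across reruns.

Default geometry: stems of 12/8/20/10 pairs, hairpin loops of 3 and
single-stranded spacers of 2 nt, giving a 122 nt reference with 100 paired
nucleotides (82% — the paired fraction reported for real ITS2 of the group
this generator emulates).  The substitution model is uniform over admissible
alternatives; no transition/transversion bias.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .barcode import BarcodeTemplate, PAIR_TO_CODE, TemplateSlot, write_template
from .errors import ValidationError
from .folding import CANONICAL_PAIRS, SecondaryStructure, StructuredSequence
from .seqio import NucSequence, write_fasta, write_vienna

CODE_TO_PAIR = {c: p for p, c in PAIR_TO_CODE.items()}
BASES = "ACGU"

PlantKind = Literal["CBC", "hCBC", "pairing_loss"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator (seed is mandatory)."""

    seed: int
    stems: tuple[int, int, int, int] = (12, 8, 20, 10)  # pairs per helix I..IV
    loops: tuple[int, int, int, int] = (3, 3, 3, 3)  # hairpin loop lengths
    spacers: tuple[int, int, int, int, int] = (2, 2, 2, 2, 2)  # 5 ss regions
    gc_fraction: float = 0.55
    wobble_fraction: float = 0.10
    n_species: int = 2
    strains_per_species: tuple[int, ...] = (3, 1)
    # events planted in species 2..n relative to species 1 (slot, kind)
    species_events: tuple[tuple[tuple[int, PlantKind], ...], ...] = ((),)
    # non-conserved slot at which a second ribotype is created within species 1
    ribotype_slot: int | None = None
    background_divergence: float = 0.10
    divergence_mode: Literal["quota", "iid"] = "quota"

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.stems) or any(l < 3 for l in self.loops):
            raise ValidationError("stems need >= 1 pair and hairpin loops >= 3 nt")
        if any(s < 0 for s in self.spacers):
            raise ValidationError("spacer lengths must be non-negative")
        if not (0.0 <= self.background_divergence <= 0.3):
            raise ValidationError("background divergence must lie in [0, 0.3]")
        if len(self.strains_per_species) != self.n_species:
            raise ValidationError("strains_per_species must list one count per species")
        if len(self.species_events) != self.n_species - 1:
            raise ValidationError("species_events must cover species 2..n")


def default_spec(seed: int) -> SyntheticSpec:
    """The default two-species study design.

    Species 1 has three strains forming two ribotypes (a pairing-loss
    difference at a non-conserved slot); species 2 is its sister, separated
    by one conserved basal-helix-III hCBC, one non-conserved hCBC and one
    non-conserved CBC in apical helix I, plus 10% background divergence in
    the unpaired regions.
    """
    return SyntheticSpec(
        seed=seed,
        species_events=(((21, "hCBC"), (11, "hCBC"), (12, "CBC")),),
        ribotype_slot=39,
    )


# ---------------------------------------------------------------------------
# Reference and template


def make_reference(spec: SyntheticSpec) -> tuple[StructuredSequence, BarcodeTemplate]:
    """Design the four-helix reference and its barcode template.

    Helix pairs are sampled GC/CG with probability ``gc_fraction``, G.U/U.G
    with ``wobble_fraction`` and A-U/U-A otherwise; loops and spacers are
    uniform random bases.  Template slots anchor every designed pair in 5'
    order; the basal five pairs of each helix are flagged conserved.
    """
    rng = np.random.default_rng(spec.seed)
    total = 2 * sum(spec.stems) + sum(spec.loops) + sum(spec.spacers)
    seq = [""] * total
    pairs: list[tuple[int, int]] = []
    helix_pairs: list[list[tuple[int, int]]] = []
    pos = 0  # 0-based cursor
    for h in range(4):
        pos += spec.spacers[h]
        stem, loop = spec.stems[h], spec.loops[h]
        start5 = pos
        start3 = pos + 2 * stem + loop - 1
        hp = []
        for k in range(stem):
            i, j = start5 + k, start3 - k
            p5, p3 = _sample_pair(rng, spec.gc_fraction, spec.wobble_fraction)
            seq[i], seq[j] = p5, p3
            hp.append((i + 1, j + 1))
        for k in range(loop):
            seq[start5 + stem + k] = BASES[rng.integers(4)]
        helix_pairs.append(hp)
        pairs.extend(hp)
        pos = start3 + 1
    pos_end = pos + spec.spacers[4]
    assert pos_end == total
    for k, c in enumerate(seq):
        if not c:  # spacer bases
            seq[k] = BASES[rng.integers(4)]
    residues = "".join(seq)
    ss = SecondaryStructure.from_pairs(sorted(pairs), total)
    ssq = StructuredSequence(NucSequence("reference", residues), ss)
    slots = []
    label = 0
    conserved_depth = 5
    for hp in helix_pairs:
        for off, (i, j) in enumerate(hp, start=1):
            label += 1
            slots.append(TemplateSlot(label, i, j, conserved=off <= conserved_depth))
    template = BarcodeTemplate(tuple(slots))
    return ssq, template


def _sample_pair(rng: np.random.Generator, gc: float, wobble: float) -> tuple[str, str]:
    u = rng.random()
    if u < gc:
        fam = [("G", "C"), ("C", "G")]
    elif u < gc + wobble:
        fam = [("G", "U"), ("U", "G")]
    else:
        fam = [("A", "U"), ("U", "A")]
    return fam[rng.integers(2)]


# ---------------------------------------------------------------------------
# Planted events


@dataclass(frozen=True)
class PlantedEvent:
    slot: int
    kind: PlantKind
    from_pair: tuple[str, str]
    to_pair: tuple[str, str]


@dataclass
class TruthSet:
    """Ground truth emitted alongside a generated dataset."""

    events_by_pair: dict[tuple[str, str], list[PlantedEvent]]
    true_divergence: dict[tuple[str, str], float]
    ribotype_partition: dict[str, str]  # strain id -> expected ribotype label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [
                {
                    "pair": list(k),
                    "events": [asdict(e) for e in v],
                }
                for k, v in self.events_by_pair.items()
            ],
            "true_divergence": [{"pair": list(k), "d": v} for k, v in self.true_divergence.items()],
            "ribotype_partition": self.ribotype_partition,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")


def _event_options(pair: tuple[str, str], kind: PlantKind) -> list[tuple[str, str]]:
    opts = []
    if kind == "CBC":
        opts = [q for q in CANONICAL_PAIRS if q[0] != pair[0] and q[1] != pair[1]]
    elif kind == "hCBC":
        opts = [q for q in CANONICAL_PAIRS if (q[0] != pair[0]) + (q[1] != pair[1]) == 1]
    elif kind == "pairing_loss":
        for side in (0, 1):
            for b in BASES:
                q = (b, pair[1]) if side == 0 else (pair[0], b)
                if q != pair and q not in CANONICAL_PAIRS:
                    opts.append(q)
    return sorted(set(opts))


def plant_events(
    ref: StructuredSequence,
    template: BarcodeTemplate,
    events: Sequence[tuple[int, PlantKind]],
    seed: int,
    taxon: str | None = None,
) -> tuple[StructuredSequence, list[PlantedEvent]]:
    """Mutate the reference at template slots to create the requested events.

    CBC: both partners substituted to another legal pair with both bases
    changed; hCBC: one partner substituted, pairing kept; pairing_loss: one
    partner substituted so that the bases no longer pair (and the pair is
    removed from the mutant's structure).  Substitutions are drawn uniformly
    among the qualifying options with the given seed.
    """
    rng = np.random.default_rng(seed)
    residues = list(ref.seq.residues)
    pairset = set(ref.ss.pairs)
    slot_by_label = {s.label: s for s in template.slots}
    planted: list[PlantedEvent] = []
    for label, kind in events:
        slot = slot_by_label.get(label)
        if slot is None or slot.anchor3 is None:
            raise ValidationError(f"slot {label} does not anchor a base pair")
        i, j = slot.anchor5, slot.anchor3
        cur = (residues[i - 1], residues[j - 1])
        options = _event_options(cur, kind)
        if not options:
            raise ValidationError(f"no {kind} is feasible from pair {cur[0]}-{cur[1]} at slot {label}")
        new = options[rng.integers(len(options))]
        residues[i - 1], residues[j - 1] = new
        if kind == "pairing_loss":
            pairset.discard((i, j))
        planted.append(PlantedEvent(label, kind, cur, new))
    ss = SecondaryStructure.from_pairs(sorted(pairset), len(ref.ss))
    name = taxon or f"{ref.seq.id}_mut"
    mutant = StructuredSequence(NucSequence(name, "".join(residues)), ss)
    return mutant, planted


def simulate_divergence(
    ref: NucSequence,
    d: float,
    mask: Sequence[int] = (),
    seed: int = 0,
    mode: Literal["quota", "iid"] = "quota",
    taxon: str | None = None,
) -> NucSequence:
    """Place substitutions outside ``mask`` (1-based protected positions).

    ``quota`` substitutes exactly round(d * n_unmasked) positions (sampled
    without replacement), so the realized divergence equals ``d`` by
    construction; ``iid`` mutates each unmasked site independently with
    probability ``d``.
    """
    if not (0.0 <= d <= 0.3):
        raise ValidationError("divergence must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    residues = list(ref.residues)
    unmasked = np.array([p for p in range(1, len(residues) + 1) if p not in set(mask)])
    if mode == "quota":
        k = round(d * len(unmasked))
        targets = rng.choice(unmasked, size=k, replace=False) if k else np.array([], dtype=int)
    elif mode == "iid":
        targets = unmasked[rng.random(len(unmasked)) < d]
    else:
        raise ValidationError(f"unknown divergence mode {mode!r}")
    for p in sorted(int(t) for t in targets):
        alternatives = [b for b in BASES if b != residues[p - 1]]
        residues[p - 1] = alternatives[rng.integers(3)]
    return NucSequence(taxon or f"{ref.id}_div", "".join(residues), ref.source_alphabet)


# ---------------------------------------------------------------------------
# Full datasets


@dataclass
class Dataset:
    spec: SyntheticSpec
    reference: StructuredSequence
    template: BarcodeTemplate
    strains: list[StructuredSequence]  # all strains, all species
    species_of: dict[str, str]
    truth: TruthSet


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """A self-consistent multi-species fixture with its truth ledger.

    Species 1's strains are the reference ribotype plus, when
    ``ribotype_slot`` is set, a second ribotype carrying a pairing-loss at
    that (non-conserved) slot in its last strain.  Each further species is
    the reference with its planted event list applied and background
    divergence placed outside the template anchors (quota mode by default).
    """
    ref, template = make_reference(spec)
    anchor_positions = [s.anchor5 for s in template.slots] + [
        s.anchor3 for s in template.slots if s.anchor3 is not None
    ]
    strains: list[StructuredSequence] = []
    species_of: dict[str, str] = {}
    events_by_pair: dict[tuple[str, str], list[PlantedEvent]] = {}
    true_div: dict[tuple[str, str], float] = {}
    ribotype_partition: dict[str, str] = {}

    # species 1: reference ribotype, optionally a second ribotype in the last strain
    sp1 = "sp1"
    n1 = spec.strains_per_species[0]
    variant = None
    if spec.ribotype_slot is not None:
        if n1 < 2:
            raise ValidationError("a second ribotype requires at least two strains in species 1")
        if spec.ribotype_slot in template.conserved_labels:
            raise ValidationError("ribotype_slot must be a non-conserved template slot")
        variant, var_events = plant_events(
            ref, template, [(spec.ribotype_slot, "pairing_loss")], seed=spec.seed + 1
        )
    for k in range(n1):
        name = f"{sp1}_strain{k + 1}"
        base = variant if (variant is not None and k == n1 - 1) else ref
        strains.append(StructuredSequence(NucSequence(name, base.seq.residues), base.ss))
        species_of[name] = sp1
        ribotype_partition[name] = "RT2" if base is variant else "RT1"
        if base is variant:
            events_by_pair[(f"{sp1}_strain1", name)] = var_events

    # further species: planted events + masked background divergence
    for s_idx in range(1, spec.n_species):
        sp = f"sp{s_idx + 1}"
        planted_src, planted = plant_events(
            ref, template, spec.species_events[s_idx - 1], seed=spec.seed + 100 + s_idx
        )
        diverged = simulate_divergence(
            planted_src.seq,
            spec.background_divergence,
            mask=anchor_positions,
            seed=spec.seed + 200 + s_idx,
            mode=spec.divergence_mode,
        )
        for k in range(spec.strains_per_species[s_idx]):
            name = f"{sp}_strain{k + 1}"
            strains.append(StructuredSequence(NucSequence(name, diverged.residues), planted_src.ss))
            species_of[name] = sp
            ribotype_partition[name] = f"RT_{sp}"
        events_by_pair[(sp1, sp)] = planted
        n_unmasked = len(ref.seq) - len(set(anchor_positions))
        realized = round(spec.background_divergence * n_unmasked) / n_unmasked if n_unmasked else 0.0
        true_div[(sp1, sp)] = realized if spec.divergence_mode == "quota" else spec.background_divergence

    truth = TruthSet(events_by_pair, true_div, ribotype_partition)
    return Dataset(spec, ref, template, strains, species_of, truth)


def write_dataset(ds: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, Vienna, template TSV, groups TSV and truth JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "strains.fasta",
        "vienna": out / "strains.vienna",
        "reference": out / "reference.vienna",
        "template": out / "template.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    write_fasta([s.seq for s in ds.strains], paths["fasta"])
    write_vienna([(s.seq, s.ss.structure) for s in ds.strains], paths["vienna"])
    write_vienna([(ds.reference.seq, ds.reference.ss.structure)], paths["reference"])
    write_template(ds.template, paths["template"])
    with open(paths["groups"], "w") as fh:
        fh.write("taxon\tspecies\n")
        for s in ds.strains:
            fh.write(f"{s.seq.id}\t{ds.species_of[s.seq.id]}\n")
    ds.truth.to_json(paths["truth"])
    return paths
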