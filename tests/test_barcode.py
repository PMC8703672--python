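"""Pair-code legend, CBC/hCBC classification and planted-event recovery."""

import numpy as np
import pytest

import its2barcode as ib
from its2barcode.barcode import PAIR_TO_CODE, code_pair
from its2barcode.synthetic import plant_events

LEGEND = {
    ("A", "U"): 1,
    ("U", "A"): 2,
    ("G", "C"): 3,
    ("C", "G"): 4,
    ("G", "U"): 5,
    ("U", "G"): 6,
}


class TestCodePair:
    @pytest.mark.parametrize("pair,code", sorted(LEGEND.items()))
    def test_legend_pairing_codes(self, pair, code):
        assert code_pair(pair[0], pair[1], paired=True) == code

    def test_mismatch_codes_seven(self):
        assert code_pair("A", "A", paired=True) == 7
        assert code_pair("C", "U", paired=True) == 7

    def test_gap_or_unpaired_codes_eight(self):
        assert code_pair("U", "-", paired=True) == 8
        assert code_pair("A", "U", paired=False) == 8

    def test_total_over_the_whole_input_alphabet(self):
        # every base/gap combination, paired or not, yields a code in 1..8
        for a in "ACGUN-":
            for b in "ACGUN-":
                for paired in (True, False):
                    code = code_pair(a, b, paired)
                    assert code in range(1, 9)
                    if not paired or "-" in (a, b):
                        assert code == 8

    def test_ambiguity_rules(self):
        # N facing a concrete base cannot be confirmed to pair: mismatch
        assert code_pair("N", "U", paired=True) == 7
        assert code_pair("N", "N", paired=True) == 8

    def test_illegal_base_raises(self):
        with pytest.raises(ib.ValidationError):
            code_pair("X", "U", paired=True)


class TestClassifyChange:
    def test_wobble_to_watson_crick_is_hcbc(self):
        # G.U -> G-C: one partner substituted, pairing kept
        assert ib.classify_change(5, 3, ("G", "U"), ("G", "C")) == "hCBC"

    def test_double_substitution_keeping_pairing_is_cbc(self):
        assert ib.classify_change(1, 3, ("A", "U"), ("G", "C")) == "CBC"

    def test_pair_swap_is_cbc_despite_same_bases(self):
        # U-A -> A-U changes both nucleotides although the base set is identical
        assert ib.classify_change(2, 1, ("U", "A"), ("A", "U")) == "CBC"

    def test_identity_is_none(self):
        assert ib.classify_change(1, 1, ("A", "U"), ("A", "U")) == "none"

    def test_loss_gain_and_silent(self):
        assert ib.classify_change(2, 8, ("U", "A"), ("U", "C")) == "pairing_loss"
        assert ib.classify_change(8, 2, ("U", "C"), ("U", "A")) == "pairing_gain"
        assert ib.classify_change(8, 7, ("U", "C"), ("A", "A")) == "silent"

    def test_inconsistent_code_pair_input_raises(self):
        with pytest.raises(ib.ValidationError):
            ib.classify_change(3, 1, ("A", "U"), ("A", "U"))  # code 3 is not A-U

    def test_swap_antisymmetry_property(self):
        rng = np.random.default_rng(31)
        mirror = {"pairing_loss": "pairing_gain", "pairing_gain": "pairing_loss"}
        cases = list(LEGEND.items()) + [(("A", "A"), 7), (("C", "U"), 7), (("U", "-"), 8), (("G", "G"), 7)]
        for _ in range(300):
            (pa, ca), (pb, cb) = (cases[rng.integers(len(cases))] for _ in range(2))
            kind = ib.classify_change(ca, cb, pa, pb)
            back = ib.classify_change(cb, ca, pb, pa)
            assert back == mirror.get(kind, kind)


class TestExtractBarcode:
    def test_reference_against_its_own_template_reproduces_pair_codes(self, reference_and_template):
        ref, template = reference_and_template
        bc = ib.extract_barcode(ref, template)
        for slot, code, bases in zip(template.slots, bc.codes, bc.bases):
            assert code == PAIR_TO_CODE[bases]
            assert bases == ref.pair_bases((slot.anchor5, slot.anchor3))

    def test_planted_hcbc_changes_exactly_one_slot(self, reference_and_template):
        ref, template = reference_and_template
        mutant, planted = plant_events(ref, template, [(21, "hCBC")], seed=5)
        bc_ref = ib.extract_barcode(ref, template)
        bc_mut = ib.extract_barcode(mutant, template)
        diff = [k + 1 for k, (x, y) in enumerate(zip(bc_ref.codes, bc_mut.codes)) if x != y]
        assert diff == [21]

    def test_deleted_anchor_codes_eight(self, reference_and_template):
        ref, template = reference_and_template
        slot = template.slots[0]
        mapping = {p: p for p in range(1, len(ref.seq) + 1)}
        mapping[slot.anchor5] = None
        bc = ib.extract_barcode(ref, template, mapping)
        assert bc.codes[0] == 8

    def test_mapping_missing_an_anchor_raises(self, reference_and_template):
        ref, template = reference_and_template
        mapping = {p: p for p in range(2, len(ref.seq) + 1)}  # anchor 1 absent
        # first slot anchors position 3 in the default design; drop that instead
        mapping.pop(template.slots[0].anchor5, None)
        with pytest.raises(ib.ValidationError, match="anchor"):
            ib.extract_barcode(ref, template, mapping)


class TestDetectEvents:
    def test_self_comparison_is_empty(self, reference_and_template):
        ref, template = reference_and_template
        bc = ib.extract_barcode(ref, template)
        assert ib.detect_events(bc, bc, template) == []

    def test_template_length_mismatch_raises(self, reference_and_template):
        ref, template = reference_and_template
        bc = ib.extract_barcode(ref, template)
        short = ib.BarcodeTemplate(template.slots[:10])
        with pytest.raises(ib.TemplateMismatchError):
            ib.detect_events(bc, bc, short)

    def test_conserved_only_skips_variable_slots(self, reference_and_template):
        ref, template = reference_and_template
        mutant, _ = plant_events(ref, template, [(11, "hCBC")], seed=3)  # non-conserved slot
        a = ib.extract_barcode(ref, template)
        b = ib.extract_barcode(mutant, template)
        assert len(ib.detect_events(a, b, template)) == 1
        assert ib.detect_events(a, b, template, conserved_only=True) == []

    def test_planted_event_recovery_is_exact_over_many_mutants(self, reference_and_template):
        # precision = recall = 1.0 for position and kind in the noise-free regime
        ref, template = reference_and_template
        bc_ref = ib.extract_barcode(ref, template)
        rng = np.random.default_rng(77)
        kinds = ["CBC", "hCBC", "pairing_loss"]
        for rep in range(500):
            k = int(rng.integers(0, 6))
            slots = rng.choice(len(template), size=k, replace=False) + 1
            wanted = [(int(s), kinds[rng.integers(3)]) for s in sorted(slots)]
            mutant, planted = plant_events(ref, template, wanted, seed=rep)
            found = ib.detect_events(bc_ref, ib.extract_barcode(mutant, template), template)
            assert {(e.slot, e.kind) for e in found} == {(p.slot, p.kind) for p in planted}

    def test_event_carries_helix_context(self, reference_and_template):
        ref, template = reference_and_template
        dm = ib.annotate_domains(ref)
        mutant, _ = plant_events(ref, template, [(21, "hCBC")], seed=1)
        (event,) = ib.detect_events(
            ib.extract_barcode(ref, template), ib.extract_barcode(mutant, template), template, domain_model=dm
        )
        assert event.helix_context == "III:1"  # basal pair of helix III


class TestRibotypes:
    def test_identical_barcodes_share_one_ribotype(self, reference_and_template):
        ref, template = reference_and_template
        bc = ib.extract_barcode(ref, template)
        labelled, n = ib.assign_ribotypes([bc, bc, bc], "CORI")
        assert n == 1
        assert {b.ribotype for b in labelled} == {"1CORI"}

    def test_one_slot_difference_makes_two_ribotypes(self, reference_and_template):
        ref, template = reference_and_template
        mutant, _ = plant_events(ref, template, [(39, "hCBC")], seed=2)
        bcs = [ib.extract_barcode(s, template) for s in (ref, mutant)]
        _, n = ib.assign_ribotypes(bcs, "CORI")
        assert n == 2

    def test_three_strain_species_with_intra_species_variant_has_two_ribotypes(self, default_dataset):
        ds = default_dataset
        sp1 = [s for s in ds.strains if ds.species_of[s.seq.id] == "sp1"]
        assert len(sp1) == 3
        bcs = [ib.extract_barcode(s, ds.template) for s in sp1]
        labelled, n = ib.assign_ribotypes(bcs, "CORI")
        assert n == 2
        assert [b.ribotype for b in labelled] == ["1CORI", "1CORI", "2CORI"]
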