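"""Folding DP against exhaustive enumeration, and domain annotation."""

import numpy as np
import pytest

import its2barcode as ib
from its2barcode.folding import MIN_LOOP, annotate_domains, structure_score

from oracles import best_structures, score_structure


def _random_seq(rng, max_len=12, min_len=1):
    length = rng.integers(min_len, max_len + 1)
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


class TestFold:
    def test_too_short_to_pair_is_all_unpaired(self):
        assert ib.fold(ib.NucSequence("t", "AAAA")).ss.structure == "...."

    def test_gc_hairpin_is_the_unique_optimum(self):
        # exhaustive enumeration confirms (((....))) is the single best structure
        best, optima = best_structures("GGGAAAACCC")
        assert len(optima) == 1
        ssq = ib.fold(ib.NucSequence("t", "GGGAAAACCC"))
        assert ssq.ss.structure == "(((....)))"
        assert structure_score(ssq) == best

    def test_dp_score_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = _random_seq(rng)
            ssq = ib.fold(ib.NucSequence("t", seq))
            best, _ = best_structures(seq)
            assert structure_score(ssq) == best, seq

    def test_tie_breaking_returns_lexicographically_smallest_optimum(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq = _random_seq(rng, max_len=10, min_len=5)
            ssq = ib.fold(ib.NucSequence("t", seq))
            _, optima = best_structures(seq)
            expected = min(sorted(o) for o in optima)
            assert list(ssq.ss.pairs) == expected, seq

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(0)
        seq = ib.NucSequence("t", _random_seq(rng, max_len=60, min_len=40))
        assert ib.fold(seq).ss.structure == ib.fold(seq).ss.structure

    def test_forcing_a_pair_never_increases_the_score(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 30:
            seq = _random_seq(rng, max_len=15, min_len=8)
            free = ib.fold_score(ib.NucSequence("t", seq))
            i = int(rng.integers(1, len(seq) - MIN_LOOP))
            j = int(rng.integers(i + MIN_LOOP + 1, len(seq) + 1))
            if seq[i - 1] + seq[j - 1] not in ("GC", "CG", "AU", "UA", "GU", "UG"):
                continue
            forced = ib.fold_score(ib.NucSequence("t", seq), forced=[(i, j)])
            assert forced <= free
            checked += 1

    def test_forced_pair_appears_and_forbidden_pair_does_not(self):
        seq = ib.NucSequence("t", "GGGAAAACCC")
        ssq = ib.fold(seq, forbidden=[(1, 10)])
        assert (1, 10) not in ssq.ss.pairs
        ssq2 = ib.fold(seq, forced=[(2, 10)])
        assert (2, 10) in ssq2.ss.pairs

    def test_inconsistent_constraints_raise(self):
        seq = ib.NucSequence("t", "GGGGAAAACCCC")
        with pytest.raises(ib.ConstraintError, match="cross"):
            ib.fold(seq, forced=[(1, 9), (3, 11)])
        with pytest.raises(ib.ConstraintError, match="non-pairing"):
            ib.fold(seq, forced=[(1, 5)])  # G opposite A cannot pair
        with pytest.raises(ib.ConstraintError, match="forced and forbidden"):
            ib.fold(seq, forced=[(1, 12)], forbidden=[(1, 12)])


class TestDomains:
    def test_two_hairpin_toy(self):
        ss = ib.SecondaryStructure.from_dotbracket("(((...)))...(((...)))")
        seq = ib.NucSequence("t", "GGGAAACCCAAAGGGAAACCC")
        dm = annotate_domains(ib.StructuredSequence(seq, ss))
        assert [h.label for h in dm.helices] == ["I", "II"]
        assert dm.helices[0].span == (1, 9)
        # linker is the only top-level unpaired interval (termini are empty)
        assert dm.ss_regions == ((10, 12),)
        assert not dm.canonical

    def test_unpaired_sequence_flagged_non_canonical(self):
        dm = annotate_domains(ib.SecondaryStructure.from_dotbracket("...."))
        assert dm.helices == ()
        assert dm.ss_regions == ((1, 4),)
        assert not dm.canonical

    def test_synthetic_reference_yields_four_helices_five_ss_regions(self, reference_and_template):
        ref, _ = reference_and_template
        dm = annotate_domains(ref)
        assert [h.label for h in dm.helices] == ["I", "II", "III", "IV"]
        assert len(dm.ss_regions) == 5
        assert dm.canonical
        spec = ib.default_spec(1)
        assert [len(h.pairs) for h in dm.helices] == list(spec.stems)

    def test_coverage_partition_invariant(self, reference_and_template):
        ref, _ = reference_and_template
        dm = annotate_domains(ref)
        counts = np.zeros(dm.length + 1, dtype=int)
        for h in dm.helices:
            counts[h.span[0] : h.span[1] + 1] += 1
        for a, b in dm.ss_regions:
            counts[a : b + 1] += 1
        assert (counts[1:] == 1).all()

    def test_bulged_stem_merges_within_tolerance(self):
        # 2 pairs, a 2-nt bulge on the 5' strand, then 2 more pairs: one helix
        ss = "((..((...))))"
        dm = annotate_domains(ib.SecondaryStructure.from_dotbracket(ss))
        assert len(dm.helices) == 1
        assert len(dm.helices[0].pairs) == 4


class TestFractionPairedAndCoordinates:
    def test_fraction_paired_examples(self):
        unpaired = ib.StructuredSequence(
            ib.NucSequence("t", "AAAA"), ib.SecondaryStructure.from_dotbracket("....")
        )
        assert ib.fraction_paired(unpaired) == 0.0
        hairpin = ib.StructuredSequence(
            ib.NucSequence("t", "GGGAAAACCC"), ib.SecondaryStructure.from_dotbracket("(((....)))")
        )
        assert ib.fraction_paired(hairpin) == pytest.approx(0.6)

    def test_reference_fraction_paired_is_closed_form(self, reference_and_template):
        ref, _ = reference_and_template
        spec = ib.default_spec(1)
        expected = 2 * sum(spec.stems) / len(ref.seq)
        assert ib.fraction_paired(ref) == pytest.approx(expected)

    def test_basal_pair_has_offset_one(self, reference_and_template):
        ref, _ = reference_and_template
        dm = annotate_domains(ref)
        h3 = dm.helix("III")
        assert ib.helix_local_coordinates(dm, h3.pairs[0]) == ("III", 1)
        h1 = dm.helix("I")
        assert ib.helix_local_coordinates(dm, h1.pairs[1]) == ("I", 2)

    def test_unpaired_position_raises(self, reference_and_template):
        ref, _ = reference_and_template
        dm = annotate_domains(ref)
        a, _b = dm.ss_regions[0]
        with pytest.raises(ib.Its2Error):
            ib.helix_local_coordinates(dm, (a, a + 50))
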