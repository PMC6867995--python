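import pytest

from introscan import energetics, match_at, parse_descriptor, scan
from introscan.scanner import (
    NucleotideSequence,
    SequenceAlphabetError,
    render_dot_bracket,
    validate_match,
)
from introscan.nullsim import implant, random_sequences

from _oracles import brute_force_scan
from conftest import make_random_descriptor


class TestSequences:
    def test_t_mapped_to_u_and_uppercased(self):
        s = NucleotideSequence.from_string("x", "acgt")
        assert s.residues == "ACGU"

    def test_bad_alphabet_rejected(self):
        with pytest.raises(SequenceAlphabetError):
            NucleotideSequence.from_string("x", "ACGX")

    def test_n_allowed(self):
        assert NucleotideSequence.from_string("x", "ANN").residues == "ANN"


class TestToyScan:
    def test_unique_hairpin_placement(self, hairpin):
        seq = NucleotideSequence.from_string("t", "GGGGAAAACCCC")
        ms = scan(seq, hairpin, policy="all")
        assert len(ms) == 1
        assert ms[0].dot_bracket == "((((....))))"
        assert (ms[0].start, ms[0].end) == (0, 12)

    def test_short_sequence_empty_not_error(self, hairpin):
        seq = NucleotideSequence.from_string("t", "GGGAAA")
        assert scan(seq, hairpin) == []

    def test_n_never_pairs(self, hairpin):
        seq = NucleotideSequence.from_string("t", "GGGNAAAANCCC")
        assert scan(seq, hairpin, policy="all") == []

    def test_match_at_pattern_gate(self, iia):
        seq = NucleotideSequence.from_string("t", "A" * 300)
        assert match_at(seq, iia, 10) is None

    def test_match_at_without_room(self, hairpin):
        seq = NucleotideSequence.from_string("t", "GGGGAAAACCCC")
        assert match_at(seq, hairpin, 5) is None


class TestDotBracket:
    def test_two_sibling_helices_balanced(self):
        d = parse_descriptor(
            """
name: two
elements:
  - {type: helix5, id: a, min: 2, max: 2}
  - {type: strand, id: la, min: 2, max: 2}
  - {type: helix3, id: a}
  - {type: strand, id: mid, min: 2, max: 2}
  - {type: helix5, id: b, min: 2, max: 2}
  - {type: strand, id: lb, min: 2, max: 2}
  - {type: helix3, id: b}
"""
        )
        seq = NucleotideSequence.from_string("t", "GGAACCAAGGAACC")
        ms = scan(seq, d, policy="all")
        assert any(m.dot_bracket == "((..))..((..))" for m in ms)
        for m in ms:
            db = render_dot_bracket(m)
            assert db.count("(") == db.count(")") == sum(
                b - a for k, (a, b) in m.element_spans.items() if k.endswith(".5p")
            )


class TestOracleEquivalence:
    def test_scan_all_equals_brute_force(self, rng):
        """Exhaustive length-assignment enumeration agrees with the matcher."""
        for trial in range(120):
            d = make_random_descriptor(rng)
            n = int(rng.integers(10, 41))
            seq_str = "".join(
                "ACGU"[i] for i in rng.integers(0, 4, n)
            )
            seq = NucleotideSequence.from_string(f"r{trial}", seq_str)
            got = {
                frozenset((k, a, b) for k, (a, b) in m.element_spans.items())
                for m in scan(seq, d, policy="all")
            }
            expected = brute_force_scan(seq.residues, d)
            assert got == expected

    def test_every_match_revalidates(self, iia, rng, composition):
        bg = random_sequences(composition, length=900, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=400, rng=rng)
        ms = scan(seq, iia)
        assert ms
        for m in ms:
            assert validate_match(m, seq, iia) == []

    def test_anchoring_at_splice_site_only(self, iia, rng, composition):
        bg = random_sequences(composition, length=900, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=400, rng=rng)
        for m in scan(seq, iia, policy="all"):
            assert seq.residues[m.start : m.start + 5] in (
                "GUGCG", "UUGCG", "GGGCG",
            )


class TestImplantRecall:
    def test_implant_found_at_truth_locus(self, iia, rng, composition):
        found = 0
        for k in range(15):
            bg = random_sequences(composition, length=1200, n=1, rng=rng)[0]
            seq, truth = implant(bg, iia, position=500, rng=rng)
            ms = scan(seq, iia)
            span = truth.end - truth.start
            if any(
                min(m.end, truth.end) - max(m.start, truth.start) > 0.5 * span
                for m in ms
            ):
                found += 1
        assert found >= 14

    def test_match_at_truth_anchor(self, iia, rng, composition):
        bg = random_sequences(composition, length=1200, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=500, rng=rng)
        m = match_at(seq, iia, truth.start)
        assert m is not None
        assert m.start == truth.start


class TestBestPerLocus:
    def test_overlapping_reduced_to_lowest_energy(self, iia, rng, composition):
        bg = random_sequences(composition, length=1200, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=500, rng=rng)
        ms = scan(seq, iia, policy="best_per_locus")
        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                ov = min(a.end, b.end) - max(a.start, b.start)
                assert ov < 0.5 * min(a.end - a.start, b.end - b.start)

    def test_representative_is_minimum_energy(self, rng):
        """match_at returns the exact minimum over all satisfying folds."""
        d = parse_descriptor(
            """
name: flex
elements:
  - {type: strand, id: s0, min: 0, max: 3}
  - {type: helix5, id: a, min: 3, max: 6}
  - {type: strand, id: la, min: 3, max: 8}
  - {type: helix3, id: a}
  - {type: strand, id: s1, min: 0, max: 3}
"""
        )
        checked = 0
        for _ in range(60):
            n = int(rng.integers(15, 35))
            seq = NucleotideSequence.from_string(
                "r", "".join("ACGU"[i] for i in rng.integers(0, 4, n))
            )
            all_matches = scan(seq, d, policy="all")
            by_anchor: dict = {}
            for m in all_matches:
                by_anchor.setdefault(m.start, []).append(m.energy)
            for anchor, energies in by_anchor.items():
                best = match_at(seq, d, anchor)
                assert best is not None
                assert best.energy == pytest.approx(min(energies), abs=1e-9)
                checked += 1
        assert checked > 20

    def test_implant_representative_beats_enumeration_cap(self, iia, rng, composition):
        bg = random_sequences(composition, length=900, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=400, rng=rng)
        best = match_at(seq, iia, truth.start)
        assert best is not None
        capped = [
            m.energy for m in scan(seq, iia, policy="all")
            if m.start == truth.start
        ]
        assert best.energy <= min(capped) + 1e-9

    def test_fast_energy_equals_dot_bracket_evaluation(self, iia, rng, composition):
        bg = random_sequences(composition, length=900, n=1, rng=rng)[0]
        seq, _ = implant(bg, iia, position=400, rng=rng)
        for m in scan(seq, iia, policy="all")[:50]:
            e = energetics.evaluate_energy(m.window(seq), m.dot_bracket)
            assert m.energy == pytest.approx(e, abs=1e-9)
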