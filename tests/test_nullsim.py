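import itertools

import numpy as np
import pytest

from introscan.nullsim import (
    DinucleotideComposition,
    default_composition,
    dinucleotide_shuffle,
    estimate_fp_rate,
    garwood_ci,
    implant,
    random_sequences,
)


def dinuc_counts(s: str) -> dict:
    out: dict = {}
    for i in range(len(s) - 1):
        out[s[i : i + 2]] = out.get(s[i : i + 2], 0) + 1
    return out


class TestComposition:
    def test_from_sequence_roundtrip(self):
        c = DinucleotideComposition.from_sequence("GGAUCCGAU")
        assert c.counts["GA"] == 2 and c.counts["AU"] == 2
        assert c.is_realizable()

    def test_shipped_composition_realizable(self):
        assert default_composition().is_realizable()

    def test_unrealizable_composition_detected(self):
        counts = {a + b: 0.0 for a in "ACGU" for b in "ACGU"}
        counts["AA"] = 3
        counts["CC"] = 3  # two disconnected components
        assert not DinucleotideComposition(counts).is_realizable()


class TestRandomSequences:
    def test_homopolymer_chain_forced(self):
        c = DinucleotideComposition.from_sequence("AAAAAA")
        (s,) = random_sequences(c, length=50, n=1, seed=1)
        assert s.residues == "A" * 50

    def test_same_seed_identical(self, composition):
        a = random_sequences(composition, length=300, n=3, seed=42)
        b = random_sequences(composition, length=300, n=3, seed=42)
        assert [x.residues for x in a] == [y.residues for y in b]

    def test_uniform_composition_frequencies(self):
        counts = {a + b: 10.0 for a in "ACGU" for b in "ACGU"}
        c = DinucleotideComposition(counts)
        seqs = random_sequences(c, length=5000, n=40, seed=3)
        totals: dict = {}
        n_di = 0
        for s in seqs:
            for di, k in dinuc_counts(s.residues).items():
                totals[di] = totals.get(di, 0) + k
                n_di += k
        p = 1 / 16
        sd = np.sqrt(p * (1 - p) * n_di)
        for di, k in totals.items():
            assert abs(k - p * n_di) < 4 * sd, di

    def test_unrealizable_rejected(self):
        counts = {a + b: 0.0 for a in "ACGU" for b in "ACGU"}
        counts["AA"] = 3
        counts["CC"] = 3
        with pytest.raises(ValueError):
            random_sequences(DinucleotideComposition(counts), length=10, n=1, seed=0)


class TestShuffle:
    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_counts_and_termini_preserved(self, rng):
        """The defining invariant, on thousands of random inputs."""
        for _ in range(2000):
            n = int(rng.integers(2, 60))
            s = "".join("ACGU"[i] for i in rng.integers(0, 4, n))
            t = dinucleotide_shuffle(s, rng=rng)
            assert dinuc_counts(t) == dinuc_counts(s)
            assert t[0] == s[0] and t[-1] == s[-1]

    def test_all_valid_shuffles_reachable_and_roughly_uniform(self):
        """Against exhaustive enumeration of the 8-mer's Euler paths."""
        s = "GCAUGCAU"
        target = dinuc_counts(s)
        valid = {
            "".join(p)
            for p in itertools.permutations(s)
            if "".join(p)[0] == s[0]
            and "".join(p)[-1] == s[-1]
            and dinuc_counts("".join(p)) == target
        }
        rng = np.random.default_rng(8)
        seen: dict = {}
        n_draws = 10_000
        for _ in range(n_draws):
            t = dinucleotide_shuffle(s, rng=rng)
            assert t in valid
            seen[t] = seen.get(t, 0) + 1
        assert set(seen) == valid
        expected = n_draws / len(valid)
        for t, k in seen.items():
            assert abs(k - expected) < 6 * np.sqrt(expected), t

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A", seed=0)


class TestImplant:
    def test_truth_spans_tile_and_splice_site_planted(self, iia, rng, composition):
        bg = random_sequences(composition, length=1000, n=1, rng=rng)[0]
        seq, truth = implant(bg, iia, position=400, rng=rng)
        assert truth.splice_site in ("GUGCG", "UUGCG", "GGGCG")
        assert seq.residues[truth.start : truth.start + 5] == truth.splice_site
        pos = truth.start
        for el in iia.elements:
            key = (
                f"{el.id}.{el.side}p" if hasattr(el, "side") else el.id
            )
            a, b = truth.element_spans[key]
            assert a == pos
            pos = b
        assert pos == truth.end

    def test_position_too_close_to_edge_rejected(self, iia, rng, composition):
        bg = random_sequences(composition, length=300, n=1, rng=rng)[0]
        with pytest.raises(ValueError):
            implant(bg, iia, position=5, rng=rng)
        with pytest.raises(ValueError):
            implant(bg, iia, position=295, rng=rng)

    def test_deterministic_by_seed(self, iia, composition):
        bg = random_sequences(composition, length=1000, n=1, seed=5)[0]
        s1, t1 = implant(bg, iia, position=400, seed=9)
        s2, t2 = implant(bg, iia, position=400, seed=9)
        assert s1.residues == s2.residues and t1 == t2


class TestFPRate:
    def test_garwood_brackets_rate(self):
        lo, hi = garwood_ci(5, 1000)
        assert lo < 5 / 1000 < hi
        lo0, hi0 = garwood_ci(0, 1000)
        assert lo0 == 0.0 and hi0 > 0

    def test_filters_only_remove(self, iia, composition):
        raw = estimate_fp_rate(
            iia, total_nt=60_000, seed=4, composition=composition,
            with_splice=False, with_tertiary=False,
        )
        filt = estimate_fp_rate(
            iia, total_nt=60_000, seed=4, composition=composition,
            with_splice=True, with_tertiary=True,
        )
        assert filt.hits <= raw.hits
        assert raw.rate >= filt.rate
        assert filt.ci_low <= filt.rate <= filt.ci_high
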