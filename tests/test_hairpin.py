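"""Folding DP, window excision, star location, and the precursor criteria."""

import numpy as np
import pytest

from mirseed._seq import revcomp
from mirseed.hairpin import (
    MIN_LOOP,
    PAIR_ENERGY,
    _CODE,
    evaluate_precursor,
    extract_window,
    fold,
    gc_content,
    locate_star,
    pair_partners,
)
from mirseed.mapping import GenomicLocus


def enumeration_mfe(seq):
    """Independent exhaustive minimum over all nested structures (n <= ~18)."""
    code = [_CODE[c] for c in seq]

    def best(i, j):
        if j - i <= MIN_LOOP:
            return 0.0
        b = best(i + 1, j)
        for t in range(i + MIN_LOOP + 1, j + 1):
            e = PAIR_ENERGY[code[i], code[t]]
            if e < 0:
                b = min(b, e + best(i + 1, t - 1) + best(t + 1, j))
        return b

    return best(0, len(seq) - 1)


class TestFold:
    def test_unpairable_sequence(self):
        db, mfe = fold("AAAAAAAAAA")
        assert (db, mfe) == ("." * 10, 0.0)

    def test_perfect_gc_hairpin(self):
        db, mfe = fold("GGGGGAAAACCCCC")
        assert db == "(((((....)))))"
        assert mfe == -15.0

    def test_structure_well_formed(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            s = "".join(bases[rng.integers(0, 4, size=60)])
            db, mfe = fold(s)
            assert len(db) == len(s)
            partners = pair_partners(db)  # raises if unbalanced
            assert mfe <= 0
            if all(p < 0 for p in partners):
                assert mfe == 0.0

    def test_dp_equals_enumeration(self, rng):
        """DP minimum equals the brute-force enumeration on short sequences."""
        bases = np.array(list("ACGT"))
        for _ in range(200):
            n = int(rng.integers(5, 19))
            s = "".join(bases[rng.integers(0, 4, size=n)])
            _, mfe = fold(s)
            assert mfe == pytest.approx(enumeration_mfe(s), abs=1e-9)

    def test_appending_cytosines_never_lowers_mfe(self, rng):
        """C cannot pair in a G-free sequence, so padding with C is neutral."""
        bases = np.array(list("ACT"))
        for _ in range(20):
            s = "".join(bases[rng.integers(0, 3, size=30)])
            _, base_mfe = fold(s)
            _, padded_mfe = fold(s + "C" * 10)
            assert padded_mfe >= base_mfe - 1e-9

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold("ACGTNACGTNACGT")


class TestGcContent:
    @pytest.mark.parametrize("seq,pct", [("GCGC", 100.0), ("AUAU", 0.0)])
    def test_extremes(self, seq, pct):
        assert gc_content(seq) == pct

    def test_matches_hand_count(self, rng):
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, size=97)])
        assert gc_content(s) == pytest.approx(
            100 * (s.count("G") + s.count("C")) / len(s)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestExtractWindow:
    def test_centered_window(self, rng):
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
        locus = GenomicLocus("r", 5000, 5021, "+")
        w, off = extract_window(ref, locus, 250)
        assert len(w) == 250
        assert off == 114
        assert w[off : off + 21] == ref[5000:5021]

    def test_left_truncated(self, rng):
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])
        locus = GenomicLocus("r", 50, 71, "+")
        w, off = extract_window(ref, locus, 250)
        assert w.startswith(ref[0])
        assert off == 50
        assert w[off : off + 21] == ref[50:71]

    def test_minus_strand_is_revcomp_of_plus(self, rng):
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
        plus = GenomicLocus("r", 900, 921, "+")
        minus = GenomicLocus("r", 900, 921, "-")
        w_plus, _ = extract_window(ref, plus, 250)
        w_minus, off = extract_window(ref, minus, 250)
        assert w_minus == revcomp(w_plus)
        assert w_minus[off : off + 21] == revcomp(ref[900:921])

    def test_locus_outside_reference(self):
        with pytest.raises(ValueError):
            extract_window("ACGT" * 10, GenomicLocus("r", 100, 121, "+"), 250)


def _duplex_hairpin(mature, loop="AACAA"):
    return mature + loop + revcomp(mature)


class TestLocateStar:
    def test_perfect_duplex_no_mismatches(self):
        mature = "TGGAGAAGCAGGGCACGTGCA"
        seq = _duplex_hairpin(mature)
        db, _ = fold(seq)
        (lo, hi), mm = locate_star(db, (0, len(mature)))
        assert mm == 0
        assert lo >= len(mature)

    def test_engineered_bulges_counted(self):
        """Three mature positions left unpaired in the duplex count as three
        star mismatches; the star span covers the partner ladder plus the
        2 nt 3' overhang."""
        # mature [0,21), loop [21,26), star [26,47); positions 4-6 bulged
        mature_part = "".join("." if i in (4, 5, 6) else "(" for i in range(21))
        star_part = "".join("." if i in (40, 41, 42) else ")" for i in range(26, 47))
        db = mature_part + "....." + star_part
        (lo, hi), mm = locate_star(db, (0, 21))
        assert mm == 3
        assert (lo, hi) == (26, 47)

    def test_mature_across_loop_fails(self):
        mature = "GGGGGGGGGG"
        seq = mature + "AAAA" + revcomp(mature)
        db, _ = fold(seq)
        # span covering the loop: pairs fall inside the span itself
        with pytest.raises(ValueError):
            locate_star(db, (5, 19))


class TestEvaluatePrecursor:
    def test_planted_precursors_pass(self, small_truth):
        for p in small_truth.precursors:
            w, off = extract_window(small_truth.genome["chr1"], p.locus, 250)
            cand = evaluate_precursor(w, (off, off + len(p.mature)))
            assert cand.passed, cand.failed_criteria
            assert cand.mfe < 0
            assert 30 <= cand.gc <= 70
            assert cand.star_mismatches <= 6

    def test_gc_out_of_range_fails_gc_only(self):
        mature = "GGGGGCCCCCGGGGGCCCCCG"
        seq = _duplex_hairpin(mature)  # GC-saturated window
        cand = evaluate_precursor(seq, (0, len(mature)))
        assert "gc" in cand.failed_criteria

    def test_star_mismatch_boundary(self):
        """Seven unpaired mature positions violate the six-mismatch bound."""
        mature = "TGGAGAAGCAGGGCACGTGCA"
        star = list(revcomp(mature))
        for p in range(7):
            j = len(mature) - 1 - (p + 3)
            star[j] = {"A": "C", "C": "A", "G": "A", "T": "C"}[star[j]]
        seq = "AACCA" + mature + "AACAA" + "".join(star) + "CCAAC"
        cand = evaluate_precursor(seq, (5, 5 + len(mature)))
        if cand.star_mismatches is not None and cand.star_mismatches > 6:
            assert "star" in cand.failed_criteria

    def test_verdict_is_conjunction_of_criteria(self, small_truth, rng):
        """Disabling every failed criterion turns any candidate into a pass."""
        bases = np.array(list("ACGT"))
        all_criteria = ("stem_loop", "star", "mfe", "gc")
        for _ in range(25):
            seq = "".join(bases[rng.integers(0, 4, size=80)])
            cand = evaluate_precursor(seq, (10, 31))
            enabled = tuple(c for c in all_criteria if c not in cand.failed_criteria)
            relaxed = evaluate_precursor(seq, (10, 31), criteria=enabled)
            assert relaxed.passed
            assert cand.passed == (not cand.failed_criteria)
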